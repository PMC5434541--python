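# Methods

## The measurement model

The package measures mucociliary transport (MCT) as the motion of discrete
radio-opaque marker beads (~103 μm glass spheres) on the airway surface,
imaged as dark discs in 2D absorption-dominated X-ray frames. Three
assumptions define the scope:

- the anatomy is rigid over a run (tissue drift invalidates the run rather
  than being corrected);
- beads are compact, roughly circular features a few pixels across, darker
  than their local background;
- per-frame bead displacement is bounded by the linking gate — the gate is
  a *measurement* parameter that caps the observable speed at
  `gate_px · pixel_size · 60 / (frame_interval · 1000)` mm/min.

Coordinates are raster: x = column rightward, y = row downward, origin at
the top-left pixel centre. Reported velocities flip the y-axis so up-image
(cranial) motion is positive; angles are degrees from vertical-up, positive
toward image-right, computed as `atan2(vx, vy)`. A stationary step has
angle 0 by convention and is flagged degenerate.

## Pipeline stages and key parameters

**Flat-field**: `(frame − dark) / (flat − dark)`; optional, used when a
beam image is available. Idempotent for flat = 1, dark = 0.

**Background**: `static_reference` (a particle-free frame captured before
particle delivery) or `temporal_median` (per-pixel median over ≥3 frames;
a moving bead occupies any pixel a minority of frames, so the median
suppresses it). The temporal-median mode is this package's addition for
runs that lack a reference frame. Residuals are `background − frame`, so
absorbing beads become positive peaks and detection thresholds one tail.

**Drift QC**: per-frame rigid translation against the background raster,
estimated by upsampled-DFT cross-correlation
(`skimage.registration.phase_cross_correlation`, `normalization=None`,
upsample 20). Plain (unnormalized) correlation is used because the frames
and background share illumination; it is exact on integer shifts and
subpixel otherwise. A run fails when the maximum drift magnitude exceeds
`drift_threshold_px` (default 5 px — a third of the linking gate; beyond
that, misregistered anatomy produces bead-scale residuals). Failing runs
are excluded, never warped back: elastic registration is out of scope. A
constant background makes translation unidentifiable and is an error.

**Detection** (per residual frame): Gaussian smooth (σ = 1.5 px) →
threshold → 8-connected components → area window → circularity filter
(4πA/P² ≥ 0.4, permissive because bead strings are elongated) →
intensity-weighted subpixel centroid, output sorted by (y, x) for
determinism. The default threshold is `k · robust_sd(raw residual)` with
k = 5 and robust SD = 1.4826·MAD. The noise scale is taken from the *raw*
residual, not the smoothed one: smoothing suppresses the noise floor ~5×,
and thresholding the smoothed frame at a fraction of *its* noise would
segment far down the blurred bead tails, bridging beads nearly two
diameters apart and inflating areas past the aggregate bound. With the raw
noise scale, blobs stay near the nominal bead footprint
(π·(d/2s)² ≈ 32.6 px² at 103 μm / 16 μm px), and the area window
(0.4–4 × nominal) admits singles and small aggregates. On a noise-free
residual the robust SD is zero; the threshold then falls back to half the
peak amplitude so synthetic noiseless inputs keep the nominal footprint.
Tightly aggregated beads are deliberately *not* split (no watershed): a
string travels as one detection, which matches how aggregated particles
move (as a unit, at a common speed) and keeps rate statistics honest.

**Linking**: frame by frame, open tracks and new detections are matched by
`scipy.optimize.linear_sum_assignment` on squared displacement, with pairs
beyond the gate assigned a forbidden cost chosen *just* above the largest
achievable feasible total — large enough that the solver maximizes the
number of feasible matches first, small enough that real cost differences
survive float64 addition (a sentinel like 1e18 silently erases them). A
track missed for up to `max_gap_frames` (default 2: particles are
typically lost "for a frame or two") may re-link with the gate scaled
linearly by the gap length, bounding implied speed consistently. Unmatched
detections always seed new tracks; every detection ends up in exactly one
track. `filter_tracks` removes singletons and, optionally, tracks with
small net displacement (static bubble-like confounders).

**Kinematics**: the headline "mean instantaneous rate" is the mean of
per-step speeds pooled over all samples (not per-track means averaged), so
abundant slow particles pull the mean down by design. The mean direction
is the resultant (vector-sum) angle — well defined on the circle — with
the arithmetic mean of sample angles reported alongside. Gap-spanning
samples are gap-averaged velocities, flagged, and included by default.
Heat-maps are square 2D histograms over (vx, vy) with out-of-extent
samples counted separately. Treatment time-courses align one bin edge at
the treatment start, so the first post bin includes the delivery window.

**Validation**: per frame, detections are matched one-to-one to truth
within a radius (default one bead diameter ≈ 6.4 px: a detection farther
than its own diameter from every truth is a different object), maximizing
matches then minimizing total distance. Sensitivity = TP/(TP+FN) pooled
over frames; precision is auxiliary. Track-level observation recall is
scored separately (a bead can be detected yet lost by the linker), with
per-particle best-single-track coverage for fragmentation analysis.

## The phantom generator

The generator emulates a vertically mounted tracheal segment viewed in 2D:

- **background**: base transmitted intensity 0.75 (arbitrary units) with
  ~3 horizontal cartilage bands per field (amplitude 0.08), low-frequency
  tissue mottle, and a smooth radial beam-profile falloff (amplitude
  0.15). The `pig_dense` style adds high-frequency speckle (amplitude
  0.15, half the bead contrast) — features of bead-like local contrast,
  which is what makes detection harder on dense cartilage;
- **beads**: radially smooth dark discs, profile
  `0.5·(1 − tanh((r − R)/w))` with a ~1 px edge, multiplied into the
  background (contrast 0.3). Ground truth records the exact rendered
  centres before additive Gaussian noise (SD 0.01);
- **motion**: per-particle speed drawn log-normal
  (`median · exp(shape·Z)`; sheep-like default median 1.336, shape 0.6 —
  mean 1.6 mm/min) and heading drawn normal (default −14.3° ± 20°), fixed
  over the run (persistent transport tracts); an optional heading jitter
  exists as an extension. Per-frame displacement is
  `speed · Δt / 60 · 1000 / pixel_size` px along the heading;
- **cadence**: 2.4 s (sheep-like) and 0.6 s (pig-like) frame intervals,
  chosen so the 15 px gate at 16 μm/px corresponds to the 6 and
  24 mm/min speed ceilings; the intervals are internal consistency
  choices, not measured quantities;
- **confounders**: a configurable fraction of beads aggregated into rigid
  "strings" sharing one path with small lateral offsets; stationary dark
  annuli emulating surface bubbles, present in the frames but absent from
  the clean reference background so they survive subtraction as static
  false positives;
- **drift**: an optional rigid whole-field translation per frame applied
  jointly to tissue, bubbles and beads;
- **respawn** (default on): a particle exiting the field is replaced by a
  fresh particle (new identity, freshly drawn speed and heading) entering
  at the caudal (bottom) edge, emulating continuous particle entry and
  keeping the field population roughly constant. Exited particles remain
  flagged in ground truth.

Everything derives from a single integer seed; identical parameters give
bit-identical sequences and truth tables.

### What the phantom does not model

No Fresnel phase contrast (beads here are absorption-contrast discs), no
photon statistics (noise is additive Gaussian), no 3D cylindrical geometry
or projection foreshortening, no elastic tissue deformation, no mucus
rheology, and no bead–bead interaction beyond rigid strings. Passing tests
therefore demonstrate correctness of the measurement chain under
controlled conditions — not robustness to every artefact of real beamline
data (e.g. ring artefacts, respiratory motion, phase fringes).

## Measurement designs used by the test and acceptance runs

Problem sizes are chosen to exercise each property at desk scale:

- *End-to-end rate recovery*: 50 particles, 150 frames, full
  874 × 1036 px field (≈14 × 16.6 mm at 16 μm/px), ~1.6 mm/min mean.
  Recovery is judged against the ground truth *pooled over observations*:
  in a clearance geometry fast particles exit sooner, so the
  observation-pooled mean sits below the per-particle mean — both the
  measurement and its truth are pooled the same way.
- *Directionality*: 300 particles (comparable to a dense imaging run's
  per-frame particle load), 50 frames. The recovered resultant angle is
  compared to the truth-trajectory resultant computed with identical
  pooling: the configured mean heading (−14.3°) is the setup, but any
  finite draw of 300 headings realizes a slightly different direction
  (SE ≈ 20°/√300 ≈ 1.2°), and pooling weights particles by residence
  time, so the realized pooled direction — not the configured constant —
  is the recoverable truth.
- *Speed-ceiling behaviour*: a fixed cohort (no respawn) moving at exactly
  0.8× or 1.2× the ceiling with parallel headings and equal speeds. With
  identical displacements, optimal assignment provably preserves identity
  for any spawn configuration, making the single-unbroken-track property
  deterministic rather than dependent on a lucky spatial draw.
- *Treatment transient*: degenerate speed distribution (all particles at
  1.6 mm/min). With dispersed speeds a clearance run is inherently
  non-stationary — the standing population is length-biased toward slow
  particles, and its mean decays toward the biased steady state — which
  would confound a null-treatment flatness check. Fixing the base speed
  isolates the imposed transient
  `1 + (boost−1)·exp(−(t−t₀)/τ)` (boost 1.5, τ = 60 s), which is the
  property under test.

## Numerical choices

- Robust noise scale: 1.4826·MAD (immune to the beads themselves).
- Assignment forbidden cost: `max_gate² · min(n_tracks, n_detections) + 1`
  (see linking above).
- Subpixel drift: upsampled-DFT correlation, factor 20 (0.05 px grid).
- Tie-breaks: detections processed in (frame, y, x) order; track ids
  assigned in creation order — output tables are byte-reproducible for a
  fixed seed.
- Degenerate inputs: empty frames yield empty (typed) tables; empty sample
  sets raise; a featureless background raises in drift estimation;
  sub-resolution bead sizes warn.

## Known limitations

- Aggregated beads are a single detection until the string disperses;
  their individual identities are not recoverable by design.
- The gate imposes a hard speed ceiling; above-ceiling transport appears
  as track fragmentation, not as a measured (higher) rate.
- Drift is assessed, never corrected; slowly deforming tissue that is not
  a rigid translation can evade the QC.
- The resultant mean direction is residence-time weighted; for strongly
  dispersed headings it differs from the unweighted per-particle mean
  heading (both are reported).
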