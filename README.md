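# mcttrack

Particle-tracking velocimetry for **mucociliary transport (MCT)**
measurement in 2D grayscale time-lapse image sequences of airway tissue.

Mucociliary transport — the cilia-driven movement of mucus and deposited
particles along the airway surface — is a primary defence of the lung and a
key readout for therapies in diseases such as cystic fibrosis. In
synchrotron X-ray imaging of tracheal tissue, ~100 μm high-refractive-index
glass beads deposited on the airway surface act as radio-opaque markers:
their motion across an image sequence *is* the local transport. This
package turns such sequences into physical transport measurements:

1. **preprocess** — flat-field correction, background removal (a
   particle-free reference frame, or the per-pixel temporal median of the
   run), and a drift QC that excludes runs whose tissue moved;
2. **detect** — beads as positive residual blobs: smooth → threshold →
   8-connected components → area/circularity filters → intensity-weighted
   subpixel centroids;
3. **link** — detections joined into tracks by globally optimal one-to-one
   assignment (minimum total squared displacement) under a displacement
   gate, with short gap closing;
4. **kinematics** — per-step velocities in mm/min, pooled rate statistics,
   transport angles, 2D velocity heat-maps and treatment time-courses;
5. **validate** — TP/FP/FN scoring against ground truth or annotations,
   with sensitivity = TP/(TP+FN);
6. **phantom** — a synthetic generator that renders textured cartilage
   backgrounds, moving beads, aggregates, stationary bubble confounders,
   noise and drift, with exact ground-truth trajectories, so the whole
   chain is testable without beamline data.

## The measurement

For a track observed at positions $x_i, x_{i+1}$ (pixels) in frames
separated by $g$ frames, the instantaneous velocity is

$$v = \frac{\Delta x \cdot s \cdot 60}{g\,\Delta t \cdot 1000}\ \text{mm/min},$$

with pixel size $s$ (μm) and frame interval $\Delta t$ (s). Up-image motion
(the cranial clearance direction) is positive $v_y$; the transport angle is
$\operatorname{atan2}(v_x, v_y)$, 0° straight up, positive toward
image-right. The headline rate is the mean of per-step speeds pooled over
all samples; the mean direction is the vector-resultant angle.

A linker that refuses displacements beyond a gate of $G$ pixels per frame
caps the measurable speed at

$$v_{\max} = \frac{G \cdot s \cdot 60}{\Delta t \cdot 1000},$$

e.g. 6.0 mm/min for a 15 px gate at 16 μm/px and 2.4 s cadence, and
24.0 mm/min at 0.6 s cadence.

## Worked example

`python examples/simulate_and_measure.py` builds a 60-frame phantom with 25
beads (~1.6 mm/min mean, heading −14.3° from vertical), runs the full
chain, and prints:

```
frames: 60, detections: 1495, tracks: 44
recovered rate: 1.750 ± 0.989 mm/min (truth: 1.753 mm/min)
transport angle: -9.9 deg from vertical
detection sensitivity: 0.997, observation recall: 0.997
```

The recovered pooled rate matches the ground-truth pooled rate to 0.2%;
sensitivity is the fraction of true bead observations detected, recall the
fraction recovered in tracks. The other examples demonstrate directional
heat-maps (`directionality_heatmap.py`), treatment transients
(`treatment_response.py`) and drift-based run exclusion
(`drift_exclusion.py`).

A thin CLI wraps the same functions:

```sh
mcttrack simulate --preset sheep --seed 1 --out seq.tif --truth truth.csv --background bg.tif
mcttrack preprocess seq.tif --pixel-size 16 --frame-interval 2.4 --background bg.tif --out resid.tif
mcttrack detect resid.tif -o detections.csv
mcttrack track detections.csv --gate 15 -o tracks.csv
mcttrack summarize tracks.csv --pixel-size 16 --frame-interval 2.4 -o summary.json
mcttrack validate detections.csv truth.csv -o report.json
```

or `mcttrack run config.yaml -o out/` for the whole pipeline (exit status 3
signals a drift-excluded run).

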