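"""Generate a sheep-like phantom run and measure its transport rate.

Builds a synthetic tracheal image sequence with 50 beads moving up-image at
~1.6 mm/min, runs background subtraction -> detection -> gated linking ->
kinematics, and compares the recovered pooled rate against the exact ground
truth the generator recorded.
"""

import mcttrack as m
from mcttrack.detect import DetectParams, concat_detections, detect_particles
from mcttrack.preprocess import subtract_background_frame

params = m.sheep_preset(shape=(512, 512), n_frames=60, n_particles=25, seed=11)
res = m.generate_phantom(params)

model = m.build_background(mode="static_reference", reference=res.background)
dparams = DetectParams.for_bead(params.bead_diameter_um, params.pixel_size_um)
detections = concat_detections(
    [detect_particles(subtract_background_frame(f, model), dparams, frame_index=i)
     for i, f in enumerate(res.sequence)]
)
tracks = m.filter_tracks(m.link_tracks(detections, gate_px=15, max_gap_frames=2))
samples = m.track_velocities(tracks, params.pixel_size_um, params.frame_interval_s)
summary = m.run_summary(samples)

truth = res.truth.positions
report = m.sensitivity_report(detections, truth, radius_px=6.4)
recall = m.track_observation_recall(tracks, truth, radius_px=6.4)

print(f"frames: {len(res.sequence)}, detections: {len(detections)}, "
      f"tracks: {tracks.track_id.nunique()}")
print(f"recovered rate: {summary.mean_speed_mm_min:.3f} ± "
      f"{summary.sd_speed_mm_min:.3f} mm/min "
      f"(truth: {truth.speed_mm_min.mean():.3f} mm/min)")
print(f"transport angle: {summary.resultant_angle_deg:+.1f} deg from vertical")
print(f"detection sensitivity: {report.sensitivity:.3f}, "
      f"observation recall: {recall['observation_recall']:.3f}")
# The pooled rate is the mean over every per-step velocity sample; the
# angle is the direction of the vector-sum velocity (0 deg = up-image,
# the cranial clearance direction; positive = toward image-right).
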