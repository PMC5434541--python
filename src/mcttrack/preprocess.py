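"""Illumination correction, background removal and drift QC.

The anatomical background (cartilage bands, beam profile) dwarfs the bead
signal, so each frame is reduced to a residual against a background model:
either a particle-free reference frame captured before particle delivery
(``static_reference``) or a per-pixel temporal median of the run itself
(``temporal_median``), which suppresses moving beads because each bead
occupies any given pixel for only a minority of frames.

Residuals are ``background - frame``: absorbing beads appear as *positive*
peaks, so detection thresholds a single tail.

Runs in which the tissue itself moves invalidate background subtraction.
``assess_drift`` estimates a single rigid translation per frame against the
background raster and flags the run for exclusion when the maximum drift
exceeds a threshold (default 5 px, a third of the linking gate) — the
run is excluded rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .sequence_io import ImageSequence

__all__ = [
    "BackgroundModel",
    "DriftReport",
    "flat_field_correct",
    "build_background",
    "subtract_background",
    "assess_drift",
]


@dataclass
class BackgroundModel:
    """A particle-free background estimate for one run."""

    mode: str  # "static_reference" | "temporal_median"
    background: np.ndarray
    source: str = ""


@dataclass
class DriftReport:
    """Per-frame rigid-translation estimates against the background.

    ``passed`` is True iff the largest drift magnitude is within
    ``threshold_px``; a failing report means background subtraction is
    unreliable and the run should be excluded from rate measurement.
    """

    dx_px: np.ndarray  # per-frame x translation of the frame vs background
    dy_px: np.ndarray
    threshold_px: float

    @property
    def magnitude_px(self) -> np.ndarray:
        return np.hypot(self.dx_px, self.dy_px)

    @property
    def max_drift_px(self) -> float:
        return float(self.magnitude_px.max())

    @property
    def passed(self) -> bool:
        return self.max_drift_px <= self.threshold_px

    def to_dict(self) -> dict:
        return {
            "dx_px": self.dx_px.tolist(),
            "dy_px": self.dy_px.tolist(),
            "max_drift_px": self.max_drift_px,
            "threshold_px": self.threshold_px,
            "passed": self.passed,
        }


def flat_field_correct(
    seq: ImageSequence, flat: np.ndarray, dark: np.ndarray | float = 0.0
) -> ImageSequence:
    """Normalize beam nonuniformity: each frame -> (frame - dark)/(flat - dark).

    ``flat`` is a sample-free beam image, ``dark`` a shutter-closed offset
    (scalar or raster). ``flat - dark`` must be strictly positive.
    """
    dark_arr = np.asarray(dark, dtype=np.float64)
    flat_arr = np.asarray(flat, dtype=np.float64)
    if flat_arr.shape != seq.shape:
        raise ValueError(f"flat shape {flat_arr.shape} != frame shape {seq.shape}")
    if dark_arr.ndim and dark_arr.shape != seq.shape:
        raise ValueError(f"dark shape {dark_arr.shape} != frame shape {seq.shape}")
    denom = flat_arr - dark_arr
    if np.any(denom <= 0):
        idx = np.argwhere(denom <= 0)[0]
        raise ValueError(
            f"flat - dark is nonpositive at pixel (row={idx[0]}, col={idx[1]})"
        )
    frames = [
        ((np.asarray(f, dtype=np.float64) - dark_arr) / denom).astype(np.float32)
        for f in seq.frames
    ]
    return ImageSequence(frames, seq.pixel_size_um, seq.frame_interval_s, seq.id)


def build_background(
    seq: ImageSequence | None = None,
    mode: str = "temporal_median",
    reference: np.ndarray | None = None,
) -> BackgroundModel:
    """Build a background model from a reference frame or the run itself.

    ``static_reference`` wraps a supplied particle-free frame (e.g. captured
    before particle delivery).  ``temporal_median`` takes the per-pixel
    median over >= 3 frames.
    """
    if mode == "static_reference":
        if reference is None:
            raise ValueError("static_reference mode requires a reference frame")
        bg = np.asarray(reference, dtype=np.float64)
        if seq is not None and bg.shape != seq.shape:
            raise ValueError(f"reference shape {bg.shape} != frame shape {seq.shape}")
        return BackgroundModel("static_reference", bg, source="supplied reference frame")
    if mode == "temporal_median":
        if seq is None:
            raise ValueError("temporal_median mode requires a sequence")
        if len(seq) < 3:
            raise ValueError(
                f"temporal_median needs >= 3 frames, got {len(seq)}"
            )
        stack = np.stack([np.asarray(f, dtype=np.float64) for f in seq.frames])
        bg = np.median(stack, axis=0)
        return BackgroundModel("temporal_median", bg, source=f"median of {len(seq)} frames")
    raise ValueError(f"unknown background mode {mode!r}")


def subtract_background(seq: ImageSequence, model: BackgroundModel) -> ImageSequence:
    """Residual sequence ``background - frame``: beads become positive peaks."""
    bg = model.background
    if bg.shape != seq.shape:
        raise ValueError(f"background shape {bg.shape} != frame shape {seq.shape}")
    frames = [(bg - np.asarray(f, dtype=np.float64)).astype(np.float32) for f in seq.frames]
    return ImageSequence(frames, seq.pixel_size_um, seq.frame_interval_s, seq.id)


def subtract_background_frame(frame: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Single-frame residual (streaming variant of :func:`subtract_background`)."""
    if model.background.shape != frame.shape:
        raise ValueError("background/frame shape mismatch")
    return (model.background - np.asarray(frame, dtype=np.float64)).astype(np.float32)


def estimate_translation(frame: np.ndarray, background: np.ndarray) -> tuple[float, float]:
    """Estimate the rigid (dx, dy) translation of frame content relative to
    the background raster by upsampled cross-correlation (subpixel)."""
    shift, _, _ = phase_cross_correlation(
        np.asarray(background, dtype=np.float64),
        np.asarray(frame, dtype=np.float64),
        upsample_factor=20,
        normalization=None,
    )
    # phase_cross_correlation returns the (row, col) shift to apply to the
    # moving image to register it onto the reference; the frame content is
    # therefore displaced by the negative of that.
    return float(-shift[1]), float(-shift[0])


def assess_drift(
    seq: ImageSequence, model: BackgroundModel, drift_threshold_px: float = 5.0
) -> DriftReport:
    """Estimate per-frame tissue drift and flag runs unfit for subtraction.

    Beads occupy a tiny fraction of the field, so the correlation is
    dominated by the anatomical background. A featureless (constant)
    background makes translation unidentifiable and is an error.
    """
    if len(seq) < 2:
        raise ValueError("drift assessment needs a sequence of length >= 2")
    if drift_threshold_px <= 0:
        raise ValueError("drift_threshold_px must be > 0")
    bg = np.asarray(model.background, dtype=np.float64)
    if bg.std() < 1e-12 * (abs(bg.mean()) + 1):
        raise ValueError("background is featureless: drift is unidentifiable")
    dx = np.empty(len(seq))
    dy = np.empty(len(seq))
    for i, frame in enumerate(seq.frames):
        dx[i], dy[i] = estimate_translation(frame, bg)
    return DriftReport(dx_px=dx, dy_px=dy, threshold_px=drift_threshold_px)
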