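"""Physical velocities and transport summaries from track tables.

Conventions
-----------
Image y increases downward, but transport is reported in an "up-image =
cranial" frame: ``vy = -Δy·scale`` so upward motion is positive.  The
transport angle is measured from vertical-up, signed positive toward
image-right: ``angle = atan2(vx, vy)`` in degrees.  A stationary step has
angle 0 by convention and is flagged degenerate.

The headline statistic — the mean instantaneous transport rate — is the
mean of per-step speeds pooled over *all* velocity samples (not per-track
means averaged): slow and stationary particles weigh the mean down by
design.  The mean transport direction is the resultant (vector-sum) angle,
which is well defined on the circle; the arithmetic mean of sample angles
is reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VELOCITY_COLUMNS",
    "RunSummary",
    "HeatMap",
    "track_velocities",
    "resultant_angle_deg",
    "run_summary",
    "velocity_heatmap",
    "treatment_response",
]

VELOCITY_COLUMNS = [
    "track_id", "time_s", "vx_mm_min", "vy_mm_min",
    "speed_mm_min", "angle_deg", "frame_step", "gap_flag", "degenerate",
]


def track_velocities(
    tracks: pd.DataFrame,
    pixel_size_um: float,
    frame_interval_s: float,
    include_gap_spans: bool = True,
) -> pd.DataFrame:
    """One velocity sample per consecutive observation pair on each track.

    For a pair spanning ``g`` frames, ``v = Δposition · pixel_size · 60 /
    (g · frame_interval · 1000)`` mm/min — a gap-spanning sample is the
    average velocity over the gap and carries ``gap_flag`` (excluded
    entirely when ``include_gap_spans`` is False).  ``time_s`` is the
    mid-point of the pair.
    """
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("calibration must be > 0")
    if len(tracks) == 0:
        return pd.DataFrame(columns=VELOCITY_COLUMNS)
    scale = pixel_size_um * 60.0 / 1000.0  # px/frame-interval -> mm/min numerator
    t = tracks.sort_values(["track_id", "frame_index"], kind="mergesort")
    tid = t["track_id"].to_numpy()
    fr = t["frame_index"].to_numpy(dtype=float)
    x = t["x_px"].to_numpy(dtype=float)
    y = t["y_px"].to_numpy(dtype=float)
    same = tid[1:] == tid[:-1]
    g = (fr[1:] - fr[:-1])[same]
    dx = (x[1:] - x[:-1])[same]
    dy = (y[1:] - y[:-1])[same]
    mid_t = ((fr[1:] + fr[:-1]) / 2.0)[same] * frame_interval_s
    vx = dx * scale / (g * frame_interval_s)
    vy = -dy * scale / (g * frame_interval_s)
    speed = np.hypot(vx, vy)
    degenerate = speed == 0
    angle = np.where(degenerate, 0.0, np.degrees(np.arctan2(vx, vy)))
    out = pd.DataFrame({
        "track_id": tid[1:][same],
        "time_s": mid_t,
        "vx_mm_min": vx,
        "vy_mm_min": vy,
        "speed_mm_min": speed,
        "angle_deg": angle,
        "frame_step": g.astype(int),
        "gap_flag": g > 1,
        "degenerate": degenerate,
    })
    if not include_gap_spans:
        out = out[~out["gap_flag"]].reset_index(drop=True)
    return out


def resultant_angle_deg(vx: np.ndarray, vy: np.ndarray) -> float:
    """Angle of the vector-sum velocity, degrees from vertical-up."""
    sx, sy = float(np.sum(vx)), float(np.sum(vy))
    if sx == 0 and sy == 0:
        return 0.0
    return float(np.degrees(np.arctan2(sx, sy)))


@dataclass
class RunSummary:
    """Pooled rate and direction statistics for one run."""

    n_samples: int
    mean_speed_mm_min: float
    sd_speed_mm_min: float
    resultant_angle_deg: float
    arithmetic_mean_angle_deg: float
    time_bins: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: bin_start_s, bin_end_s, mean_speed_mm_min, sd_speed_mm_min, n

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "mean_speed_mm_min": self.mean_speed_mm_min,
            "sd_speed_mm_min": self.sd_speed_mm_min,
            "resultant_angle_deg": self.resultant_angle_deg,
            "arithmetic_mean_angle_deg": self.arithmetic_mean_angle_deg,
            "time_bins": self.time_bins.to_dict(orient="records"),
        }


def _binned_stats(samples: pd.DataFrame, edges: np.ndarray) -> pd.DataFrame:
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = samples[(samples["time_s"] >= lo) & (samples["time_s"] < hi)]
        if len(sel) == 0:
            continue
        sp = sel["speed_mm_min"]
        rows.append({
            "bin_start_s": float(lo),
            "bin_end_s": float(hi),
            "mean_speed_mm_min": float(sp.mean()),
            "sd_speed_mm_min": float(sp.std(ddof=1)) if len(sp) > 1 else 0.0,
            "n": int(len(sp)),
        })
    return pd.DataFrame(rows)


def run_summary(samples: pd.DataFrame, time_bin_s: float | None = None) -> RunSummary:
    """Pooled mean ± SD of speed, resultant angle, optional time bins."""
    if len(samples) == 0:
        raise ValueError("run_summary needs at least one velocity sample")
    sp = samples["speed_mm_min"]
    n = len(sp)
    bins = pd.DataFrame()
    if time_bin_s is not None:
        if time_bin_s <= 0:
            raise ValueError("time_bin_s must be > 0")
        t0, t1 = samples["time_s"].min(), samples["time_s"].max()
        edges = np.arange(np.floor(t0 / time_bin_s) * time_bin_s,
                          t1 + time_bin_s, time_bin_s)
        bins = _binned_stats(samples, edges)
    return RunSummary(
        n_samples=n,
        mean_speed_mm_min=float(sp.mean()),
        sd_speed_mm_min=float(sp.std(ddof=1)) if n > 1 else 0.0,
        resultant_angle_deg=resultant_angle_deg(
            samples["vx_mm_min"].to_numpy(), samples["vy_mm_min"].to_numpy()
        ),
        arithmetic_mean_angle_deg=float(samples["angle_deg"].mean()),
        time_bins=bins,
    )


@dataclass
class HeatMap:
    """2D histogram of velocity samples over (vx, vy) bins.

    Displayed with vy increasing upward (cranial at the top), matching the
    screen orientation of the images themselves: stationary particles sit
    at the origin, faster particles farther out, angular position giving
    the direction of motion.
    """

    counts: np.ndarray       # shape (n_vy_bins, n_vx_bins), row 0 = lowest vy
    vx_edges: np.ndarray
    vy_edges: np.ndarray
    n_out_of_range: int

    def total_in_range(self) -> int:
        return int(self.counts.sum())

    def resultant_angle_deg(self) -> float:
        """Resultant direction recomputed from bin centres (count-weighted)."""
        cx = (self.vx_edges[:-1] + self.vx_edges[1:]) / 2
        cy = (self.vy_edges[:-1] + self.vy_edges[1:]) / 2
        vxs = (self.counts * cx[None, :]).sum()
        vys = (self.counts * cy[:, None]).sum()
        return float(np.degrees(np.arctan2(vxs, vys)))


def velocity_heatmap(
    samples: pd.DataFrame,
    bin_width_mm_min: float = 0.25,
    extent_mm_min: float = 6.0,
) -> HeatMap:
    """Bin (vx, vy) samples into a square 2D histogram of half-width
    ``extent_mm_min``; samples outside the extent are counted separately."""
    if bin_width_mm_min <= 0 or extent_mm_min <= 0:
        raise ValueError("bin width and extent must be > 0")
    n = int(np.ceil(2 * extent_mm_min / bin_width_mm_min))
    edges = -extent_mm_min + bin_width_mm_min * np.arange(n + 1)
    vx = samples["vx_mm_min"].to_numpy()
    vy = samples["vy_mm_min"].to_numpy()
    inside = (vx >= edges[0]) & (vx < edges[-1]) & (vy >= edges[0]) & (vy < edges[-1])
    counts, _, _ = np.histogram2d(vy[inside], vx[inside], bins=[edges, edges])
    return HeatMap(
        counts=counts,
        vx_edges=edges.copy(),
        vy_edges=edges.copy(),
        n_out_of_range=int((~inside).sum()),
    )


def treatment_response(
    samples: pd.DataFrame,
    treatment_start_s: float,
    bin_s: float = 60.0,
) -> pd.DataFrame:
    """Time-course of the mean rate around a treatment.

    Bins are aligned so one edge falls exactly at ``treatment_start_s``;
    the first post bin therefore includes the delivery time itself (some
    particles respond within the delivery window).  Returns bin_start_s,
    bin_end_s, label (baseline/post), mean, SD, n, with at least one
    baseline bin required.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    if len(samples) == 0:
        raise ValueError("no velocity samples")
    t = samples["time_s"]
    if not (t < treatment_start_s).any():
        raise ValueError("no pre-treatment samples: cannot form a baseline")
    n_pre = int(np.ceil((treatment_start_s - t.min()) / bin_s))
    n_post = max(int(np.ceil((t.max() - treatment_start_s) / bin_s)), 0)
    edges = treatment_start_s + bin_s * np.arange(-n_pre, n_post + 1)
    out = _binned_stats(samples, edges)
    out["label"] = np.where(out["bin_start_s"] < treatment_start_s, "baseline", "post")
    return out
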