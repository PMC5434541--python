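"""Scoring detections and tracks against ground truth.

Uses the TP/FP/FN sensitivity framework: per frame, detections are matched
one-to-one to true particle positions within a radius (default one bead
diameter — a detection farther than its own diameter from every truth is
not the same object); unmatched detections are false positives, unmatched
truths false negatives, and sensitivity = TP / (TP + FN).

Detection-level sensitivity and track-level observation recall are scored
separately: a particle can be detected in a frame yet lost by the linker,
and the two failure modes have different fixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ValidationReport",
    "match_to_truth",
    "sensitivity_report",
    "track_observation_recall",
]

_FORBIDDEN = 1e9


def match_to_truth(
    det_xy: np.ndarray, truth_xy: np.ndarray, radius_px: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one matching minimizing total distance within a radius.

    Returns (pairs, fp_indices, fn_indices): ``pairs`` are (detection,
    truth) index pairs; unmatched detections are FPs, unmatched truths FNs.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    det_xy = np.atleast_2d(np.asarray(det_xy, dtype=float)) if len(det_xy) else np.empty((0, 2))
    truth_xy = np.atleast_2d(np.asarray(truth_xy, dtype=float)) if len(truth_xy) else np.empty((0, 2))
    nd, nt = len(det_xy), len(truth_xy)
    if nd == 0 or nt == 0:
        return [], list(range(nd)), list(range(nt))
    d = np.sqrt(
        (det_xy[:, 0:1] - truth_xy[None, :, 0]) ** 2
        + (det_xy[:, 1:2] - truth_xy[None, :, 1]) ** 2
    )
    cost = np.where(d <= radius_px, d, _FORBIDDEN)
    ri, ci = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if cost[i, j] < _FORBIDDEN]
    matched_d = {i for i, _ in pairs}
    matched_t = {j for _, j in pairs}
    fp = [i for i in range(nd) if i not in matched_d]
    fn = [j for j in range(nt) if j not in matched_t]
    return pairs, fp, fn


@dataclass
class ValidationReport:
    """Pooled and per-frame TP/FP/FN counts with derived rates."""

    tp: int
    fp: int
    fn: int
    radius_px: float
    per_frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: frame_index, tp, fp, fn, sensitivity

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ValueError("sensitivity undefined: no truth objects scored")
        return self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            raise ValueError("precision undefined: no detections scored")
        return self.tp / (self.tp + self.fp)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity if self.tp + self.fn else None,
            "precision": self.precision if self.tp + self.fp else None,
            "radius_px": self.radius_px,
            "per_frame": self.per_frame.to_dict(orient="records"),
        }


def sensitivity_report(
    detections: pd.DataFrame,
    truth_positions: pd.DataFrame,
    radius_px: float = 6.4,
    frames: list[int] | None = None,
) -> ValidationReport:
    """Score a detection table against true per-frame positions.

    ``truth_positions`` needs particle_id, frame_index, x_px, y_px (the
    ground-truth table of a phantom, or a manual annotation table in the
    same schema).  ``frames`` restricts scoring, e.g. ``[0]`` scores the
    first frame only as done for manual validation.
    """
    if frames is None:
        frames = sorted(set(truth_positions["frame_index"].astype(int)))
    if not frames:
        raise ValueError("no frames to score")
    rows = []
    tp = fp = fn = 0
    for f in frames:
        d = detections[detections["frame_index"] == f]
        t = truth_positions[truth_positions["frame_index"] == f]
        pairs, fps, fns = match_to_truth(
            d[["x_px", "y_px"]].to_numpy(), t[["x_px", "y_px"]].to_numpy(), radius_px
        )
        ftp, ffp, ffn = len(pairs), len(fps), len(fns)
        tp, fp, fn = tp + ftp, fp + ffp, fn + ffn
        rows.append({
            "frame_index": f, "tp": ftp, "fp": ffp, "fn": ffn,
            "sensitivity": ftp / (ftp + ffn) if ftp + ffn else np.nan,
        })
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no truth objects in scored frames")
    return ValidationReport(tp=tp, fp=fp, fn=fn, radius_px=radius_px,
                            per_frame=pd.DataFrame(rows))


def track_observation_recall(
    tracks: pd.DataFrame,
    truth_positions: pd.DataFrame,
    radius_px: float = 6.4,
) -> dict:
    """Fraction of true (particle, frame) observations recovered by tracks.

    Each track observation is matched one-to-one to a truth observation in
    its frame (within ``radius_px``); a track's identity is the majority
    truth particle over its matched observations.  Reports overall recall
    and, per particle, the coverage of its best single track — a particle
    followed by one unbroken track has best_single_track_coverage 1.0.
    """
    total_truth = len(truth_positions)
    if total_truth == 0:
        raise ValueError("empty ground truth")
    matched_rows = []  # (track_id, particle_id, frame_index)
    for f, tgrp in truth_positions.groupby("frame_index"):
        d = tracks[tracks["frame_index"] == f]
        if len(d) == 0:
            continue
        pairs, _, _ = match_to_truth(
            d[["x_px", "y_px"]].to_numpy(), tgrp[["x_px", "y_px"]].to_numpy(), radius_px
        )
        for di, ti in pairs:
            matched_rows.append((
                int(d["track_id"].iloc[di]),
                int(tgrp["particle_id"].iloc[ti]),
                int(f),
            ))
    m = pd.DataFrame(matched_rows, columns=["track_id", "particle_id", "frame_index"])
    recall = len(m) / total_truth
    per_particle = {}
    truth_counts = truth_positions.groupby("particle_id").size()
    if len(m):
        cov = m.groupby(["particle_id", "track_id"]).size()
        for pid, n_true in truth_counts.items():
            if pid in cov.index.get_level_values(0):
                best = cov.loc[pid].max()
            else:
                best = 0
            per_particle[int(pid)] = float(best / n_true)
    else:
        per_particle = {int(pid): 0.0 for pid in truth_counts.index}
    return {
        "observation_recall": float(recall),
        "n_matched": int(len(m)),
        "n_truth": int(total_truth),
        "best_single_track_coverage": per_particle,
        "radius_px": radius_px,
    }
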