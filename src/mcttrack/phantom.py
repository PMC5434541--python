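"""Synthetic phantom sequences with known particle trajectories.

The generator emulates a 2D absorption-contrast view of an excised tracheal
segment mounted vertically: a textured cartilage-band background under a
nonuniform beam profile, dark ~100 μm glass-bead marker particles moving
predominantly up the image (the cranial clearance direction) at a few
mm/min, optional bead "strings" (aggregates sharing one path), stationary
bubble-like ring confounders, additive Gaussian noise, and optional rigid
whole-field drift.  Every rendered bead centre is recorded in a ground-truth
table, so detection, linking and kinematics can all be validated end to end.

Two background styles are provided: ``sheep_smooth`` (broad, smooth
cartilage bands) and ``pig_dense`` (the same plus high-frequency speckle
whose local contrast approaches the bead contrast, which is what makes
detection harder on dense cartilage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .sequence_io import ImageSequence

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "PhantomResult",
    "generate_background",
    "generate_phantom",
    "treatment_phantom",
    "sheep_preset",
    "pig_preset",
]

#: Base (particle-free, beam-free) transmitted intensity, arbitrary units.
_BASE_LEVEL = 0.75


@dataclass
class PhantomParams:
    """Parameters of one synthetic imaging run.

    Defaults describe a sheep-like run: full ~16.6 × 14 mm field at
    16 μm/px, 103 μm beads, a 2.4 s frame cadence (so a 15 px linking gate
    corresponds to a 6 mm/min speed ceiling), and a log-normal speed
    distribution whose mean is ~1.6 mm/min.

    Speeds are log-normal: ``speed = speed_median_mm_min * exp(shape * Z)``
    with standard-normal ``Z``, so the mean is
    ``median * exp(shape**2 / 2)``.  Headings are normal with mean
    ``heading_mean_deg`` (degrees from vertical "up"; positive toward
    image-right) and SD ``heading_sd_deg``, drawn once per particle.
    """

    shape: tuple[int, int] = (874, 1036)
    pixel_size_um: float = 16.0
    frame_interval_s: float = 2.4
    n_frames: int = 150
    n_particles: int = 50
    bead_diameter_um: float = 103.0
    bead_contrast: float = 0.3
    speed_median_mm_min: float = 1.3364
    speed_shape: float = 0.6
    heading_mean_deg: float = -14.3
    heading_sd_deg: float = 20.0
    aggregate_fraction: float = 0.0
    aggregate_size: int = 4
    n_bubbles: int = 0
    background_style: str = "sheep_smooth"
    beam_amplitude: float = 0.15
    band_amplitude: float = 0.08
    speckle_amplitude: float = 0.15
    noise_sd: float = 0.01
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    respawn: bool = True
    heading_jitter_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_particles < 0 or self.n_bubbles < 0:
            raise ValueError("counts must be >= 0 (and n_frames >= 1)")
        if self.bead_diameter_um / self.pixel_size_um < 2:
            raise ValueError("bead must span at least 2 pixels")
        if not (0 < self.bead_contrast < 1):
            raise ValueError("bead_contrast must be in (0, 1)")
        if self.background_style not in ("sheep_smooth", "pig_dense"):
            raise ValueError(f"unknown background style {self.background_style!r}")
        if not (0 <= self.aggregate_fraction <= 1):
            raise ValueError("aggregate_fraction must be in [0, 1]")

    @property
    def bead_radius_px(self) -> float:
        return self.bead_diameter_um / self.pixel_size_um / 2.0

    def speed_mean_mm_min(self) -> float:
        """Mean of the log-normal speed distribution (closed form)."""
        return self.speed_median_mm_min * math.exp(self.speed_shape**2 / 2)


@dataclass
class GroundTruth:
    """True per-frame particle positions and per-particle kinematics.

    ``positions`` has one row per in-field (particle_id, frame) pair with
    the true centre in pixels and the instantaneous speed in mm/min;
    ``particles`` one row per particle with its base speed, heading, and
    whether it exited the field during the run.
    """

    positions: pd.DataFrame  # particle_id, frame_index, x_px, y_px, speed_mm_min
    particles: pd.DataFrame  # particle_id, speed_mm_min, heading_deg, aggregate_id, exited

    def at_frame(self, frame_index: int) -> pd.DataFrame:
        return self.positions[self.positions["frame_index"] == frame_index]

    def n_particles(self) -> int:
        return len(self.particles)


@dataclass
class PhantomResult:
    """A rendered phantom: the sequence, its ground truth, and the clean
    particle-free background (the analogue of a pre-delivery reference
    frame captured for background subtraction)."""

    sequence: ImageSequence
    truth: GroundTruth
    background: np.ndarray

    def __iter__(self):  # allow (seq, truth) / (seq, truth, bg) unpacking
        return iter((self.sequence, self.truth, self.background))


def sheep_preset(**overrides) -> PhantomParams:
    """Sheep-like run: smooth bands, 2.4 s cadence, ~1.6 mm/min mean rate."""
    return replace(PhantomParams(), **overrides)


def pig_preset(**overrides) -> PhantomParams:
    """Pig-like run: dense speckled cartilage, 0.6 s cadence (24 mm/min
    ceiling at the 15 px gate), ~1.32 mm/min mean rate."""
    base = PhantomParams(
        frame_interval_s=0.6,
        background_style="pig_dense",
        heading_mean_deg=28.3,
        speed_median_mm_min=1.1026,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# background


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-SD band-limited noise field."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _background_raster(params: PhantomParams, seed: int, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # Horizontal cartilage bands: ~3 rings per field, with a slowly varying
    # phase so the bands are not perfectly straight.
    band_period = h / 3.5
    phase = 2 * np.pi * 0.15 * _smooth_noise(rng, (1, w), sigma=w / 8)
    bands = params.band_amplitude * np.sin(2 * np.pi * yy / band_period + phase)

    # Low-frequency 2D tissue mottle (tied to band amplitude so an all-zero
    # structure request yields a constant raster).
    mottle = 0.4 * params.band_amplitude * _smooth_noise(rng, (h, w), sigma=8.0)

    texture = bands + mottle
    if params.background_style == "pig_dense":
        # High-frequency speckle with local contrast on the order of the
        # bead contrast — features of similar appearance to the beads.
        speckle = params.speckle_amplitude * _smooth_noise(rng, (h, w), sigma=1.2)
        texture = texture + speckle

    base = _BASE_LEVEL * (1.0 + texture)

    # Nonuniform beam: smooth radial falloff from the field centre.
    if params.beam_amplitude != 0:
        r2 = ((yy - (h - 1) / 2) / (h / 2)) ** 2 + ((xx - (w - 1) / 2) / (w / 2)) ** 2
        beam = 1.0 - params.beam_amplitude * r2 / 2.0
    else:
        beam = 1.0
    return (base * beam).astype(np.float64)


def generate_background(params: PhantomParams, seed: int | None = None) -> np.ndarray:
    """Render the particle-free tissue background (deterministic per seed)."""
    if seed is None:
        seed = params.seed
    return _background_raster(params, seed, params.shape)


# ---------------------------------------------------------------------------
# bead and bubble rendering


def _render_bead(frame: np.ndarray, x: float, y: float, radius_px: float, contrast: float) -> None:
    """Multiply a radially smooth dark disc into ``frame`` at (x, y).

    Profile is ``0.5 * (1 - tanh((r - R) / w))``: ≈1 inside the bead, 0
    outside, with a ~1 px soft edge, so the intensity minimum sits at the
    disc centre and centroids are meaningful at subpixel scale.
    """
    w = max(0.5, 0.18 * radius_px)
    half = int(math.ceil(radius_px + 4 * w)) + 1
    h, wid = frame.shape
    x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
    y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, wid)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    r = np.hypot(xx - x, yy - y)
    prof = 0.5 * (1.0 - np.tanh((r - radius_px) / w))
    frame[y0c:y1c, x0c:x1c] *= 1.0 - contrast * prof


def _render_bubble(frame: np.ndarray, x: float, y: float, r_out: float, r_in: float, contrast: float) -> None:
    """Dark annulus (air-bubble edge) — static confounder."""
    half = int(math.ceil(r_out)) + 3
    h, wid = frame.shape
    x0c, x1c = max(int(x) - half, 0), min(int(x) + half + 1, wid)
    y0c, y1c = max(int(y) - half, 0), min(int(y) + half + 1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    r = np.hypot(xx - x, yy - y)
    ring = 0.5 * (1 - np.tanh((r - r_out) / 0.7)) * 0.5 * (1 + np.tanh((r - r_in) / 0.7))
    frame[y0c:y1c, x0c:x1c] *= 1.0 - contrast * ring


# ---------------------------------------------------------------------------
# trajectories


class _ParticleState:
    __slots__ = ("pid", "x", "y", "speed", "heading", "aggregate_id", "exited")

    def __init__(self, pid, x, y, speed, heading, aggregate_id):
        self.pid = pid
        self.x = x
        self.y = y
        self.speed = speed  # base speed, mm/min
        self.heading = heading  # deg from vertical-up, +ve toward image right
        self.aggregate_id = aggregate_id
        self.exited = False


def _draw_particle(rng: np.random.Generator, params: PhantomParams, pid: int, spawn_bottom: bool) -> _ParticleState:
    h, w = params.shape
    margin = params.bead_radius_px + 2
    x = rng.uniform(margin, w - margin)
    if spawn_bottom:
        y = rng.uniform(h - margin - 10, h - margin)
    else:
        y = rng.uniform(margin, h - margin)
    speed = params.speed_median_mm_min * math.exp(params.speed_shape * rng.standard_normal())
    heading = rng.normal(params.heading_mean_deg, params.heading_sd_deg)
    return _ParticleState(pid, x, y, speed, heading, aggregate_id=-1)


def _speed_modifier_none(t: float) -> float:
    return 1.0


def _generate(params: PhantomParams, speed_modifier: Callable[[float], float]) -> PhantomResult:
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    margin = params.bead_radius_px + 2
    if w <= 2 * margin or h <= 2 * margin + 10:
        raise ValueError("image too small: particle spawn region is empty")

    # clean background, possibly padded for drift
    drift = np.asarray(params.drift_px_per_frame, dtype=float)
    total_drift = drift * (params.n_frames - 1)
    pad = int(math.ceil(np.abs(total_drift).max())) + 2 if np.any(drift) else 0
    bg_seed = params.seed
    background = _background_raster(params, bg_seed, (h + 2 * pad, w + 2 * pad))
    clean_background = background[pad : pad + h, pad : pad + w].copy()

    # static bubbles: on the tissue (drift with it), absent from the clean
    # reference background so they survive subtraction as static features
    scene = background.copy()
    for _ in range(params.n_bubbles):
        bx = rng.uniform(margin, w - margin) + pad
        by = rng.uniform(margin, h - margin) + pad
        _render_bubble(scene, bx, by, r_out=4.0, r_in=2.0, contrast=0.8 * params.bead_contrast)

    # particles
    particles: list[_ParticleState] = []
    next_pid = 0
    for _ in range(params.n_particles):
        p = _draw_particle(rng, params, next_pid, spawn_bottom=False)
        particles.append(p)
        next_pid += 1

    # aggregate some of them into strings sharing a path
    n_agg = int(round(params.aggregate_fraction * params.n_particles))
    agg_id = 0
    i = 0
    while i + 1 < n_agg:
        size = min(params.aggregate_size, n_agg - i)
        leader = particles[i]
        leader.aggregate_id = agg_id
        spacing = 2 * params.bead_radius_px + 0.8
        th = math.radians(leader.heading)
        ux, uy = math.sin(th), -math.cos(th)  # unit along-path (up-image)
        for k in range(1, size):
            m = particles[i + k]
            m.aggregate_id = agg_id
            m.speed = leader.speed
            m.heading = leader.heading
            lateral = rng.normal(0.0, 0.6)
            m.x = leader.x - k * spacing * ux - lateral * uy
            m.y = leader.y - k * spacing * uy + lateral * ux
        i += size
        agg_id += 1

    dt_min = params.frame_interval_s / 60.0  # minutes per frame
    px_per_mm = 1000.0 / params.pixel_size_um

    pos_rows: list[tuple] = []
    frames: list[np.ndarray] = []
    record: dict[int, _ParticleState] = {}

    for k in range(params.n_frames):
        t = k * params.frame_interval_s
        off = drift * k  # (dx, dy) of tissue content at this frame
        if pad:
            shifted = ndimage.shift(scene, shift=(off[1], off[0]), order=1, mode="nearest")
            frame = shifted[pad : pad + h, pad : pad + w].copy()
        else:
            frame = scene.copy()

        mod = speed_modifier(t)
        active = [p for p in particles if not p.exited]
        for p in active:
            x, y = p.x + off[0], p.y + off[1]
            _render_bead(frame, x, y, params.bead_radius_px, params.bead_contrast)
            record.setdefault(p.pid, p)
            pos_rows.append((p.pid, k, x, y, p.speed * mod))

        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        frames.append(frame.astype(np.float32))

        # advance to next frame
        if k == params.n_frames - 1:
            break
        step_px = px_per_mm * dt_min * mod
        respawned: list[_ParticleState] = []
        for p in particles:
            if p.exited:
                continue
            heading = p.heading
            if params.heading_jitter_sd_deg > 0:
                heading = heading + rng.normal(0.0, params.heading_jitter_sd_deg)
            th = math.radians(heading)
            p.x += p.speed * step_px * math.sin(th)
            p.y -= p.speed * step_px * math.cos(th)
            if not (margin <= p.x <= w - margin and margin <= p.y <= h - margin):
                p.exited = True
                if params.respawn:
                    newp = _draw_particle(rng, params, next_pid, spawn_bottom=True)
                    next_pid += 1
                    respawned.append(newp)
        particles.extend(respawned)

    positions = pd.DataFrame(
        pos_rows, columns=["particle_id", "frame_index", "x_px", "y_px", "speed_mm_min"]
    )
    part_rows = [
        (p.pid, p.speed, p.heading, p.aggregate_id, p.exited)
        for p in sorted(record.values(), key=lambda q: q.pid)
    ]
    particles_df = pd.DataFrame(
        part_rows, columns=["particle_id", "speed_mm_min", "heading_deg", "aggregate_id", "exited"]
    )
    seq = ImageSequence(
        frames=frames,
        pixel_size_um=params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        id=f"phantom-{params.background_style}-seed{params.seed}",
    )
    return PhantomResult(seq, GroundTruth(positions, particles_df), clean_background.astype(np.float32))


def generate_phantom(params: PhantomParams) -> PhantomResult:
    """Render a constant-speed phantom run with matching ground truth.

    Deterministic for fixed params (all randomness from ``params.seed``).
    Ground-truth centres equal the rendered bead centres exactly (noise is
    added after rendering).
    """
    return _generate(params, _speed_modifier_none)


def treatment_phantom(
    params: PhantomParams,
    boost_factor: float,
    boost_start_s: float,
    decay_s: float,
) -> PhantomResult:
    """Phantom with a transient speed boost after aerosol-like treatment.

    For t >= boost_start_s every particle's speed is multiplied by
    ``1 + (boost_factor - 1) * exp(-(t - boost_start_s) / decay_s)``; the
    ground truth records the time-varying instantaneous speeds.  With
    ``boost_factor == 1`` trajectories are identical to
    :func:`generate_phantom` at the same seed.
    """
    if boost_factor < 1:
        raise ValueError("boost_factor must be >= 1")
    if decay_s <= 0:
        raise ValueError("decay_s must be > 0")

    def modifier(t: float) -> float:
        if t < boost_start_s:
            return 1.0
        return 1.0 + (boost_factor - 1.0) * math.exp(-(t - boost_start_s) / decay_s)

    return _generate(params, modifier)
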