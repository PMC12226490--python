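"""Synthetic two-animal pose sessions with known ground truth.

The generator emulates the statistical structure of a top-view recording of
two mice in a rectangular arena:

- Each animal's centroid follows a reflected random walk whose step has an
  isotropic Gaussian component (scale ``step_sd``, mm per frame) plus a
  cohesion term pulling toward (``attraction > 0``) or pushing away from
  (``attraction < 0``) the other animal.
- Five body-part labels (nose, ears, tail base, tail end) are placed on a
  rigid template oriented along the current heading; the template's mean is
  the centroid, so in the noise-free limit the pipeline centroid equals the
  ground-truth centroid exactly.  Isotropic Gaussian jitter of scale
  ``jitter_sd`` models pose-estimation error.
- Each label is independently occluded ("rejected") with a per-part
  probability; likelihoods are drawn Uniform(p_cutoff, 1) for accepted
  labels and Uniform(0, p_cutoff) for rejected ones, so the sub-cutoff
  probability is exactly the configured rate.  An episodic mode draws
  geometric occlusion run lengths instead (grooming/digging-like bouts),
  and occlusion rates can optionally increase beyond a distance threshold.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .trajectory_io import (
    BODY_PARTS,
    ArenaCalibration,
    PoseTrack,
    SessionMeta,
)

#: Gain (mm per frame) multiplying ``attraction`` in the cohesion term.
ATTRACTION_GAIN_MM = 2.0

#: Default per-part occlusion probabilities.  Ordering (nose highest, then
#: tail base, tail end, ears lowest) mirrors the rejection profile typical
#: of top-view tracking, where the nose is occluded during digging and
#: grooming and the ears are almost always visible.
DEFAULT_REJECTION_RATES: Mapping[str, float] = {
    "nose": 0.44,
    "left_ear": 0.11,
    "right_ear": 0.11,
    "tail_base": 0.32,
    "tail_end": 0.27,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated 2-mouse session.

    Defaults describe a 10-min, 30-fps session in a 300 x 200 mm arena
    with adult-mouse body length (80 mm nose to tail end), locomotion in
    the 100-200 mm/s range, and the default occlusion profile above.
    """

    seed: int = 0
    n_frames: int = 18_000
    fps: float = 30.0
    arena_w: float = 300.0
    arena_h: float = 200.0
    step_sd: float = 4.0
    attraction: float = 0.0
    body_length: float = 80.0
    rejection_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REJECTION_RATES)
    )
    jitter_sd: float = 1.5
    p_cutoff: float = 0.6
    mm_per_pixel: float = 0.68
    occlusion_mode: str = "iid"  # "iid" or "episodic"
    episode_mean_frames: float = 30.0
    distance_occlusion_threshold_mm: float | None = None
    distance_occlusion_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (self.arena_w > self.body_length > 0 and self.arena_h > self.body_length):
            raise ValueError("arena dimensions must exceed body_length, which must be > 0")
        if self.step_sd < 0 or self.jitter_sd < 0:
            raise ValueError("step_sd and jitter_sd must be >= 0")
        if not -1.0 <= self.attraction <= 1.0:
            raise ValueError("attraction must lie in [-1, 1]")
        missing = set(BODY_PARTS) - set(self.rejection_rates)
        if missing:
            raise ValueError(f"rejection_rates missing parts {sorted(missing)}")
        for part, rate in self.rejection_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rejection rate for {part} must lie in [0,1], got {rate}")
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.occlusion_mode not in ("iid", "episodic"):
            raise ValueError("occlusion_mode must be 'iid' or 'episodic'")
        if self.episode_mean_frames < 1:
            raise ValueError("episode_mean_frames must be >= 1")
        if self.distance_occlusion_factor < 0:
            raise ValueError("distance_occlusion_factor must be >= 0")


@dataclass
class GroundTruth:
    """Per-frame truth underlying a simulated session (all in mm)."""

    centroid_mm: np.ndarray  # (n_frames, 2 animals, 2)
    distance_mm: np.ndarray  # (n_frames,)
    rejected: np.ndarray  # (n_frames, 2, 5) bool
    likelihood: np.ndarray  # (n_frames, 2, 5)
    mean_speed_mm_s: np.ndarray  # (2,)


def _body_template(body_length: float) -> np.ndarray:
    """Rigid 5-point template in body coordinates (+x = heading), zero mean.

    Nose at the front, ears slightly behind and lateral, tail base and tail
    end behind; the nose-to-tail-end span equals ``body_length``.
    """
    L = body_length
    pts = np.array(
        [
            [0.45 * L, 0.0],  # nose
            [0.28 * L, 0.14 * L],  # left ear
            [0.28 * L, -0.14 * L],  # right ear
            [-0.15 * L, 0.0],  # tail base
            [-0.55 * L, 0.0],  # tail end
        ]
    )
    return pts - pts.mean(axis=0)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] by specular reflection."""
    period = 2.0 * (hi - lo)
    y = np.mod(x - lo, period)
    return lo + np.minimum(y, period - y)


def _simulate_centroids(cfg: SimConfig, rng: np.random.Generator):
    """Reflected biased random walk of both centroids; returns (pos, heading)."""
    template = _body_template(cfg.body_length)
    margin = float(np.abs(template).max()) + 1.0
    lo_x, hi_x = margin, cfg.arena_w - margin
    lo_y, hi_y = margin, cfg.arena_h - margin

    pos = np.empty((cfg.n_frames, 2, 2))
    pos[0, 0] = [lo_x + 0.25 * (hi_x - lo_x), 0.5 * (lo_y + hi_y)]
    pos[0, 1] = [lo_x + 0.75 * (hi_x - lo_x), 0.5 * (lo_y + hi_y)]
    noise = cfg.step_sd * rng.standard_normal((cfg.n_frames - 1, 2, 2))

    heading = np.empty((cfg.n_frames, 2))
    heading[0] = 0.0  # +x initial heading

    gain = cfg.attraction * ATTRACTION_GAIN_MM
    for t in range(1, cfg.n_frames):
        prev = pos[t - 1]
        sep = prev[1] - prev[0]
        norm = np.hypot(sep[0], sep[1])
        step = noise[t - 1].copy()
        if norm > 1e-12 and gain != 0.0:
            unit = sep / norm
            step[0] += gain * unit
            step[1] -= gain * unit
        nxt = prev + step
        nxt[:, 0] = _reflect(nxt[:, 0], lo_x, hi_x)
        nxt[:, 1] = _reflect(nxt[:, 1], lo_y, hi_y)
        pos[t] = nxt
        delta = nxt - prev
        moved = np.hypot(delta[:, 0], delta[:, 1]) > 1e-12
        heading[t] = np.where(moved, np.arctan2(delta[:, 1], delta[:, 0]), heading[t - 1])
    return pos, heading


def _draw_rejections(cfg: SimConfig, distance: np.ndarray, rng: np.random.Generator):
    """Per-label occlusion flags, (n_frames, 2, 5) bool."""
    rates = np.array([cfg.rejection_rates[p] for p in BODY_PARTS])
    # Per-frame rate matrix, optionally boosted at large separations.
    frame_rates = np.broadcast_to(rates, (cfg.n_frames, len(BODY_PARTS))).copy()
    if cfg.distance_occlusion_threshold_mm is not None:
        far = distance > cfg.distance_occlusion_threshold_mm
        frame_rates[far] = np.clip(frame_rates[far] * cfg.distance_occlusion_factor, 0, 1)

    if cfg.occlusion_mode == "iid":
        u = rng.random((cfg.n_frames, 2, len(BODY_PARTS)))
        return u < frame_rates[:, None, :]

    # Episodic: two-state Markov chain per label with stationary occupancy
    # equal to the target rate and mean occluded run length
    # episode_mean_frames.  p_exit = 1/mean_len; p_enter solves
    # rate = p_enter / (p_enter + p_exit).
    p_exit = 1.0 / cfg.episode_mean_frames
    with np.errstate(divide="ignore", invalid="ignore"):
        p_enter = np.where(
            frame_rates < 1.0, frame_rates * p_exit / (1.0 - frame_rates), 1.0
        )
    p_enter = np.clip(p_enter, 0.0, 1.0)
    rejected = np.empty((cfg.n_frames, 2, len(BODY_PARTS)), dtype=bool)
    u = rng.random((cfg.n_frames, 2, len(BODY_PARTS)))
    rejected[0] = u[0] < frame_rates[0][None, :]
    for t in range(1, cfg.n_frames):
        enter = u[t] < p_enter[t][None, :]
        stay = u[t] >= p_exit
        rejected[t] = np.where(rejected[t - 1], stay, enter)
    return rejected


def simulate_session(
    cfg: SimConfig, meta: SessionMeta | None = None
) -> tuple[PoseTrack, GroundTruth]:
    """Simulate one 2-mouse session; returns the pixel-space track and truth.

    The emitted :class:`PoseTrack` is in pixels (divide-by-scale of the mm
    simulation), ready for the same calibration step as a real recording.
    """
    rng = np.random.default_rng(cfg.seed)
    pos, heading = _simulate_centroids(cfg, rng)
    sep = pos[:, 1] - pos[:, 0]
    distance = np.hypot(sep[:, 0], sep[:, 1])

    template = _body_template(cfg.body_length)
    cos, sin = np.cos(heading), np.sin(heading)  # (n_frames, 2)
    # Rotate template into world frame per animal per frame.
    rot = np.empty((cfg.n_frames, 2, 2, 2))
    rot[..., 0, 0] = cos
    rot[..., 0, 1] = -sin
    rot[..., 1, 0] = sin
    rot[..., 1, 1] = cos
    labels_mm = pos[:, :, None, :] + np.einsum("faij,pj->fapi", rot, template)
    if cfg.jitter_sd > 0:
        labels_mm = labels_mm + cfg.jitter_sd * rng.standard_normal(labels_mm.shape)
    # Clip in pixel space so the *emitted* coordinates respect the arena
    # bounds exactly (the px/mm conversion would otherwise round past them).
    labels_px = labels_mm / cfg.mm_per_pixel
    labels_px[..., 0] = np.clip(labels_px[..., 0], 0.0, cfg.arena_w / cfg.mm_per_pixel)
    labels_px[..., 1] = np.clip(labels_px[..., 1], 0.0, cfg.arena_h / cfg.mm_per_pixel)

    rejected = _draw_rejections(cfg, distance, rng)
    u = rng.random(rejected.shape)
    likelihood = np.where(
        rejected, u * cfg.p_cutoff, cfg.p_cutoff + u * (1.0 - cfg.p_cutoff)
    )

    if cfg.n_frames > 1:
        steps = np.diff(pos, axis=0)
        speed = np.hypot(steps[..., 0], steps[..., 1]).mean(axis=0) * cfg.fps
    else:
        speed = np.zeros(2)

    if meta is None:
        meta = SessionMeta(
            session_id=f"sim-{cfg.seed}", strain="BTBR", sex="M", age_months=4.0
        )
    calibration = ArenaCalibration(
        mm_per_pixel=cfg.mm_per_pixel,
        fps=cfg.fps,
        image_width=int(np.ceil(cfg.arena_w / cfg.mm_per_pixel)),
        image_height=int(np.ceil(cfg.arena_h / cfg.mm_per_pixel)),
    )
    track = PoseTrack(
        meta=meta,
        calibration=calibration,
        xy=labels_px,
        likelihood=likelihood,
        units="px",
    )
    truth = GroundTruth(
        centroid_mm=pos,
        distance_mm=distance,
        rejected=rejected,
        likelihood=likelihood,
        mean_speed_mm_s=speed,
    )
    return track, truth


def simulate_cohort(
    n_pairs: int,
    cfg_a: SimConfig,
    cfg_b: SimConfig,
    seed: int,
    n_pairs_b: int | None = None,
    labels: tuple[str, str] = ("BTBR", "CBA"),
) -> tuple[list[tuple[PoseTrack, GroundTruth]], list[tuple[PoseTrack, GroundTruth]]]:
    """Simulate two cohorts of independent sessions (e.g. two strains).

    Each session gets an independent seed derived from ``seed``.  Sexes
    alternate M/F within each cohort and ages are drawn uniformly from the
    2-8 month adult range, giving downstream grouping code something to
    chew on without planting any effect.
    """
    if n_pairs < 1 or (n_pairs_b is not None and n_pairs_b < 1):
        raise ValueError("each cohort needs at least one pair")
    n_b = n_pairs if n_pairs_b is None else n_pairs_b
    rng = np.random.default_rng(seed)
    cohorts = []
    for label, cfg, n in ((labels[0], cfg_a, n_pairs), (labels[1], cfg_b, n_b)):
        sessions = []
        for i in range(n):
            session_seed = int(rng.integers(0, 2**31 - 1))
            age = float(np.round(rng.uniform(2.0, 8.0), 1))
            meta = SessionMeta(
                session_id=f"{label}-{i:03d}",
                strain=label,
                sex="M" if i % 2 == 0 else "F",
                age_months=age,
            )
            sessions.append(simulate_session(replace(cfg, seed=session_seed), meta=meta))
        cohorts.append(sessions)
    return cohorts[0], cohorts[1]
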