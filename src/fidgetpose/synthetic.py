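"""Seeded synthetic skeleton cohorts with FM+-like and FM−-like kinematics.

The study's videos are confidential, so every downstream stage is
exercised on generated 25-point skeleton sequences instead.  The
generator caricatures the two movement phenotypes:

* **FM+ (fidgety-like)** — small-amplitude, moderate-speed oscillations
  with frequent direction changes, weak inter-joint coupling and
  intermittent activity;
* **FM− (writhing-like)** — slower, larger-amplitude, strongly
  correlated en-bloc movements.

Each snippet starts from a fixed supine base posture (trunk length 1 in
model units), perturbs the joints with band-limited oscillations (sum of
two random-phase sinusoids plus Ornstein–Uhlenbeck jitter for the
"variable acceleration" character), applies a per-participant camera
similarity transform (isotropic scale + translation), and finally thins
joints with i.i.d. dropout (dropped joints become confidence-0).

Nothing here is a biomechanical claim: the defaults are synthetic
conventions chosen so the two classes are well separated by amplitude,
tempo and coupling, which is what the classifier is meant to pick up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .skeleton import (
    N_JOINTS, SNIPPET_FPS, SNIPPET_FRAMES, Label, SkeletonSequence, SkeletonSnippet,
)

# Supine infant template in model units: mid-hip at the origin, neck at
# (0, -1) so trunk length is exactly 1; y grows downward (image convention),
# limbs flexed.  Any anatomically plausible template would do.
BASE_POSTURE = np.array([
    (0.00, -1.25),   # 0  Nose
    (0.00, -1.00),   # 1  Neck
    (-0.35, -0.95),  # 2  RShoulder
    (-0.55, -0.65),  # 3  RElbow
    (-0.45, -0.35),  # 4  RWrist
    (0.35, -0.95),   # 5  LShoulder
    (0.55, -0.65),   # 6  LElbow
    (0.45, -0.35),   # 7  LWrist
    (0.00, 0.00),    # 8  MidHip
    (-0.18, 0.00),   # 9  RHip
    (-0.38, 0.45),   # 10 RKnee
    (-0.30, 0.85),   # 11 RAnkle
    (0.18, 0.00),    # 12 LHip
    (0.38, 0.45),    # 13 LKnee
    (0.30, 0.85),    # 14 LAnkle
    (-0.08, -1.32),  # 15 REye
    (0.08, -1.32),   # 16 LEye
    (-0.16, -1.28),  # 17 REar
    (0.16, -1.28),   # 18 LEar
    (0.34, 1.00),    # 19 LBigToe
    (0.42, 0.97),    # 20 LSmallToe
    (0.26, 0.90),    # 21 LHeel
    (-0.34, 1.00),   # 22 RBigToe
    (-0.42, 0.97),   # 23 RSmallToe
    (-0.26, 0.90),   # 24 RHeel
])

# Relative movement amplitude per joint: distal joints swing more than the
# trunk; the mid-hip anchor moves least.
JOINT_AMPLITUDE_SCALE = np.array([
    0.5, 0.5, 0.4, 1.0, 1.3, 0.4, 1.0, 1.3, 0.15, 0.3,
    1.0, 1.3, 0.3, 1.0, 1.3, 0.5, 0.5, 0.5, 0.5, 1.3,
    1.3, 1.2, 1.3, 1.3, 1.2,
])


@dataclass(frozen=True)
class MotionClassConfig:
    """Kinematic recipe for one movement class.

    Parameters
    ----------
    amplitude_frac
        Typical oscillation amplitude as a fraction of trunk length.
    speed_hz
        (low, high) dominant oscillation frequency band in Hz.
    direction_change_rate
        Expected direction re-randomizations per second per joint
        (a Poisson process).
    inter_joint_correlation
        0 = joints move independently, 1 = fully en-bloc.
    duty_cycle
        Fraction of time the movement is active (gated by on/off bouts).
    """

    amplitude_frac: float
    speed_hz: tuple[float, float]
    direction_change_rate: float
    inter_joint_correlation: float
    duty_cycle: float = 1.0
    ou_jitter_frac: float = 0.3   # OU jitter sd relative to amplitude
    ou_timescale_s: float = 0.2

    def __post_init__(self):
        if not self.amplitude_frac >= 0:
            raise ValueError("amplitude_frac must be >= 0")
        lo, hi = self.speed_hz
        if not (0 < lo <= hi):
            raise ValueError("speed_hz must be a positive (low, high) band")
        if not 0 <= self.inter_joint_correlation <= 1:
            raise ValueError("inter_joint_correlation must lie in [0, 1]")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty_cycle must lie in (0, 1]")
        if self.direction_change_rate < 0:
            raise ValueError("direction_change_rate must be >= 0")


#: Fidgety-like: small, brisk, uncoupled, intermittent.
FM_PLUS_DEFAULT = MotionClassConfig(
    amplitude_frac=0.04, speed_hz=(1.0, 3.0), direction_change_rate=2.0,
    inter_joint_correlation=0.15, duty_cycle=0.8)

#: Writhing-like: large, slow, en-bloc, continuous.
FM_MINUS_DEFAULT = MotionClassConfig(
    amplitude_frac=0.15, speed_hz=(0.2, 0.7), direction_change_rate=0.2,
    inter_joint_correlation=0.9, duty_cycle=1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for a full synthetic cohort.

    Defaults mirror the study scale: 45 participants, 1800 snippets in
    total with a 53.6% FM+ share.  The per-participant camera transform
    (uniform scale in pixels per trunk length, plus a pixel offset) is
    constant across that participant's snippets.
    """

    n_participants: int = 45
    snippets_per_participant: int = 40
    class_mix: float = 0.536
    fm_plus: MotionClassConfig = FM_PLUS_DEFAULT
    fm_minus: MotionClassConfig = FM_MINUS_DEFAULT
    dropout_prob: float = 0.02
    camera_scale_range: tuple[float, float] = (80.0, 320.0)
    camera_offset_range: tuple[float, float] = (0.0, 500.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.snippets_per_participant < 1:
            raise ValueError("snippets_per_participant must be >= 1")
        if not 0 <= self.class_mix <= 1:
            raise ValueError("class_mix must lie in [0, 1]")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")


def _poisson_event_times(rng, rate, t_end):
    """Event times of a Poisson process on [0, t_end)."""
    if rate <= 0:
        return np.empty(0)
    n_draw = max(8, int(3 * rate * t_end) + 8)
    times = np.cumsum(rng.exponential(1 / rate, size=n_draw))
    while times[-1] < t_end:  # pragma: no cover - astronomically rare
        times = np.concatenate([times, times[-1] + np.cumsum(rng.exponential(1 / rate, n_draw))])
    return times[times < t_end]


def _piecewise_directions(rng, t, rate):
    """Unit direction vector per time step, re-randomized at Poisson times."""
    changes = _poisson_event_times(rng, rate, t[-1] + 1 / SNIPPET_FPS)
    angles = rng.uniform(0, 2 * np.pi, size=len(changes) + 1)
    seg = np.searchsorted(changes, t, side="right")
    theta = angles[seg]
    return np.column_stack([np.cos(theta), np.sin(theta)])


def _ou_jitter(rng, n, theta_per_step, sigma_stationary):
    """Discretized 2D Ornstein–Uhlenbeck path with the given stationary sd.

    AR(1) recursion x_i = (1-theta) x_{i-1} + s n_i, run as a linear filter.
    """
    a = 1.0 - theta_per_step
    noise_scale = sigma_stationary * np.sqrt(2 * theta_per_step)
    x0 = rng.normal(0, sigma_stationary, 2)
    noise = rng.normal(0, 1, (n, 2))
    path, _ = lfilter([noise_scale], [1.0, -a], noise, axis=0, zi=(a * x0)[None, :])
    return path


def _motion_component(rng, t, cfg: MotionClassConfig):
    """One 2D displacement track of unit typical magnitude."""
    f = rng.uniform(*cfg.speed_hz, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    osc = 0.5 * (np.sin(2 * np.pi * f[0] * t + phase[0])
                 + np.sin(2 * np.pi * f[1] * t + phase[1]))
    track = osc[:, None] * _piecewise_directions(rng, t, cfg.direction_change_rate)
    theta_per_step = min(1.0, (1 / cfg.ou_timescale_s) / SNIPPET_FPS)
    track += _ou_jitter(rng, len(t), theta_per_step, cfg.ou_jitter_frac)
    return track


def _duty_gate(rng, t, duty_cycle, bout_scale_s=2.0):
    """Smoothed on/off activity gate with the requested active fraction."""
    if duty_cycle >= 1.0:
        return np.ones(len(t))
    t_end = t[-1] + 1 / SNIPPET_FPS
    on_first = rng.random() < duty_cycle
    n_bouts = max(8, int(6 * t_end / bout_scale_s) + 8)
    on_even = on_first
    means = np.where((np.arange(n_bouts) % 2 == 0) == on_even,
                     duty_cycle * bout_scale_s, (1 - duty_cycle) * bout_scale_s)
    edges = np.cumsum(rng.exponential(means))
    while edges[-1] < t_end:  # pragma: no cover - astronomically rare
        edges = np.concatenate([edges, edges[-1] + np.cumsum(rng.exponential(means))])
    seg = np.searchsorted(edges, t, side="right")
    gate = np.where((seg % 2 == 0) == on_first, 1.0, 0.0)
    kernel = np.ones(5) / 5.0  # 0.1 s ramp
    return np.convolve(gate, kernel, mode="same")


def generate_snippet(class_label: Label, motion_cfg: MotionClassConfig,
                     camera_params: tuple[float, tuple[float, float]] = (1.0, (0.0, 0.0)),
                     rng: np.random.Generator | None = None,
                     dropout_prob: float = 0.0,
                     participant_id: str = "P000",
                     snippet_id: str = "S0000") -> SkeletonSnippet:
    """Generate one 250-frame snippet of the given movement class.

    ``camera_params`` is ``(scale, (offset_x, offset_y))``: pixel
    coordinates are ``scale * model_xy + offset``.
    """
    rng = np.random.default_rng(rng)
    t = np.arange(SNIPPET_FRAMES) / SNIPPET_FPS
    rho = motion_cfg.inter_joint_correlation

    shared = _motion_component(rng, t, motion_cfg)
    displacement = np.empty((SNIPPET_FRAMES, N_JOINTS, 2))
    for j in range(N_JOINTS):
        own = _motion_component(rng, t, motion_cfg)
        mixed = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        displacement[:, j, :] = mixed * JOINT_AMPLITUDE_SCALE[j]
    gate = _duty_gate(rng, t, motion_cfg.duty_cycle)
    displacement *= motion_cfg.amplitude_frac * gate[:, None, None]

    model_xy = BASE_POSTURE[None, :, :] + displacement
    scale, (ox, oy) = camera_params
    xy = scale * model_xy + np.array([ox, oy])

    confidence = rng.uniform(0.5, 1.0, size=(SNIPPET_FRAMES, N_JOINTS))
    if dropout_prob > 0:
        dropped = rng.random((SNIPPET_FRAMES, N_JOINTS)) < dropout_prob
        confidence[dropped] = 0.0
        xy[dropped] = 0.0

    seq = SkeletonSequence(xy, confidence, SNIPPET_FPS, participant_id, snippet_id)
    return SkeletonSnippet(seq, snippet_id, class_label)


def generate_cohort(cfg: CohortConfig) -> tuple[list[SkeletonSnippet], pd.DataFrame]:
    """Generate a seeded cohort and its labels table.

    Deterministic given ``cfg``: every participant and snippet draws from
    its own seed stream derived from ``(cfg.seed, participant, snippet)``,
    so two cohorts differing only in camera ranges contain identical
    motion, labels and dropout patterns.  The labels table follows the
    labels-CSV schema with both raters set to the generating class.
    """
    snippets: list[SkeletonSnippet] = []
    rows = []
    for p in range(cfg.n_participants):
        pid = f"P{p:03d}"
        cam_rng = np.random.default_rng([cfg.seed, p, 0])
        scale = cam_rng.uniform(*cfg.camera_scale_range)
        offset = tuple(cam_rng.uniform(*cfg.camera_offset_range, size=2))
        for s in range(cfg.snippets_per_participant):
            srng = np.random.default_rng([cfg.seed, p, s + 1])
            is_plus = srng.random() < cfg.class_mix
            label = Label.FM_PLUS if is_plus else Label.FM_MINUS
            motion = cfg.fm_plus if is_plus else cfg.fm_minus
            sid = f"{pid}_S{s:04d}"
            snippets.append(generate_snippet(label, motion, (scale, offset), srng,
                                             cfg.dropout_prob, pid, sid))
            rows.append({"snippet_id": sid, "participant_id": pid,
                         "rater_a": label.value, "rater_b": label.value})
    return snippets, pd.DataFrame(rows)


def mean_joint_displacement(snippet: SkeletonSnippet) -> float:
    """Mean distance of each present joint from its snippet-mean position,
    in trunk-length units (camera-invariant movement-amplitude statistic)."""
    from .features import normalize_skeleton

    norm = normalize_skeleton(snippet)
    xy = norm.sequence.xy
    present = norm.sequence.confidence > 0
    deviations = []
    for j in range(N_JOINTS):
        mask = present[:, j]
        if mask.sum() < 2:
            continue
        pts = xy[mask, j, :]
        deviations.append(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())
    return float(np.mean(deviations))
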