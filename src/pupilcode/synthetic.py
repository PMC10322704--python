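"""Synthetic session generator with known ground truth.

Emulates a head-fixed recording session: a 20 Hz pupil video reduced to
eight edge landmarks per frame, per-cell calcium fluorescence (plus a
neuropil halo) on a 5.15 Hz volumetric clock, wheel running speed, randomly
spaced liquid rewards with lick bursts, and 30 s optogenetic stimulation
trains.  Every cell is built from known generative weights on the pupil,
locomotion and reward predictors, so variance-partitioning estimates can be
checked against analytic truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "BehaviorTraces",
    "PupilSim",
    "GroundTruth",
    "LandmarkSet",
    "Session",
    "simulate_behavior",
    "simulate_pupil",
    "simulate_cells",
    "render_landmarks",
    "simulate_session",
    "first_order_lowpass",
    "raised_cosine_kernel",
]

STIM_FREQUENCIES_HZ = (1.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Session parameters.

    Defaults describe one full recording session: 50 rewards at random
    1-1.5 min intervals (hence a 75 min session), a 20 Hz pupil camera and
    a 5.15 Hz imaging volume rate.
    """

    duration_s: float = 4500.0
    pupil_rate_hz: float = 20.0
    cell_rate_hz: float = 5.15
    n_cells: int = 60
    reward_interval_s: tuple[float, float] = (60.0, 90.0)
    n_rewards: int = 50
    run_bout_rate: float = 2.0           # bouts per minute
    run_bout_duration_s: float = 5.0     # mean bout duration
    calcium_tau_s: float = 1.2           # GCaMP6s-like decay
    noise_sd: float = 0.5                # white noise on the z-scale signal
    blink_rate_hz: float = 0.05
    landmark_jitter_px: float = 0.5
    seed: int = 0

    # pupil dynamics
    pupil_baseline_px: float = 30.0
    pupil_tau_s: float = 1.0             # first-order low-pass time constant
    pupil_gain_px: float = 4.0           # px of radius per unit drive
    ou_tau_s: float = 20.0               # latent arousal correlation time
    ou_sd: float = 1.0
    loco_coupling: float = 0.4           # drive units per (speed / 10 cm/s)
    reward_coupling: float = 1.0
    reward_pupil_tau_s: float = 3.0      # decay of post-reward pupil transient

    # licking and stimulation
    lick_window_s: tuple[float, float] = (0.1, 2.1)
    lick_prob: float = 0.6
    stim_interval_s: tuple[float, float] = (120.0, 150.0)
    stim_duration_s: float = 30.0

    # reward kernel used by the generative reward predictor
    reward_kernel_support_s: float = 2.0

    def validate(self) -> None:
        lo, hi = self.reward_interval_s
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("pupil_rate_hz", "cell_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if lo > hi or lo <= 0:
            raise ValueError("reward_interval_s must satisfy 0 < lower <= upper")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_rewards < 0:
            raise ValueError("n_rewards must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_rewards * lo > self.duration_s:
            raise ValueError(
                f"duration {self.duration_s:g} s cannot fit {self.n_rewards} rewards "
                f"at a minimum interval of {lo:g} s"
            )


@dataclass
class BehaviorTraces:
    """Behavioral traces on the pupil (camera) clock."""

    time_s: np.ndarray
    speed_cmps: np.ndarray
    reward_times_s: np.ndarray
    lick_wave: np.ndarray            # binary, pupil clock
    stim_epochs: list[tuple[float, float, float]]  # (onset, offset, freq Hz)
    bout_onsets_s: np.ndarray        # generative run-bout switch times
    bout_offsets_s: np.ndarray

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass
class PupilSim:
    """Simulated pupil radius and its latent generative traces."""

    time_s: np.ndarray
    radius_px: np.ndarray
    arousal: np.ndarray              # latent OU process
    drive: np.ndarray                # net drive before the low-pass stage


@dataclass
class GroundTruth:
    """Generative weights and analytic variance decomposition per cell.

    ``variance_shares`` is the covariance decomposition
    w_j * Cov(q_j, s) / Var(cell): shares plus ``noise_share`` sum to one
    exactly.  ``unique_contrib_pct`` is the analytic leave-one-predictor-out
    contribution 100 * u_j / Var(signal) that a nested-regression
    partitioning estimates; ``labels`` applies the 20 % cutoff rule to it.
    """

    weights: np.ndarray              # (n_cells, 3): pupil, locomotion, reward
    noise_var: np.ndarray            # (n_cells,)
    arousal: np.ndarray
    variance_shares: np.ndarray      # (n_cells, 3)
    noise_share: np.ndarray          # (n_cells,)
    unique_contrib_pct: np.ndarray   # (n_cells, 3)
    labels: np.ndarray               # (n_cells,) of {pupil, reward, both, other}
    predictor_names: tuple[str, ...] = ("pupil", "locomotion", "reward")


@dataclass
class LandmarkSet:
    """Eight pupil-edge landmarks per frame with per-point confidence."""

    time_s: np.ndarray
    x: np.ndarray                    # (n_frames, 8) pixels
    y: np.ndarray                    # (n_frames, 8)
    confidence: np.ndarray           # (n_frames, 8) in [0, 1]
    center: tuple[float, float] = (100.0, 100.0)


@dataclass
class Session:
    """A complete synthetic session bundle."""

    config: SimulationConfig
    behavior: BehaviorTraces
    pupil: PupilSim
    landmarks: LandmarkSet
    cell_time_s: np.ndarray
    cell_raw: np.ndarray             # (n_cells, n_samples) raw fluorescence
    halo_raw: np.ndarray             # (n_cells, n_samples) neuropil halo
    truth: GroundTruth


def first_order_lowpass(drive: np.ndarray, tau_s: float, dt_s: float,
                        init: float = 0.0) -> np.ndarray:
    """Exact first-order relaxation toward ``drive`` with time constant tau.

    x[t+1] = x[t] + (1 - exp(-dt/tau)) * (drive[t] - x[t]); a step input is
    approached as 1 - exp(-t/tau), which tests check in closed form.
    """
    alpha = 1.0 - np.exp(-dt_s / tau_s)
    out = np.empty_like(np.asarray(drive, dtype=float))
    x = float(init)
    for i, d in enumerate(drive):
        x = x + alpha * (d - x)
        out[i] = x
    return out


def raised_cosine_kernel(support_s: float, rate_hz: float) -> np.ndarray:
    """Unit-area raised-cosine bump on [0, support]; a causal event kernel."""
    n = max(int(round(support_s * rate_hz)), 2)
    t = np.arange(n) / rate_hz
    k = 1.0 - np.cos(2.0 * np.pi * np.minimum(t / support_s, 1.0))
    k /= k.sum() / rate_hz
    return k


def _ou_process(n: int, dt: float, tau: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples via exact discretization."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    noise = rng.standard_normal(n) * sd * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i]
    return x


def simulate_behavior(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> BehaviorTraces:
    """Draw rewards, lick bursts, running bouts and stimulation epochs."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.pupil_rate_hz
    n = int(round(config.duration_s * rate))
    time_s = np.arange(n) / rate

    # rewards: inter-event gaps uniform in the configured interval
    lo, hi = config.reward_interval_s
    gaps = rng.uniform(lo, hi, size=config.n_rewards)
    reward_times = np.cumsum(gaps)
    if config.n_rewards and reward_times[-1] >= config.duration_s:
        raise ValueError(
            f"drawn reward times exceed duration {config.duration_s:g} s; "
            f"increase duration_s or reduce n_rewards"
        )

    # lick bursts: Bernoulli train inside a fixed post-reward window
    lick = np.zeros(n)
    w0, w1 = config.lick_window_s
    for t0 in reward_times:
        i0, i1 = int(np.ceil((t0 + w0) * rate)), int(np.floor((t0 + w1) * rate))
        i1 = min(i1, n - 1)
        if i0 <= i1:
            lick[i0:i1 + 1] = (rng.random(i1 + 1 - i0) < config.lick_prob)

    # running bouts: two-state process; rectangular envelope smoothed by a
    # 3-sample moving average so the 1 cm/s crossing stays within one sample
    # of the generative switch time
    speed = np.zeros(n)
    onsets, offsets = [], []
    if config.run_bout_rate > 0:
        t = rng.exponential(60.0 / config.run_bout_rate)
        while t < config.duration_s - 1.0:
            dur = float(np.clip(rng.exponential(config.run_bout_duration_s), 1.5, 20.0))
            t1 = min(t + dur, config.duration_s - 0.5)
            i0, i1 = int(round(t * rate)), int(round(t1 * rate))
            amp = rng.uniform(5.0, 15.0)
            wobble = 1.0 + 0.2 * np.sin(2 * np.pi * 1.5 * time_s[i0:i1])
            speed[i0:i1] = amp * wobble
            onsets.append(time_s[i0])
            offsets.append(time_s[min(i1, n - 1)])
            t = t1 + 2.0 + rng.exponential(60.0 / config.run_bout_rate)
        if len(speed) >= 3:
            kernel = np.ones(3)
            speed = np.convolve(speed, kernel, mode="same") / np.convolve(
                np.ones(n), kernel, mode="same")

    # optogenetic stimulation trains, frequencies cycled in shuffled blocks
    epochs: list[tuple[float, float, float]] = []
    s_lo, s_hi = config.stim_interval_s
    t = rng.uniform(s_lo, s_hi)
    freqs: list[float] = []
    while t + config.stim_duration_s < config.duration_s:
        if not freqs:
            freqs = list(rng.permutation(STIM_FREQUENCIES_HZ))
        epochs.append((t, t + config.stim_duration_s, freqs.pop()))
        t += rng.uniform(s_lo, s_hi)

    return BehaviorTraces(
        time_s=time_s, speed_cmps=speed, reward_times_s=reward_times,
        lick_wave=lick, stim_epochs=epochs,
        bout_onsets_s=np.asarray(onsets), bout_offsets_s=np.asarray(offsets),
    )


def simulate_pupil(behavior: BehaviorTraces, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> PupilSim:
    """Pupil radius as a low-pass-filtered mixture of arousal, locomotion
    and post-reward transients.

    The first-order low-pass makes the pupil lag its net drive, so neural
    activity built from the same drive leads dilation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    dt = 1.0 / config.pupil_rate_hz
    n = len(behavior.time_s)

    arousal = _ou_process(n, dt, config.ou_tau_s, config.ou_sd, rng)

    reward_impulses = np.zeros(n)
    idx = np.round(behavior.reward_times_s * config.pupil_rate_hz).astype(int)
    reward_impulses[idx[idx < n]] = 1.0
    k = np.exp(-np.arange(int(5 * config.reward_pupil_tau_s / dt)) * dt
               / config.reward_pupil_tau_s)
    reward_transient = np.convolve(reward_impulses, k)[:n]

    drive = (arousal
             + config.loco_coupling * behavior.speed_cmps / 10.0
             + config.reward_coupling * reward_transient)

    radius = config.pupil_baseline_px + config.pupil_gain_px * first_order_lowpass(
        drive, config.pupil_tau_s, dt, init=float(drive[0]))
    radius = np.maximum(radius, 1.0)  # physical floor; never hit at defaults
    return PupilSim(time_s=behavior.time_s, radius_px=radius,
                    arousal=arousal, drive=drive)


def default_cell_weights(n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Designed cell classes: pupil-only, reward-only, mixed, locomotion.

    Major weights are drawn on 0.6-1.4, minor weights on 0.1-0.3, giving a
    graded spread of true variance shares for rank-recovery tests.
    """
    w = rng.uniform(0.1, 0.3, size=(n_cells, 3))
    for i in range(n_cells):
        cls = i % 4
        major = rng.uniform(0.6, 1.4)
        if cls == 0:                      # pupil-only
            w[i, 0] = major
        elif cls == 1:                    # reward-only
            w[i, 2] = major
        elif cls == 2:                    # mixed pupil + reward
            w[i, 0] = major
            w[i, 2] = rng.uniform(0.6, 1.4)
        else:                             # locomotion
            w[i, 1] = major
    return w


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def build_cell_predictors(behavior: BehaviorTraces, pupil: PupilSim,
                          config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Resample pupil/speed/lick to the cell clock and z-score.

    Returns (cell_time_s, Q) where Q columns are the generative predictors
    (pupil, locomotion, reward) already convolved as the generator uses them.
    """
    n_c = int(np.floor(config.duration_s * config.cell_rate_hz))
    t_c = np.arange(n_c) / config.cell_rate_hz
    pupil_c = np.interp(t_c, pupil.time_s, pupil.radius_px)
    speed_c = np.interp(t_c, behavior.time_s, behavior.speed_cmps)
    lick_c = np.interp(t_c, behavior.time_s, behavior.lick_wave)
    kernel = raised_cosine_kernel(config.reward_kernel_support_s, config.cell_rate_hz)
    reward_c = np.convolve(lick_c, kernel)[:n_c] / config.cell_rate_hz

    ca = np.exp(-np.arange(int(np.ceil(5 * config.calcium_tau_s * config.cell_rate_hz)) + 1)
                / (config.calcium_tau_s * config.cell_rate_hz))
    ca /= ca.sum()

    q = np.column_stack([
        np.convolve(_zscore(v), ca)[:n_c]
        for v in (pupil_c, speed_c, reward_c)
    ])
    return t_c, q


def simulate_cells(behavior: BehaviorTraces, pupil: PupilSim,
                   config: SimulationConfig,
                   weights: np.ndarray | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Generate raw cell + halo fluorescence with analytic ground truth.

    Each cell is baseline + scale * (w . q + noise) where q are the
    calcium-kernel-convolved z-scored predictors; the halo carries a shared
    slow contamination plus a small leak of the cell signal, which the
    neuropil subtraction step must remove.
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    t_c, q = build_cell_predictors(behavior, pupil, config)
    n_c = len(t_c)
    if weights is None:
        weights = default_cell_weights(config.n_cells, rng)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (config.n_cells, 3):
        raise ValueError(f"weights must have shape ({config.n_cells}, 3)")

    cov = np.cov(q, rowvar=False, bias=True)  # realized predictor covariance
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.pinv(cov)

    noise_var = np.full(config.n_cells, config.noise_sd ** 2)
    shares = np.zeros((config.n_cells, 3))
    contrib = np.zeros((config.n_cells, 3))
    noise_share = np.zeros(config.n_cells)

    signals = q @ weights.T                 # (n_samples, n_cells), noiseless
    sig_var = signals.var(axis=0)
    for i in range(config.n_cells):
        w = weights[i]
        total = sig_var[i] + noise_var[i]
        if total == 0:
            noise_share[i] = 1.0
            continue
        # covariance decomposition: sums with the noise share to exactly 1
        shares[i] = w * (cov @ w) / total
        noise_share[i] = noise_var[i] / total
        if sig_var[i] > 0:
            # unique variance of predictor j: w_j^2 * Var(q_j | q_-j)
            unique = w ** 2 / np.diag(cov_inv)
            contrib[i] = 100.0 * unique / sig_var[i]

    labels = np.array([_true_label(c) for c in contrib])

    slow = _ou_process(n_c, 1.0 / config.cell_rate_hz, 60.0, 1.0, rng)
    noise = rng.standard_normal((config.n_cells, n_c)) * config.noise_sd
    z = signals.T + noise                   # (n_cells, n_samples)
    cell_raw = 100.0 + 20.0 * z + 5.0 * slow
    halo_raw = 80.0 + 5.0 * slow + 0.05 * 20.0 * signals.T

    truth = GroundTruth(
        weights=weights, noise_var=noise_var, arousal=pupil.arousal,
        variance_shares=shares, noise_share=noise_share,
        unique_contrib_pct=contrib, labels=labels,
    )
    return t_c, cell_raw, halo_raw, truth


def _true_label(contrib_pct: np.ndarray, major_cutoff: float = 20.0) -> str:
    p, _, r = contrib_pct
    if p >= major_cutoff and r >= major_cutoff:
        return "both"
    if p >= major_cutoff:
        return "pupil"
    if r >= major_cutoff:
        return "reward"
    return "other"


def render_landmarks(pupil: PupilSim, config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     center: tuple[float, float] = (100.0, 100.0),
                     ) -> LandmarkSet:
    """Reduce the pupil circle to 8 jittered edge points per frame.

    Blinks are rendered as confidence drops (the extraction path only sees
    confidence), not geometric occlusion.
    """
    if np.any(pupil.radius_px <= 0):
        raise ValueError("pupil radius must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n = len(pupil.time_s)
    angles = np.arange(8) * (2 * np.pi / 8)
    x = center[0] + pupil.radius_px[:, None] * np.cos(angles)[None, :]
    y = center[1] + pupil.radius_px[:, None] * np.sin(angles)[None, :]
    if config.landmark_jitter_px > 0:
        x = x + rng.normal(0, config.landmark_jitter_px, size=x.shape)
        y = y + rng.normal(0, config.landmark_jitter_px, size=y.shape)

    confidence = 0.95 + 0.04 * rng.random((n, 8))
    if config.blink_rate_hz > 0:
        t = rng.exponential(1.0 / config.blink_rate_hz)
        while t < pupil.time_s[-1]:
            dur = rng.uniform(0.15, 0.4)
            i0 = int(round(t * config.pupil_rate_hz))
            i1 = min(int(round((t + dur) * config.pupil_rate_hz)) + 1, n)
            confidence[i0:i1] = rng.uniform(0.05, 0.5, size=confidence[i0:i1].shape)
            t += dur + rng.exponential(1.0 / config.blink_rate_hz)
    # never blink on the very first/last frame so interpolation has anchors
    confidence[0] = np.maximum(confidence[0], 0.95)
    confidence[-1] = np.maximum(confidence[-1], 0.95)

    return LandmarkSet(time_s=pupil.time_s, x=x, y=y,
                       confidence=np.clip(confidence, 0.0, 1.0), center=center)


@dataclass
class SubjectRecording:
    """One head-fixed wheel session for the two-group comparison scenario."""

    subject_id: str
    group_id: str
    time_s: np.ndarray
    speed_cmps: np.ndarray
    pupil_px: np.ndarray
    baseline_px: float               # designed tonic pupil level


def simulate_group_scenario(n_control: int = 8, n_ablated: int = 7,
                            duration_s: float = 180.0, rate_hz: float = 20.0,
                            baseline_control_px: float = 30.0,
                            baseline_diff_px: float = 2.0,
                            between_subject_sd_px: float = 1.0,
                            seed: int = 0) -> list[SubjectRecording]:
    """Two groups with identical running-bout statistics but different
    tonic pupil size.

    Emulates a cell-ablation comparison: both groups draw bouts from the
    same shape distribution (amplitude 7-9 cm/s, 5 s duration), while the
    ablated group's resting pupil baseline sits ``baseline_diff_px`` below
    the control group's.  Pupil couples to locomotion identically in both
    groups, so only bout-matched baseline comparisons should differ.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    time_s = np.arange(n) / rate_hz
    subjects: list[SubjectRecording] = []
    for group, count, mu in (("control", n_control, baseline_control_px),
                             ("ablated", n_ablated,
                              baseline_control_px - baseline_diff_px)):
        for i in range(count):
            speed = np.zeros(n)
            t = 15.0 + rng.uniform(0.0, 5.0)
            while t + 10.0 < duration_s:
                i0 = int(round(t * rate_hz))
                i1 = i0 + int(round(5.0 * rate_hz))
                speed[i0:i1] = rng.uniform(7.0, 9.0)
                t += rng.uniform(22.0, 28.0)
            kernel = np.ones(3)
            speed = np.convolve(speed, kernel, "same") / np.convolve(
                np.ones(n), kernel, "same")
            baseline = mu + between_subject_sd_px * rng.standard_normal()
            coupling = first_order_lowpass(0.15 * speed, 1.0, 1.0 / rate_hz)
            pupil = baseline + coupling + 0.2 * rng.standard_normal(n)
            subjects.append(SubjectRecording(
                subject_id=f"{group}_{i}", group_id=group, time_s=time_s,
                speed_cmps=speed, pupil_px=pupil, baseline_px=baseline))
    return subjects


def simulate_session(config: SimulationConfig,
                     weights: np.ndarray | None = None) -> Session:
    """Run the full generator with seeds fanned out from ``config.seed``."""
    config.validate()
    behavior = simulate_behavior(config)
    pupil = simulate_pupil(behavior, config)
    t_c, cell_raw, halo_raw, truth = simulate_cells(behavior, pupil, config,
                                                    weights=weights)
    landmarks = render_landmarks(pupil, config)
    return Session(config=config, behavior=behavior, pupil=pupil,
                   landmarks=landmarks, cell_time_s=t_c,
                   cell_raw=cell_raw, halo_raw=halo_raw, truth=truth)
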