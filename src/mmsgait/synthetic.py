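"""Seeded generator of gait-like multi-node recordings with known truth.

Each node carries a quasi-periodic rectified carrier: one movement cycle
per cadence period, rising from a baseline trough to a peak and back. The
planted ground truth lives at the spike level — the *normalized* peak
amplitude of every cycle is drawn first (note that peak/(peak + mean of
flanking troughs) always exceeds 1/2, so planted amplitudes live in
(0.5, 1)), and the waveform is built so that MMS extraction recovers the
planted values exactly up to sampling discretization: a peak of height
m*g/(1-g) over baseline m normalizes back to g.

Directed couplings are applied at the spike level with integer spike lags,
x_k = base_k + gain * (y_{k-lag} - mean_y), so downstream causality
analysis sees exactly the single-delay autoregressive structure it
estimates. Optional tremor contaminates the waveform with a sinusoid in
the tremor band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .io_kinematics import KinematicRecording

DEFAULT_RATE_HZ = 100.0
DEFAULT_DURATION_S = 180.0
#: default planted amplitude distribution: gamma with mean 0.72, sd 0.08,
#: comfortably inside the (0.5, 1) band of realizable normalized peaks
DEFAULT_AMPLITUDE_GAMMA = (81.0, 0.0089)
AMPLITUDE_CLIP = (0.505, 0.98)
BASELINE = 1.0


@dataclass
class Coupling:
    source: str
    target: str
    gain: float
    lag: int        # spike-index units

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("coupling lag must be a positive integer")
        if not np.isfinite(self.gain):
            raise ValueError("coupling gain must be finite")


@dataclass
class Tremor:
    node: str
    frequency_hz: float
    amplitude: float


@dataclass
class ModeMixtureSpec:
    """Planted amplitude mixture: exponential low mode + Gaussian high mode."""

    mode1_weight: float = 0.3
    exp_shift: float = 0.52
    exp_rate: float = 25.0
    gauss_mean: float = 0.78
    gauss_sd: float = 0.04


@dataclass
class GroundTruth:
    """Full specification (and record) of one simulated subject."""

    node_names: list[str] = field(default_factory=lambda: ["pelvis", "foot_l", "foot_r"])
    cadence_hz: float = 1.0
    cadence_jitter_sd: float = 0.05      # lognormal sd of cycle-period factors
    amplitude_gamma: dict[str, tuple[float, float]] = field(default_factory=dict)
    mode_mixture: dict[str, ModeMixtureSpec] = field(default_factory=dict)
    couplings: list[Coupling] = field(default_factory=list)
    tremors: list[Tremor] = field(default_factory=list)
    seed: int = 0
    # realized spike-level truth, filled in by simulate_subject
    peak_times_s: np.ndarray | None = None
    planted_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValueError("cadence must be positive")
        for c in self.couplings:
            for end in (c.source, c.target):
                if end not in self.node_names:
                    raise ValueError(f"coupling references unknown node {end!r}")


def _draw_amplitudes(truth: GroundTruth, node: str, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    if node in truth.mode_mixture:
        spec = truth.mode_mixture[node]
        is_exp = rng.random(n) < spec.mode1_weight
        vals = np.where(
            is_exp,
            spec.exp_shift + rng.exponential(1.0 / spec.exp_rate, n),
            rng.normal(spec.gauss_mean, spec.gauss_sd, n))
    else:
        shape, scale = truth.amplitude_gamma.get(node, DEFAULT_AMPLITUDE_GAMMA)
        vals = rng.gamma(shape, scale, n)
    return np.clip(vals, *AMPLITUDE_CLIP)


def simulate_subject(
    truth: GroundTruth,
    duration_s: float = DEFAULT_DURATION_S,
    rate_hz: float = DEFAULT_RATE_HZ,
    *,
    subject_id: str = "sim",
    group_label: str = "",
) -> tuple[KinematicRecording, GroundTruth]:
    """Simulate one subject's walk; fully reproducible under the seed.

    Returns the recording plus a copy of the truth with the realized peak
    times and planted (post-coupling) normalized amplitudes filled in.
    """
    if duration_s < 10:
        raise ValueError("duration must be at least 10 s")
    if rate_hz < 20:
        raise ValueError("rate must be at least 20 Hz")
    rng = np.random.default_rng(truth.seed)

    # jittered cycle grid shared by all nodes (gait is a body-wide rhythm)
    mean_period = 1.0 / truth.cadence_hz
    n_guess = int(np.ceil(duration_s / mean_period)) + 8
    periods = mean_period * rng.lognormal(0.0, truth.cadence_jitter_sd, n_guess)
    edges = np.concatenate([[0.0], np.cumsum(periods)])
    edges = edges[edges <= duration_s]
    n_cycles = len(edges) - 1
    if n_cycles < 2:
        raise ValueError("duration too short for two gait cycles")
    max_lag = max((c.lag for c in truth.couplings), default=0)
    if max_lag >= n_cycles:
        raise ValueError(
            f"coupling lag {max_lag} exceeds expected spike count {n_cycles}")

    base = {node: _draw_amplitudes(truth, node, n_cycles, rng)
            for node in truth.node_names}
    means = {node: float(v.mean()) for node, v in base.items()}
    final = {node: v.copy() for node, v in base.items()}
    incoming: dict[str, list[Coupling]] = {}
    for c in truth.couplings:
        incoming.setdefault(c.target, []).append(c)
    if incoming:
        for k in range(n_cycles):
            for node, edges_in in incoming.items():
                add = 0.0
                for c in edges_in:
                    if k - c.lag >= 0:
                        add += c.gain * (final[c.source][k - c.lag]
                                         - means[c.source])
                final[node][k] = np.clip(base[node][k] + add, *AMPLITUDE_CLIP)

    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    channels: dict[str, np.ndarray] = {}
    peak_times = 0.5 * (edges[:-1] + edges[1:])
    for node in truth.node_names:
        sig = np.full(len(t), BASELINE)
        for k in range(n_cycles):
            g = final[node][k]
            peak_height = BASELINE * g / (1.0 - g)
            lo, hi = edges[k], edges[k + 1]
            mask = (t >= lo) & (t < hi)
            phase = (t[mask] - lo) / (hi - lo)
            sig[mask] = BASELINE + (peak_height - BASELINE) * 0.5 * (
                1.0 - np.cos(2.0 * np.pi * phase))
        channels[node] = sig
    for tr in truth.tremors:
        channels[tr.node] = channels[tr.node] + tr.amplitude * np.sin(
            2.0 * np.pi * tr.frequency_hz * t)

    realized = replace(truth, peak_times_s=peak_times,
                       planted_values={n: final[n] for n in truth.node_names})
    rec = KinematicRecording(
        node_names=list(truth.node_names), sampling_rate_hz=rate_hz,
        channels=channels, unit="rad/s", subject_id=subject_id,
        group_label=group_label)
    return rec, realized


@dataclass
class GroupSpec:
    """Cohort-level generative parameters for one group."""

    label: str
    n_subjects: int
    node_names: list[str] = field(default_factory=lambda: ["pelvis", "foot_l", "foot_r"])
    cadence_mean_hz: float = 1.0
    cadence_sd_hz: float = 0.05
    mode_mixture: ModeMixtureSpec | None = None
    couplings: list[Coupling] = field(default_factory=list)
    gain_jitter_sd: float = 0.05
    tremors: list[Tremor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject per group")


def simulate_cohort(
    group_specs: Sequence[GroupSpec],
    duration_s: float = DEFAULT_DURATION_S,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: int = 0,
) -> list[tuple[KinematicRecording, GroundTruth]]:
    """Simulate a cohort: per-subject parameter draws around group means."""
    ss = np.random.SeedSequence(seed)
    out = []
    for spec in group_specs:
        for i in range(spec.n_subjects):
            child = ss.spawn(1)[0]
            sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            cadence = max(0.3, rng.normal(spec.cadence_mean_hz, spec.cadence_sd_hz))
            couplings = [
                Coupling(c.source, c.target,
                         gain=c.gain * float(rng.lognormal(0, spec.gain_jitter_sd)),
                         lag=c.lag)
                for c in spec.couplings]
            mixture = {}
            if spec.mode_mixture is not None:
                w = float(np.clip(rng.normal(spec.mode_mixture.mode1_weight, 0.03),
                                  0.02, 0.95))
                mixture = {node: replace(spec.mode_mixture, mode1_weight=w)
                           for node in spec.node_names}
            truth = GroundTruth(
                node_names=list(spec.node_names), cadence_hz=cadence,
                mode_mixture=mixture, couplings=couplings,
                tremors=list(spec.tremors), seed=sub_seed)
            rec, realized = simulate_subject(
                truth, duration_s, rate_hz,
                subject_id=f"{spec.label}_{i:02d}", group_label=spec.label)
            out.append((rec, realized))
    return out


def demo_group_specs(n_per_group: int = 4) -> list[GroupSpec]:
    """Two-group demo cohort with planted, opposing signatures.

    The control-like group carries a low exponential-mode weight and a
    fast, strong bidirectional foot coupling (short lag -> high force); the
    impaired-like group carries a high exponential-mode weight and a weak,
    slow coupling, mirroring the directions in which gait pathology moves
    these axes.
    """
    nodes = ["pelvis", "foot_l", "foot_r"]
    return [
        GroupSpec(
            label="control_like", n_subjects=n_per_group, node_names=list(nodes),
            mode_mixture=ModeMixtureSpec(mode1_weight=0.2),
            couplings=[Coupling("foot_l", "foot_r", gain=0.5, lag=2),
                       Coupling("foot_r", "foot_l", gain=0.5, lag=2)]),
        GroupSpec(
            label="impaired_like", n_subjects=n_per_group, node_names=list(nodes),
            mode_mixture=ModeMixtureSpec(mode1_weight=0.6),
            couplings=[Coupling("foot_l", "foot_r", gain=0.25, lag=4),
                       Coupling("foot_r", "foot_l", gain=0.25, lag=4)]),
    ]


def simulate_coupled_pair(
    n: int,
    a2: float = 0.5,
    b: float = 0.4,
    lag: int = 3,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    *,
    b_back: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct spike-domain simulation of the single-delay causal model.

    x_n = a2 x_{n-l} + b y_{n-l} + w_n with y white noise (or, with
    ``b_back`` nonzero, a mutually coupled pair simulated jointly).
    Returns (x, y) with y causing x.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    burn = 10 * lag
    total = n + burn
    wx = rng.normal(0, noise_sd, total)
    wy = rng.normal(0, noise_sd, total)
    if b_back == 0.0:
        y = wy
        drive = wx.copy()
        drive[lag:] += b * y[:-lag]
        x = sp_signal.lfilter([1.0], np.concatenate([[1.0], np.zeros(lag - 1), [-a2]]), drive)
    else:
        x = np.zeros(total)
        y = np.zeros(total)
        for k in range(total):
            xl = x[k - lag] if k >= lag else 0.0
            yl = y[k - lag] if k >= lag else 0.0
            x[k] = a2 * xl + b * yl + wx[k]
            y[k] = a2 * yl + b_back * xl + wy[k]
    return x[burn:], y[burn:]
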