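"""Synthetic dual-task redundant-target studies from specified race architectures.

Generates complete trial logs — stimulus onsets on the paradigm's delayed
exponential timeline (fixed 1000-ms delay + exponential with 2000-ms mean),
four equiprobable letter-pair conditions (TT / TL / LT / LL), a 2000-ms
timeout, bimanual button presses — together with pursuit-tracking traces
(sum-of-sinusoids target path sampled every 100 ms).  Response times come
from an explicit generative race architecture:

* ``parallel_ucip`` — unlimited-capacity independent parallel race; the
  redundant RT is the minimum of two stochastically independent channels at
  their single-target rates (statistical facilitation only).
* ``parallel_fixed`` — fixed total capacity; each channel runs at half rate
  when both targets are present (kappa = 0.5).
* ``parallel_kappa`` — per-channel rates scaled by an arbitrary kappa under
  redundant load (kappa = 1 recovers UCIP).
* ``serial_st`` — serial self-terminating scan; items inspected one at a
  time (left first with probability ``left_first_prob``), distractor
  identification costs time when a distractor is inspected before the target,
  and processing stops at the first target.
* ``coactive`` — channel activations pool into a single accumulator that
  needs ``coactive_criterion`` counts; redundant trials superpose both
  channels' rates (shifted-exponential channels only).

Dual-task load is expressed by deriving a second architecture from the
single-task one (additive non-decision slowing by default, optionally a
kappa reduction), which reproduces the "slower RTs, unchanged efficiency"
pattern of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trials import TrialRecord

ARCHITECTURES = (
    "parallel_ucip",
    "parallel_fixed",
    "parallel_kappa",
    "serial_st",
    "coactive",
)


@dataclass(frozen=True)
class ChannelModel:
    """Completion-time distribution of one processing channel.

    ``shifted_exponential`` (default): shift_ms + Exp(1/rate); the simplest
    family with closed-form race behavior.  ``lognormal``: exp(N(mu, sigma));
    offered for realism.  ``deterministic``: a constant, for degenerate
    checks.  ``rate_scale`` multiplies the processing rate, i.e. divides the
    stochastic part of the completion time.
    """

    family: str = "shifted_exponential"
    rate: float | None = 1.0 / 225.0  # events per ms (shifted_exponential)
    shift_ms: float = 0.0
    mu: float | None = None  # log-ms (lognormal)
    sigma: float | None = None
    value_ms: float | None = None  # deterministic

    def __post_init__(self) -> None:
        if self.family not in ("shifted_exponential", "lognormal", "deterministic"):
            raise ValueError(f"unknown channel family {self.family!r}")
        if self.family == "shifted_exponential" and (self.rate is None or self.rate <= 0):
            raise ValueError("shifted_exponential needs a positive rate")
        if self.family == "lognormal" and (self.mu is None or self.sigma is None):
            raise ValueError("lognormal needs mu and sigma")
        if self.family == "deterministic" and (self.value_ms is None or self.value_ms < 0):
            raise ValueError("deterministic needs a nonnegative value_ms")
        if self.shift_ms < 0:
            raise ValueError("shift_ms must be >= 0")

    def sample(self, rng: np.random.Generator, size: int, rate_scale: float = 1.0):
        if rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.family == "shifted_exponential":
            return self.shift_ms + rng.exponential(1.0 / (self.rate * rate_scale), size)
        if self.family == "lognormal":
            return self.shift_ms + rng.lognormal(self.mu, self.sigma, size) / rate_scale
        return np.full(size, self.shift_ms + self.value_ms / rate_scale)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Generative race model: channel distributions + architecture + capacity.

    ``base_time_ms`` is a shared deterministic non-decision time added once
    per trial (keeping it deterministic preserves exact hazard additivity
    under UCIP).  ``kappa`` scales per-channel rates when two targets are
    present (1 = unlimited, 0.5 = fixed total capacity).  ``lapse_rate`` is
    the probability of missing a target trial outright; ``fa_rate`` the
    probability of responding on a redundant-distractor (LL) trial.
    """

    architecture: str = "parallel_ucip"
    left: ChannelModel = field(default_factory=ChannelModel)
    right: ChannelModel = field(default_factory=ChannelModel)
    distractor: ChannelModel = field(default_factory=ChannelModel)
    base_time_ms: float = 350.0
    kappa: float = 1.0
    left_first_prob: float = 0.5
    lapse_rate: float = 0.01
    fa_rate: float = 0.09
    coactive_criterion: int = 2

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.base_time_ms < 0:
            raise ValueError("base_time_ms must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for name, p in (("left_first_prob", self.left_first_prob),
                        ("lapse_rate", self.lapse_rate), ("fa_rate", self.fa_rate)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.architecture == "coactive":
            for ch in (self.left, self.right):
                if ch.family != "shifted_exponential":
                    raise ValueError("coactive requires shifted_exponential channels")

    @property
    def effective_kappa(self) -> float:
        if self.architecture == "parallel_ucip":
            return 1.0
        if self.architecture == "parallel_fixed":
            return 0.5
        return self.kappa

    def with_dual_task_cost(self, base_shift_ms: float = 30.0,
                            kappa_scale: float = 1.0) -> "ArchitectureSpec":
        """Derive a dual-task architecture: additive non-decision slowing
        (default) and/or a capacity reduction."""
        arch = self.architecture
        kappa = self.effective_kappa * kappa_scale
        if kappa_scale != 1.0 and arch in ("parallel_ucip", "parallel_fixed"):
            arch = "parallel_kappa"
        return replace(self, architecture=arch, kappa=kappa,
                       base_time_ms=self.base_time_ms + base_shift_ms)


def sample_rts(arch: ArchitectureSpec, condition: str, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` core decision RTs (ms) for a target-present condition.

    Lapses, false alarms and the timeout are applied at the trial level
    (:func:`simulate_trial`), not here, so this is the clean race
    distribution used for calibration.
    """
    if condition == "LL":
        raise ValueError("LL trials have no target RT distribution")
    if condition not in ("TT", "TL", "LT"):
        raise ValueError(f"unknown condition {condition!r}")
    a = arch.architecture
    if a in ("parallel_ucip", "parallel_fixed", "parallel_kappa"):
        if condition == "TT":
            k = arch.effective_kappa
            t = np.minimum(arch.left.sample(rng, n, k), arch.right.sample(rng, n, k))
        elif condition == "TL":
            t = arch.left.sample(rng, n)
        else:
            t = arch.right.sample(rng, n)
    elif a == "serial_st":
        left_first = rng.random(n) < arch.left_first_prob
        if condition == "TT":
            # first item inspected is always a target
            t = np.where(left_first, arch.left.sample(rng, n),
                         arch.right.sample(rng, n))
        elif condition == "TL":
            d = arch.distractor.sample(rng, n)
            t = arch.left.sample(rng, n) + np.where(left_first, 0.0, d)
        else:
            d = arch.distractor.sample(rng, n)
            t = arch.right.sample(rng, n) + np.where(left_first, d, 0.0)
    else:  # coactive
        c = arch.coactive_criterion
        if condition == "TT":
            pooled = arch.left.rate + arch.right.rate
            t = arch.left.shift_ms + rng.gamma(c, 1.0 / pooled, n)
        elif condition == "TL":
            t = arch.left.shift_ms + rng.gamma(c, 1.0 / arch.left.rate, n)
        else:
            t = arch.right.shift_ms + rng.gamma(c, 1.0 / arch.right.rate, n)
    return arch.base_time_ms + t


def simulate_trial(arch: ArchitectureSpec, condition: str,
                   rng: np.random.Generator) -> float | None:
    """Simulate one trial; returns the decision RT in ms, or None for a
    non-response (miss, correct rejection, or lapse).

    LL trials respond only with probability ``fa_rate`` (the false-alarm RT
    is drawn from a randomly chosen single-channel race); target trials lapse
    into a miss with probability ``lapse_rate``.
    """
    if condition == "LL":
        if rng.random() < arch.fa_rate:
            side = "TL" if rng.random() < 0.5 else "LT"
            return float(sample_rts(arch, side, 1, rng)[0])
        return None
    if rng.random() < arch.lapse_rate:
        return None
    return float(sample_rts(arch, condition, 1, rng)[0])


@dataclass(frozen=True)
class SessionConfig:
    """Timeline of one testing block: 20 intervals of 60 s, delayed
    exponential inter-stimulus intervals (1000 ms fixed delay + Exp(2000 ms)
    mean), 2000-ms timeout, uniform condition probabilities.

    ``isi_from`` selects whether the ISI clock starts at stimulus offset
    (response or timeout; default) or at stimulus onset — the paradigm
    description is compatible with either reading.
    """

    n_intervals: int = 20
    interval_s: float = 60.0
    isi_delay_ms: float = 1000.0
    isi_exp_mean_ms: float = 2000.0
    timeout_ms: float = 2000.0
    condition_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    button_offset_mean_ms: float = 30.0
    button_offset_sd_ms: float = 15.0
    isi_from: str = "offset"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.condition_probs), 1.0, abs_tol=1e-9):
            raise ValueError("condition_probs must sum to 1")
        if self.isi_delay_ms < 0:
            raise ValueError("isi_delay_ms must be >= 0")
        if self.isi_from not in ("offset", "onset"):
            raise ValueError("isi_from must be 'offset' or 'onset'")


CONDITION_ORDER = ("TT", "TL", "LT", "LL")


def draw_isi_gaps(cfg: SessionConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n inter-stimulus gaps (ms) from the delayed exponential."""
    return cfg.isi_delay_ms + rng.exponential(cfg.isi_exp_mean_ms, n)


def simulate_session(
    arch: ArchitectureSpec,
    cfg: SessionConfig,
    participant_id: str,
    task_load: str = "single",
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Simulate one block of intervals, returning trial records.

    Onsets are placed sequentially within each interval: the next onset is
    the previous stimulus offset (response, or timeout for non-responses)
    plus a delayed-exponential gap; events are truncated at the interval end.
    Each response emits two button RTs (the second press trails the first by
    |N(30, 15)| ms, truncated at the timeout); only the minimum enters
    analysis downstream.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    interval_ms = cfg.interval_s * 1000.0
    probs = np.asarray(cfg.condition_probs)
    records: list[TrialRecord] = []
    for interval in range(1, cfg.n_intervals + 1):
        t = 0.0
        while True:
            onset = t + float(draw_isi_gaps(cfg, 1, rng)[0])
            if onset >= interval_ms:
                break
            condition = CONDITION_ORDER[rng.choice(4, p=probs)]
            rt = simulate_trial(arch, condition, rng)
            if rt is not None and rt >= cfg.timeout_ms:
                rt = None  # response would land after the timeout: scored a miss
            if rt is None:
                rec = TrialRecord(
                    participant_id=participant_id, task_load=task_load,
                    interval_index=interval, onset_ms=onset, condition=condition,
                    rt_left_ms=None, rt_right_ms=None, responded=False,
                )
                offset = onset + cfg.timeout_ms
            else:
                lag = abs(rng.normal(cfg.button_offset_mean_ms, cfg.button_offset_sd_ms))
                second = min(rt + lag, cfg.timeout_ms)
                if rng.random() < 0.5:
                    rt_left, rt_right = rt, second
                else:
                    rt_left, rt_right = second, rt
                rec = TrialRecord(
                    participant_id=participant_id, task_load=task_load,
                    interval_index=interval, onset_ms=onset, condition=condition,
                    rt_left_ms=rt_left, rt_right_ms=rt_right, responded=True,
                )
                offset = onset + rt
            records.append(rec)
            t = onset if cfg.isi_from == "onset" else offset
    return records


def simulate_cohort(
    arch_single: ArchitectureSpec,
    n_participants: int,
    cfg: SessionConfig,
    arch_dual: ArchitectureSpec | None = None,
    participant_prefix: str = "P",
) -> list[TrialRecord]:
    """Simulate a full study: one single-task block per participant and, if
    ``arch_dual`` is given, a dual-task block as well (within-participant
    design).  Per-participant random streams are spawned from ``cfg.seed``
    via ``numpy.random.SeedSequence`` so cohorts are reproducible and
    participants statistically independent.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_participants)
    records: list[TrialRecord] = []
    width = max(2, len(str(n_participants)))
    for i, child in enumerate(children, start=1):
        pid = f"{participant_prefix}{i:0{width}d}"
        rng = np.random.default_rng(child)
        records.extend(simulate_session(arch_single, cfg, pid, "single", rng))
        if arch_dual is not None:
            records.extend(simulate_session(arch_dual, cfg, pid, "dual", rng))
    return records


# ---------------------------------------------------------------------------
# pursuit tracking


@dataclass(frozen=True)
class TrackingConfig:
    """Sum-of-sinusoids pursuit target and a first-order manual controller.

    The target position is an angle (deg) along the tracking arc,
    theta(t) = sum_i A_i sin(2 pi f_i t + phi_i) with component frequencies
    0.07, 0.15 and 0.23 Hz and random per-interval phases.  Amplitudes
    default to equal thirds of the 90-deg arc half-range.  The cursor follows
    a discrete first-order pursuit law with lag, proportional gain and motor
    noise, its speed clamped at ``max_rate_deg_s`` (the cursor's rate limit;
    the target path is not clamped).  Both series are sampled every 100 ms.
    """

    frequencies_hz: tuple[float, ...] = (0.07, 0.15, 0.23)
    amplitudes_deg: tuple[float, ...] | None = None
    arc_half_range_deg: float = 90.0
    controller_lag_ms: float = 200.0
    controller_gain: float = 0.8
    controller_noise_sd_deg: float = 1.5
    sample_period_ms: float = 100.0
    max_rate_deg_s: float = 80.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.frequencies_hz):
            raise ValueError("frequencies must be positive")
        if self.sample_period_ms <= 0:
            raise ValueError("sample_period_ms must be positive")
        if self.amplitudes_deg is not None and len(self.amplitudes_deg) != len(
            self.frequencies_hz
        ):
            raise ValueError("one amplitude per frequency component required")

    @property
    def amplitudes(self) -> np.ndarray:
        if self.amplitudes_deg is not None:
            return np.asarray(self.amplitudes_deg, dtype=float)
        k = len(self.frequencies_hz)
        return np.full(k, self.arc_half_range_deg / k)


@dataclass
class TrackingTrace:
    """Target and cursor angle series (deg) sampled on a common clock."""

    t_ms: np.ndarray
    target_deg: np.ndarray
    cursor_deg: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_ms": self.t_ms, "target_deg": self.target_deg,
             "cursor_deg": self.cursor_deg}
        )


def target_path(cfg: TrackingConfig, t_s: np.ndarray, phases: np.ndarray) -> np.ndarray:
    freqs = np.asarray(cfg.frequencies_hz)
    amps = cfg.amplitudes
    return np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t_s[None, :]
                               + phases[:, None]),
        axis=0,
    )


def simulate_tracking(
    cfg: TrackingConfig,
    interval_s: float = 60.0,
    rng: np.random.Generator | None = None,
    active: bool = True,
) -> TrackingTrace:
    """Simulate one tracking interval.

    ``active=False`` leaves the cursor parked at the arc center (the
    single-task baseline in which the participant ignores the tracking
    display), yielding chance-level error.
    """
    if rng is None:
        rng = np.random.default_rng()
    dt_s = cfg.sample_period_ms / 1000.0
    n = int(round(interval_s / dt_s)) + 1
    t_ms = np.arange(n) * cfg.sample_period_ms
    phases = rng.uniform(0, 2 * np.pi, len(cfg.frequencies_hz))
    target = target_path(cfg, t_ms / 1000.0, phases)
    cursor = np.zeros(n)
    if active:
        lag_steps = int(round(cfg.controller_lag_ms / cfg.sample_period_ms))
        max_step = cfg.max_rate_deg_s * dt_s
        for k in range(1, n):
            ref = target[max(k - lag_steps, 0)]
            move = cfg.controller_gain * (ref - cursor[k - 1])
            move = float(np.clip(move, -max_step, max_step))
            noise = rng.normal(0.0, cfg.controller_noise_sd_deg) if \
                cfg.controller_noise_sd_deg > 0 else 0.0
            cursor[k] = cursor[k - 1] + move + noise
    return TrackingTrace(t_ms=t_ms, target_deg=target, cursor_deg=cursor)


def rmse_angular(target_deg, cursor_deg=None) -> float:
    """Root mean squared angular error (deg) between cursor and target."""
    if cursor_deg is None:  # accept a TrackingTrace
        trace = target_deg
        target_deg, cursor_deg = trace.target_deg, trace.cursor_deg
    target_deg = np.asarray(target_deg, dtype=float)
    cursor_deg = np.asarray(cursor_deg, dtype=float)
    if target_deg.shape != cursor_deg.shape:
        raise ValueError(
            f"length mismatch: target has {target_deg.size} samples, "
            f"cursor has {cursor_deg.size}"
        )
    return float(np.sqrt(np.mean((cursor_deg - target_deg) ** 2)))


def write_tracking_trace(trace: TrackingTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def simulate_participant_rts(
    arch: ArchitectureSpec,
    n_per_condition: int,
    rng: np.random.Generator,
    conditions: Sequence[str] = ("TT", "TL", "LT"),
) -> dict[str, np.ndarray]:
    """Draw clean per-condition RT samples for one simulated participant
    (calibration shortcut that skips the session timeline)."""
    return {c: sample_rts(arch, c, n_per_condition, rng) for c in conditions}
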