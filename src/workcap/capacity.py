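"""Workload capacity and resilience measures for redundant-target RTs.

Under a first-terminating (OR) stopping rule, an unlimited-capacity
independent parallel (UCIP) race predicts that the integrated hazard of the
redundant-target condition equals the sum of the single-target integrated
hazards.  The capacity coefficient

    C(t) = H_AB(t) / (H_A(t) + H_B(t))

is 1 under UCIP, > 1 for super-capacity, < 1 for limited capacity, and 0.5
when total capacity is fixed (zero-sum between channels).  When the
single-target conditions contain a distractor in the empty location, the same
ratio computed from the distractor-present single-target hazards H_AX, H_XB
is called resilience, R(t); a serial self-terminating system with negligible
distractor cost pins R(t) at 0.5 and R(t) grows with distractor cost.

The standardized score (Cz for capacity designs, Rz for resilience designs)
collapses the curve into a single asymptotically standard-normal z value via
a counting-process martingale contrast of the redundant hazard against the
sum of the single hazards; 0 means UCIP-level efficiency, positive means
super-capacity.  The Miller (race model) inequality F_AB <= F_A + F_B and the
Grice inequality F_AB >= max(F_A, F_B) bound UCIP performance from above and
below at the distribution level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hazard import HazardEstimate, ecdf_at, estimate_cumulative_hazard

DEFAULT_GRID_QUANTILES = (0.01, 0.99)


def default_grid(*samples, quantiles=DEFAULT_GRID_QUANTILES) -> np.ndarray:
    """Pooled distinct RTs between the given quantiles of the combined sample."""
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    lo, hi = np.quantile(pooled, quantiles)
    t = np.unique(pooled)
    return t[(t >= lo) & (t <= hi)]


@dataclass
class CapacityCurve:
    """C(t) or R(t) evaluated on a time grid (undefined points dropped)."""

    grid: np.ndarray
    values: np.ndarray
    kind: str  # "capacity" | "resilience"
    n_dropped: int = 0

    @property
    def time_average(self) -> float:
        """Unweighted mean of the curve over its (defined) grid."""
        return float(np.mean(self.values))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.grid, self.kind: self.values})


def _hazard_ratio_curve(
    numerator: HazardEstimate,
    denominators: tuple[HazardEstimate, HazardEstimate],
    grid,
    kind: str,
) -> CapacityCurve:
    if grid is None:
        grid = np.unique(
            np.concatenate(
                [numerator.jump_times] + [d.jump_times for d in denominators]
            )
        )
    grid = np.asarray(grid, dtype=float)
    num = numerator.at(grid)
    den = denominators[0].at(grid) + denominators[1].at(grid)
    defined = den > 0
    if not np.any(defined):
        raise ValueError(
            f"{kind} coefficient undefined: denominator hazard is zero on the "
            "entire grid"
        )
    n_dropped = int(np.sum(~defined))
    return CapacityCurve(
        grid=grid[defined], values=num[defined] / den[defined], kind=kind,
        n_dropped=n_dropped,
    )


def capacity_coefficient(
    h_ab: HazardEstimate, h_a: HazardEstimate, h_b: HazardEstimate, grid=None
) -> CapacityCurve:
    """C(t) = H_AB(t) / (H_A(t) + H_B(t)) on ``grid``.

    Points where the denominator is zero are dropped (never imputed); if no
    grid is given the pooled jump times of the three estimates are used.
    """
    return _hazard_ratio_curve(h_ab, (h_a, h_b), grid, "capacity")


def resilience_coefficient(
    h_ab: HazardEstimate, h_ax: HazardEstimate, h_xb: HazardEstimate, grid=None
) -> CapacityCurve:
    """R(t) = H_AB(t) / (H_AX(t) + H_XB(t)), the distractor-present analogue
    of the capacity coefficient."""
    return _hazard_ratio_curve(h_ab, (h_ax, h_xb), grid, "resilience")


def capacity_from_samples(redundant, single_a, single_b, grid=None,
                          kind: str = "capacity") -> CapacityCurve:
    """Convenience: estimate the three hazards and form the ratio curve.

    If no grid is given, the pooled distinct RTs between the 1st and 99th
    percentile of the combined sample are used.
    """
    if grid is None:
        grid = default_grid(redundant, single_a, single_b)
    h_ab = estimate_cumulative_hazard(redundant)
    h_a = estimate_cumulative_hazard(single_a)
    h_b = estimate_cumulative_hazard(single_b)
    return _hazard_ratio_curve(h_ab, (h_a, h_b), grid, kind)


@dataclass(frozen=True)
class StandardizedScore:
    """Standardized UCIP contrast (Cz / Rz): z = numerator / sqrt(variance)."""

    z: float
    numerator: float
    variance: float
    n: dict[str, int]


def standardized_ucip_z(redundant, single_1, single_2, min_n: int = 10) -> StandardizedScore:
    """Standardized capacity/resilience score against the UCIP benchmark.

    Contrasts the redundant-condition cumulative hazard with the sum of the
    two single-condition hazards via the counting-process form

        D   = sum_t L(t) [dN_r(t)/Y_r(t) - dN_1(t)/Y_1(t) - dN_2(t)/Y_2(t)]
        Var = sum_t L(t)^2 [dN_r/Y_r^2 + dN_1/Y_1^2 + dN_2/Y_2^2]
        z   = D / sqrt(Var)

    where N_k counts responses, Y_k is the at-risk count, and the weight
    L(t) = Y_r (Y_1 + Y_2) / (Y_r + Y_1 + Y_2) is predictable, so D is a
    mean-zero martingale under the UCIP null and z is asymptotically standard
    normal.  Positive z = super-capacity (redundant hazard above the UCIP
    sum); negative z = limited capacity.

    When the single-target samples come from distractor-present conditions
    the score is an Rz; from distractor-absent conditions, a Cz.
    """
    samples = {
        "redundant": np.asarray(redundant, dtype=float),
        "single_1": np.asarray(single_1, dtype=float),
        "single_2": np.asarray(single_2, dtype=float),
    }
    for name, s in samples.items():
        if s.size < min_n:
            raise ValueError(
                f"sample {name!r} has {s.size} observations; at least "
                f"{min_n} are required"
            )
    pooled = np.unique(np.concatenate(list(samples.values())))
    dN = {}
    Y = {}
    for name, s in samples.items():
        s_sorted = np.sort(s)
        # events at each pooled time; at risk just before it
        left = np.searchsorted(s_sorted, pooled, side="left")
        right = np.searchsorted(s_sorted, pooled, side="right")
        dN[name] = (right - left).astype(float)
        Y[name] = (s.size - left).astype(float)

    ok = (Y["redundant"] > 0) & (Y["single_1"] > 0) & (Y["single_2"] > 0)
    Yr, Y1, Y2 = Y["redundant"][ok], Y["single_1"][ok], Y["single_2"][ok]
    L = Yr * (Y1 + Y2) / (Yr + Y1 + Y2)
    D = np.sum(
        L * (dN["redundant"][ok] / Yr - dN["single_1"][ok] / Y1 - dN["single_2"][ok] / Y2)
    )
    V = np.sum(
        L**2 * (dN["redundant"][ok] / Yr**2 + dN["single_1"][ok] / Y1**2
                + dN["single_2"][ok] / Y2**2)
    )
    if V <= 0:
        raise ValueError("variance estimate is zero; degenerate samples")
    return StandardizedScore(
        z=float(D / np.sqrt(V)),
        numerator=float(D),
        variance=float(V),
        n={k: int(v.size) for k, v in samples.items()},
    )


@dataclass
class BoundCheckResult:
    """Race-model (Miller) and Grice bound checks on a time grid."""

    grid: np.ndarray
    f_redundant: np.ndarray
    miller_bound: np.ndarray
    grice_bound: np.ndarray
    miller_violation: np.ndarray = field(default=None)
    grice_violation: np.ndarray = field(default=None)

    @property
    def any_miller_violation(self) -> bool:
        return bool(np.any(self.miller_violation))

    @property
    def miller_violation_fraction(self) -> float:
        return float(np.mean(self.miller_violation))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ms": self.grid,
                "F_redundant": self.f_redundant,
                "miller_bound": self.miller_bound,
                "grice_bound": self.grice_bound,
                "miller_violation": self.miller_violation,
                "grice_violation": self.grice_violation,
            }
        )


def race_model_bounds(redundant, single_1, single_2, grid=None) -> BoundCheckResult:
    """Check the Miller and Grice inequalities on empirical CDFs.

    Miller (race-model) bound: F_r(t) <= min(F_1(t) + F_2(t), 1); exceeding
    it anywhere is evidence of super-capacity.  Grice bound:
    F_r(t) >= max(F_1(t), F_2(t)); falling below it indicates extreme
    capacity limitation.  The Grice bound never exceeds the Miller bound.
    """
    for name, s in (("redundant", redundant), ("single_1", single_1),
                    ("single_2", single_2)):
        if len(np.atleast_1d(s)) == 0:
            raise ValueError(f"sample {name!r} is empty")
    if grid is None:
        grid = default_grid(redundant, single_1, single_2, quantiles=(0.0, 1.0))
    grid = np.asarray(grid, dtype=float)
    f_r = ecdf_at(redundant, grid)
    f_1 = ecdf_at(single_1, grid)
    f_2 = ecdf_at(single_2, grid)
    miller = np.minimum(f_1 + f_2, 1.0)
    grice = np.maximum(f_1, f_2)
    return BoundCheckResult(
        grid=grid,
        f_redundant=f_r,
        miller_bound=miller,
        grice_bound=grice,
        miller_violation=f_r > miller,
        grice_violation=f_r < grice,
    )


def plot_capacity_curve(curve: CapacityCurve, ax=None, **kwargs):
    """Plot C(t)/R(t) with the UCIP (1.0) and fixed-capacity (0.5) benchmarks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(curve.grid, curve.values, where="post", **kwargs)
    ax.axhline(1.0, ls="--", c="gray", lw=0.8)
    ax.axhline(0.5, ls=":", c="gray", lw=0.8)
    ax.set_xlabel("t (ms)")
    ax.set_ylabel("C(t)" if curve.kind == "capacity" else "R(t)")
    return ax
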