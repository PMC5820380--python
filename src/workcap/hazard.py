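"""Nelson-Aalen estimation of the cumulative hazard of response times.

The hazard h(t) of a speeded response is the instantaneous probability of a
response at time t given none has occurred yet; its integral H(t) is the
cumulative (integrated) hazard.  With n observed RTs and no censoring, the
Nelson-Aalen estimator jumps at each distinct RT by d_i / n_i, where d_i is
the number of responses tied at that time and n_i the number still at risk
(RT >= t_i).  H(t) is the right-continuous running sum of those increments.

The per-jump increments, risk-set sizes and variance terms are kept because
the standardized capacity/resilience score needs them, not just H(t) itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HazardEstimate:
    """Right-continuous step estimate of a cumulative hazard H(t).

    Attributes
    ----------
    jump_times : ndarray
        Strictly increasing distinct event times (ms).
    increments : ndarray
        Per-jump Nelson-Aalen increments d_i / n_i.
    events : ndarray
        Tied event counts d_i at each jump.
    n_at_risk : ndarray
        Risk-set sizes n_i just before each jump.
    variance_increments : ndarray
        Per-jump variance terms d_i / n_i**2 (Poisson-type estimator).
    n : int
        Sample size.
    """

    jump_times: np.ndarray
    increments: np.ndarray
    events: np.ndarray
    n_at_risk: np.ndarray
    variance_increments: np.ndarray
    n: int

    @property
    def values(self) -> np.ndarray:
        """Cumulative hazard at each jump time (right-continuous)."""
        return np.cumsum(self.increments)

    def at(self, t) -> np.ndarray:
        """Evaluate H(t) at arbitrary times (0 before the first jump)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        H = np.concatenate([[0.0], self.values])
        return H[idx]

    def variance_at(self, t) -> np.ndarray:
        """Estimated variance of H(t) at arbitrary times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        V = np.concatenate([[0.0], np.cumsum(self.variance_increments)])
        return V[idx]


def estimate_cumulative_hazard(rts) -> HazardEstimate:
    """Nelson-Aalen cumulative-hazard estimate from an uncensored RT sample.

    Parameters
    ----------
    rts : array-like
        Correct-response RTs in ms; at least 2 observations, all positive.
        Ties are handled by aggregated event counts.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot estimate a hazard from an empty sample")
    if rts.size < 2:
        raise ValueError("need at least 2 observations to estimate a hazard")
    if np.any(rts <= 0) or not np.all(np.isfinite(rts)):
        raise ValueError("all RTs must be positive and finite")
    times, counts = np.unique(rts, return_counts=True)
    # at risk just before t_i: everyone with RT >= t_i
    n_at_risk = rts.size - np.concatenate([[0], np.cumsum(counts[:-1])])
    increments = counts / n_at_risk
    return HazardEstimate(
        jump_times=times,
        increments=increments,
        events=counts,
        n_at_risk=n_at_risk,
        variance_increments=counts / n_at_risk**2,
        n=int(rts.size),
    )


def ecdf_at(sample, t) -> np.ndarray:
    """Empirical CDF of ``sample`` evaluated at times ``t``."""
    sample = np.sort(np.asarray(sample, dtype=float))
    t = np.asarray(t, dtype=float)
    return np.searchsorted(sample, t, side="right") / sample.size
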