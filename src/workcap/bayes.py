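"""Hierarchical Bayesian estimation for RTs, resilience scores, and tracking
error, via Markov chain Monte Carlo.

The RT model is an additive normal ANOVA with participant and condition
effects (optionally task load and its interaction with condition):

    Y ~ N(a0 + a_participant + a_condition [+ a_load + a_load.condition], sigma_y^2)

with data-scaled vague priors: the grand mean a0 ~ N(M, (100*SD)^2), the
residual sd sigma_y ~ Uniform(SD/1000, SD*1000), each effect family's
deflections ~ N(0, sigma_effect^2), and a vague gamma prior on each
sigma_effect, where M and SD are the observed response mean and sd.
Deflections are constrained to sum to zero across the cells of the design
(recentred after every sweep, with the absorbed mass pushed into a0).

The effect-sd gamma prior is parameterized by mode SD/2 and sd 2*SD
(Kruschke's convention for this model family), converted internally to
shape/rate; a literal shape = SD/2, rate = 2*SD reading is available through
:class:`EffectSdPrior` but is strongly informative near zero and is not the
default.

Sampling is Gibbs where conditionals are conjugate (location parameters;
sigma_y and the one-sample sigma reduce to truncated inverse-gamma draws
under the uniform-on-sigma prior) with scalar slice-sampling updates on
log(sigma) for the non-conjugate effect sds (the correlation model uses
componentwise Metropolis).  Convergence is monitored with the Gelman-Rubin
potential scale reduction factor; the conventional adequacy criterion is
R-hat <= 1.01.

Models follow a Model / Results split: construct a model from data, call
``fit()`` to obtain a results object carrying draws, summaries, credible
intervals, contrasts and diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special


# ---------------------------------------------------------------------------
# configuration and priors


@dataclass(frozen=True)
class McmcConfig:
    """MCMC protocol: chains, burn-in, retained-phase steps (per chain), thin.

    The default is the desk-scale protocol (4 chains x 25,000 steps, thin 5,
    1000 burn-in -> 20,000 retained draws).  :meth:`full_protocol` gives the
    full-scale protocol whose thinned retained count is 50,000 per chain set
    (4 chains x 62,500 steps / thin 5).
    """

    n_chains: int = 4
    burn_in: int = 1000
    steps: int = 25_000
    thin: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.steps < self.thin or self.thin < 1:
            raise ValueError("invalid MCMC configuration")

    @property
    def retained_per_chain(self) -> int:
        return self.steps // self.thin

    @property
    def total_retained(self) -> int:
        return self.retained_per_chain * self.n_chains

    @classmethod
    def full_protocol(cls, seed: int | None = None) -> "McmcConfig":
        return cls(n_chains=4, burn_in=1000, steps=62_500, thin=5, seed=seed)

    @classmethod
    def smoke(cls, seed: int | None = None) -> "McmcConfig":
        """Very short protocol for quick checks."""
        return cls(n_chains=4, burn_in=200, steps=2_000, thin=5, seed=seed)


def gamma_shape_rate_from_mode_sd(mode: float, sd: float) -> tuple[float, float]:
    """Shape/rate of a gamma distribution with the given mode and sd."""
    if mode < 0 or sd <= 0:
        raise ValueError("mode must be >= 0 and sd > 0")
    rate = (mode + math.sqrt(mode**2 + 4 * sd**2)) / (2 * sd**2)
    shape = 1.0 + mode * rate
    return shape, rate


@dataclass(frozen=True)
class EffectSdPrior:
    """Gamma prior on an effect-family standard deviation.

    ``mode_sd`` (default): gamma with mode = SD/2 and sd = 2*SD, a vague
    prior scaled to the data.  ``shape_rate``: gamma with shape = SD/2 and
    rate = 2*SD literally; note that for SD on the order of 10^2 this
    concentrates the prior near SD/ (4 SD) = 0.25 with tiny spread and will
    shrink all effects essentially to zero — it is provided for comparison,
    not recommended.
    """

    parameterization: str = "mode_sd"

    def shape_rate(self, data_sd: float) -> tuple[float, float]:
        if self.parameterization == "mode_sd":
            return gamma_shape_rate_from_mode_sd(data_sd / 2.0, 2.0 * data_sd)
        if self.parameterization == "shape_rate":
            return data_sd / 2.0, 2.0 * data_sd
        raise ValueError(f"unknown parameterization {self.parameterization!r}")


# ---------------------------------------------------------------------------
# low-level samplers


def _sample_sigma_uniform_prior(
    sse: float, n: int, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Draw sigma from p(sigma) ~ sigma^-n exp(-sse / 2 sigma^2) on [lo, hi].

    Under the flat-on-sigma prior this is an inverse-gamma draw for sigma^2
    with shape (n-1)/2 and scale sse/2, truncated to [lo^2, hi^2]; sampled
    exactly by inverse-CDF.
    """
    shape = (n - 1) / 2.0
    scale = sse / 2.0
    if scale <= 0:
        return float(lo)
    # InvGamma(shape, scale) CDF at x is gammaincc(shape, scale / x)
    flo = special.gammaincc(shape, scale / lo**2)
    fhi = special.gammaincc(shape, scale / hi**2)
    if fhi - flo < 1e-12:
        # posterior mass falls (numerically) outside the prior support
        return float(np.clip(math.sqrt(scale / (shape + 1.0)), lo, hi))
    u = rng.uniform(flo, fhi)
    return float(math.sqrt(scale / special.gammainccinv(shape, u)))


def _slice_effect_sigma(
    sigma: float,
    deflections: np.ndarray,
    shape: float,
    rate: float,
    rng: np.random.Generator,
    width: float = 1.0,
    floor: float = 1e-12,
) -> float:
    """Slice-sampling update of log(sigma) for an effect-sd with gamma prior
    (stepping-out construction; a rejection-free within-Gibbs scalar move
    that keeps mixing through the shrinkage funnel).

    ``floor`` bounds sigma away from zero so that near-degenerate effect
    families (all deflections shrunk to ~0) cannot underflow.
    """
    J = deflections.size
    ssq = float(np.sum(deflections**2))
    log_floor = math.log(floor)

    def logf(x: float) -> float:
        # gamma(shape, rate) prior on sigma, normal likelihood of J
        # deflections, plus the log-parameterization Jacobian
        if x < log_floor or x > 700.0:
            return -math.inf
        s = math.exp(x)
        return (shape - J) * x - rate * s - ssq / (2.0 * s * s)

    x0 = math.log(max(sigma, floor))
    y = logf(x0) - rng.exponential(1.0)
    # step out
    L = x0 - width * rng.random()
    R = L + width
    for _ in range(50):
        if logf(L) <= y:
            break
        L -= width
    for _ in range(50):
        if logf(R) <= y:
            break
        R += width
    # shrink
    for _ in range(100):
        x1 = rng.uniform(L, R)
        if logf(x1) > y:
            return max(math.exp(x1), floor)
        if x1 < x0:
            L = x1
        else:
            R = x1
    return max(sigma, floor)


def gelman_rubin(chains) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is an (m, n) array of m chains with n draws each.  Identical
    chains give 1.0 (the within-chain variance is zero only when every chain
    is constant, in which case the chains agree trivially).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 chains")
    m, n = x.shape
    means = x.mean(axis=1)
    W = float(np.mean(x.var(axis=1, ddof=1)))
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_hat = (n - 1) / n * W + B / n
    # the PSRF is reported on [1, inf): sampling noise can push the raw
    # ratio fractionally below 1 (exactly sqrt((n-1)/n) for identical chains)
    return max(float(math.sqrt(var_hat / W)), 1.0)


# ---------------------------------------------------------------------------
# posterior summaries


@dataclass(frozen=True)
class PosteriorSummary:
    """Mean and central credible interval of a scalar posterior."""

    mean: float
    lower: float
    upper: float
    n_draws: int
    rhat: float | None = None
    effect_size: float | None = None


def summarize_draws(draws, interval_mass: float = 0.95, hdi: bool = False) -> PosteriorSummary:
    """Posterior mean and credible interval of a draw vector.

    Central equal-tailed interval by default; ``hdi=True`` gives the highest
    density interval instead.
    """
    x = np.ravel(np.asarray(draws, dtype=float))
    if x.size == 0:
        raise ValueError("empty draws")
    if not 0 < interval_mass < 1:
        raise ValueError("interval_mass must lie in (0, 1)")
    if hdi:
        n = x.size
        xs = np.sort(x)
        k = max(int(math.floor(interval_mass * n)), 1)
        if k >= n:
            lo, hi = xs[0], xs[-1]
        else:
            widths = xs[k:] - xs[: n - k]
            i = int(np.argmin(widths))
            lo, hi = xs[i], xs[i + k]
    else:
        alpha = (1 - interval_mass) / 2
        lo, hi = np.quantile(x, [alpha, 1 - alpha])
    return PosteriorSummary(mean=float(x.mean()), lower=float(lo), upper=float(hi),
                            n_draws=int(x.size))


class McmcResults:
    """Base results object: named draw arrays of shape (chains, draws, ...)."""

    def __init__(self, draws: dict[str, np.ndarray], labels: dict[str, list],
                 config: McmcConfig):
        self.draws = draws
        self.labels = labels
        self.config = config

    def flat_draws(self) -> dict[str, np.ndarray]:
        """Flatten vector parameters into scalar series keyed 'name[level]'."""
        out: dict[str, np.ndarray] = {}
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
                labs = self.labels.get(name)
                for j in range(flat.shape[2]):
                    lab = labs[j] if labs is not None else j
                    out[f"{name}[{lab}]"] = flat[:, :, j]
        return out

    def gelman_rubin(self) -> pd.Series:
        return pd.Series({k: gelman_rubin(v) for k, v in self.flat_draws().items()})

    @property
    def max_rhat(self) -> float:
        return float(self.gelman_rubin().max())

    def converged(self, threshold: float = 1.01) -> bool:
        return self.max_rhat <= threshold

    def summary(self, interval_mass: float = 0.95, hdi: bool = False) -> pd.DataFrame:
        rows = {}
        rhats = self.gelman_rubin()
        for name, arr in self.flat_draws().items():
            s = summarize_draws(arr, interval_mass, hdi)
            rows[name] = {
                "mean": s.mean, "lower": s.lower, "upper": s.upper,
                "rhat": rhats[name], "n_draws": s.n_draws,
            }
        return pd.DataFrame(rows).T

    def to_frame(self) -> pd.DataFrame:
        """All retained draws as a tidy DataFrame (columnar text friendly)."""
        flat = self.flat_draws()
        cols = {name: arr.reshape(-1) for name, arr in flat.items()}
        n = next(iter(cols.values())).size
        chains = np.repeat(np.arange(self.config.n_chains),
                           n // self.config.n_chains)
        return pd.DataFrame({"chain": chains, **cols})


# ---------------------------------------------------------------------------
# hierarchical ANOVA on RTs


def _cell_stats(y, idx_arrays, shape):
    """Per-cell counts, sums, and the total sum of squares."""
    flat = np.ravel_multi_index(idx_arrays, shape)
    size = int(np.prod(shape))
    n = np.bincount(flat, minlength=size).reshape(shape).astype(float)
    s = np.bincount(flat, weights=y, minlength=size).reshape(shape)
    return n, s, float(np.sum(y * y))


class HierarchicalRTModel:
    """Additive hierarchical normal model of per-trial (or per-cell) RTs.

    One-way design: participant + condition.  Passing ``task_load`` gives
    the two-way design with additive load and load x condition effects.

    Parameters
    ----------
    data : DataFrame
        One row per observation.
    response, participant, condition, task_load : str
        Column names; ``task_load=None`` selects the one-way design.
    effect_sd_prior : EffectSdPrior
        Prior family for the effect standard deviations.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "rt_ms",
        participant: str = "participant_id",
        condition: str = "condition",
        task_load: str | None = None,
        effect_sd_prior: EffectSdPrior = EffectSdPrior(),
    ):
        y = np.asarray(data[response], dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        self.y = y
        self.participants = pd.Categorical(data[participant])
        self.conditions = pd.Categorical(data[condition])
        if len(self.participants.categories) < 2:
            raise ValueError("need at least 2 participants")
        if len(self.conditions.categories) < 2:
            raise ValueError("need at least 2 conditions")
        self.loads = None
        if task_load is not None:
            self.loads = pd.Categorical(data[task_load])
            if len(self.loads.categories) < 2:
                raise ValueError("need at least 2 task-load levels")
        self.effect_sd_prior = effect_sd_prior
        self.M = float(y.mean())
        self.SD = float(y.std(ddof=1)) if y.size > 1 else 1.0
        if self.SD == 0:
            self.SD = max(abs(self.M), 1.0) * 1e-6

    @property
    def design(self) -> str:
        return "one_way" if self.loads is None else "two_way"

    def fit(self, mcmc: McmcConfig | None = None) -> "HierarchicalRTResults":
        mcmc = mcmc or McmcConfig()
        if self.design == "one_way":
            draws, labels = self._fit_one_way(mcmc)
        else:
            draws, labels = self._fit_two_way(mcmc)
        return HierarchicalRTResults(draws, labels, mcmc, model=self)

    # -- samplers ----------------------------------------------------------

    def _prior_consts(self):
        M, SD = self.M, self.SD
        shape, rate = self.effect_sd_prior.shape_rate(SD)
        return dict(
            M=M, SD=SD, a0_var=(100.0 * SD) ** 2,
            sig_lo=SD / 1000.0, sig_hi=SD * 1000.0,
            eff_shape=shape, eff_rate=rate,
        )

    def _fit_one_way(self, mcmc: McmcConfig):
        y = self.y
        p_idx = np.asarray(self.participants.codes)
        c_idx = np.asarray(self.conditions.codes)
        P = len(self.participants.categories)
        C = len(self.conditions.categories)
        n_pc, s_pc, sumsq = _cell_stats(y, (p_idx, c_idx), (P, C))
        n_p, n_c = n_pc.sum(axis=1), n_pc.sum(axis=0)
        s_p, s_c = s_pc.sum(axis=1), s_pc.sum(axis=0)
        total_sum, N = float(y.sum()), y.size
        pc = self._prior_consts()
        R = mcmc.retained_per_chain
        out = {
            "a0": np.empty((mcmc.n_chains, R)),
            "a_participant": np.empty((mcmc.n_chains, R, P)),
            "a_condition": np.empty((mcmc.n_chains, R, C)),
            "sigma_y": np.empty((mcmc.n_chains, R)),
            "sigma_participant": np.empty((mcmc.n_chains, R)),
            "sigma_condition": np.empty((mcmc.n_chains, R)),
        }
        for ci, child in enumerate(np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)):
            rng = np.random.default_rng(child)
            a0 = pc["M"] + rng.normal(0, pc["SD"] / 10)
            ap = np.where(n_p > 0, s_p / np.maximum(n_p, 1) - pc["M"], 0.0)
            ac = np.where(n_c > 0, s_c / np.maximum(n_c, 1) - pc["M"], 0.0)
            ap -= ap.mean()
            ac -= ac.mean()
            sy = pc["SD"]
            sp = max(float(np.std(ap)), pc["SD"] / 10)
            sc = max(float(np.std(ac)), pc["SD"] / 10)
            r = 0
            for it in range(mcmc.burn_in + mcmc.steps):
                inv_sy2 = 1.0 / (sy * sy)
                # a0 | rest (conjugate normal)
                resid = total_sum - float(n_p @ ap) - float(n_c @ ac)
                prec = N * inv_sy2 + 1.0 / pc["a0_var"]
                mean = (resid * inv_sy2 + pc["M"] / pc["a0_var"]) / prec
                a0 = rng.normal(mean, 1.0 / math.sqrt(prec))
                # participant deflections (conjugate, vectorized)
                Sp = s_p - n_p * a0 - n_pc @ ac
                prec_p = n_p * inv_sy2 + 1.0 / (sp * sp)
                ap = rng.normal(Sp * inv_sy2 / prec_p, 1.0 / np.sqrt(prec_p))
                # condition deflections
                Sc = s_c - n_c * a0 - n_pc.T @ ap
                prec_c = n_c * inv_sy2 + 1.0 / (sc * sc)
                ac = rng.normal(Sc * inv_sy2 / prec_c, 1.0 / np.sqrt(prec_c))
                # sum-to-zero recentring (absorb means into a0)
                mp, mc = ap.mean(), ac.mean()
                ap -= mp
                ac -= mc
                a0 += mp + mc
                # residual sd
                mu = a0 + ap[:, None] + ac[None, :]
                sse = sumsq - 2.0 * float(np.sum(mu * s_pc)) + float(np.sum(n_pc * mu * mu))
                sy = _sample_sigma_uniform_prior(max(sse, 0.0), N,
                                                pc["sig_lo"], pc["sig_hi"], rng)
                # effect sds (Metropolis on log sigma)
                sp = _slice_effect_sigma(sp, ap, pc["eff_shape"], pc["eff_rate"], rng)
                sc = _slice_effect_sigma(sc, ac, pc["eff_shape"], pc["eff_rate"], rng)
                k = it - mcmc.burn_in
                if k >= 0 and (k + 1) % mcmc.thin == 0 and r < R:
                    out["a0"][ci, r] = a0
                    out["a_participant"][ci, r] = ap
                    out["a_condition"][ci, r] = ac
                    out["sigma_y"][ci, r] = sy
                    out["sigma_participant"][ci, r] = sp
                    out["sigma_condition"][ci, r] = sc
                    r += 1
        labels = {
            "a_participant": list(self.participants.categories),
            "a_condition": list(self.conditions.categories),
        }
        return out, labels

    def _fit_two_way(self, mcmc: McmcConfig):
        y = self.y
        p_idx = np.asarray(self.participants.codes)
        l_idx = np.asarray(self.loads.codes)
        c_idx = np.asarray(self.conditions.codes)
        P = len(self.participants.categories)
        L = len(self.loads.categories)
        C = len(self.conditions.categories)
        n_cell, s_cell, sumsq = _cell_stats(y, (p_idx, l_idx, c_idx), (P, L, C))
        N, total_sum = y.size, float(y.sum())
        n_p = n_cell.sum(axis=(1, 2))
        n_l = n_cell.sum(axis=(0, 2))
        n_c = n_cell.sum(axis=(0, 1))
        n_lc = n_cell.sum(axis=0)
        s_p = s_cell.sum(axis=(1, 2))
        s_l = s_cell.sum(axis=(0, 2))
        s_c = s_cell.sum(axis=(0, 1))
        s_lc = s_cell.sum(axis=0)
        pc = self._prior_consts()
        R = mcmc.retained_per_chain
        out = {
            "a0": np.empty((mcmc.n_chains, R)),
            "a_participant": np.empty((mcmc.n_chains, R, P)),
            "a_task_load": np.empty((mcmc.n_chains, R, L)),
            "a_condition": np.empty((mcmc.n_chains, R, C)),
            "a_interaction": np.empty((mcmc.n_chains, R, L, C)),
            "sigma_y": np.empty((mcmc.n_chains, R)),
            "sigma_participant": np.empty((mcmc.n_chains, R)),
            "sigma_task_load": np.empty((mcmc.n_chains, R)),
            "sigma_condition": np.empty((mcmc.n_chains, R)),
            "sigma_interaction": np.empty((mcmc.n_chains, R)),
        }
        for ci, child in enumerate(np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)):
            rng = np.random.default_rng(child)
            a0 = pc["M"] + rng.normal(0, pc["SD"] / 10)
            ap = np.zeros(P)
            al = np.zeros(L)
            ac = np.zeros(C)
            alc = np.zeros((L, C))
            sy = pc["SD"]
            sp = sl = sc = slc = pc["SD"] / 4
            r = 0
            for it in range(mcmc.burn_in + mcmc.steps):
                inv_sy2 = 1.0 / (sy * sy)
                # a0
                resid = (total_sum - float(n_p @ ap) - float(n_l @ al)
                         - float(n_c @ ac) - float(np.sum(n_lc * alc)))
                prec = N * inv_sy2 + 1.0 / pc["a0_var"]
                mean = (resid * inv_sy2 + pc["M"] / pc["a0_var"]) / prec
                a0 = rng.normal(mean, 1.0 / math.sqrt(prec))
                # participant deflections
                other = a0 + al[None, :, None] + ac[None, None, :] + alc[None, :, :]
                Sp = s_p - np.sum(n_cell * other, axis=(1, 2))
                prec_p = n_p * inv_sy2 + 1.0 / (sp * sp)
                ap = rng.normal(Sp * inv_sy2 / prec_p, 1.0 / np.sqrt(prec_p))
                # load deflections
                other = a0 + ap[:, None, None] + ac[None, None, :] + alc[None, :, :]
                Sl = s_l - np.sum(n_cell * other, axis=(0, 2))
                prec_l = n_l * inv_sy2 + 1.0 / (sl * sl)
                al = rng.normal(Sl * inv_sy2 / prec_l, 1.0 / np.sqrt(prec_l))
                # condition deflections
                other = a0 + ap[:, None, None] + al[None, :, None] + alc[None, :, :]
                Sc = s_c - np.sum(n_cell * other, axis=(0, 1))
                prec_c = n_c * inv_sy2 + 1.0 / (sc * sc)
                ac = rng.normal(Sc * inv_sy2 / prec_c, 1.0 / np.sqrt(prec_c))
                # interaction deflections
                other = a0 + ap[:, None, None] + al[None, :, None] + ac[None, None, :]
                Slc = s_lc - np.sum(n_cell * other, axis=0)
                prec_lc = n_lc * inv_sy2 + 1.0 / (slc * slc)
                alc = rng.normal(Slc * inv_sy2 / prec_lc, 1.0 / np.sqrt(prec_lc))
                # sum-to-zero: double-centre the interaction, recentre mains
                r_l = alc.mean(axis=1)
                r_c = alc.mean(axis=0)
                g = alc.mean()
                alc = alc - r_l[:, None] - r_c[None, :] + g
                al = al + r_l
                ac = ac + r_c
                a0 -= g
                mp, ml, mc2 = ap.mean(), al.mean(), ac.mean()
                ap -= mp
                al -= ml
                ac -= mc2
                a0 += mp + ml + mc2
                # residual sd
                mu = a0 + ap[:, None, None] + al[None, :, None] \
                    + ac[None, None, :] + alc[None, :, :]
                sse = sumsq - 2.0 * float(np.sum(mu * s_cell)) \
                    + float(np.sum(n_cell * mu * mu))
                sy = _sample_sigma_uniform_prior(max(sse, 0.0), N,
                                                pc["sig_lo"], pc["sig_hi"], rng)
                sp = _slice_effect_sigma(sp, ap, pc["eff_shape"], pc["eff_rate"], rng)
                sl = _slice_effect_sigma(sl, al, pc["eff_shape"], pc["eff_rate"], rng)
                sc = _slice_effect_sigma(sc, ac, pc["eff_shape"], pc["eff_rate"], rng)
                slc = _slice_effect_sigma(slc, alc.ravel(), pc["eff_shape"],
                                       pc["eff_rate"], rng)
                k = it - mcmc.burn_in
                if k >= 0 and (k + 1) % mcmc.thin == 0 and r < R:
                    out["a0"][ci, r] = a0
                    out["a_participant"][ci, r] = ap
                    out["a_task_load"][ci, r] = al
                    out["a_condition"][ci, r] = ac
                    out["a_interaction"][ci, r] = alc
                    out["sigma_y"][ci, r] = sy
                    out["sigma_participant"][ci, r] = sp
                    out["sigma_task_load"][ci, r] = sl
                    out["sigma_condition"][ci, r] = sc
                    out["sigma_interaction"][ci, r] = slc
                    r += 1
        conds = list(self.conditions.categories)
        loads = list(self.loads.categories)
        labels = {
            "a_participant": list(self.participants.categories),
            "a_task_load": loads,
            "a_condition": conds,
            "a_interaction": [f"{l}.{c}" for l in loads for c in conds],
        }
        return out, labels


@dataclass(frozen=True)
class ContrastSummary:
    """Posterior contrast: mean difference, credible interval, effect size.

    ``effect_size`` is the posterior mean difference divided by the posterior
    mean residual sd (a standardized mean difference on the observation
    scale).
    """

    mean: float
    lower: float
    upper: float
    effect_size: float

    @property
    def excludes_zero(self) -> bool:
        return self.lower > 0 or self.upper < 0


class HierarchicalRTResults(McmcResults):
    def __init__(self, draws, labels, config, model: HierarchicalRTModel):
        super().__init__(draws, labels, config)
        self.model = model

    def _level_draws(self, factor: str, level) -> np.ndarray:
        labs = self.labels[factor]
        try:
            j = labs.index(level)
        except ValueError:
            raise KeyError(f"{level!r} is not a level of {factor}: {labs}") from None
        return self.draws[factor][:, :, j]

    def level_mean(self, factor: str, level, interval_mass: float = 0.95) -> PosteriorSummary:
        """Posterior of a0 + deflection for one level of a factor (a
        marginal cell mean, other factors at their sum-to-zero baseline)."""
        d = self.draws["a0"] + self._level_draws(factor, level)
        return summarize_draws(d, interval_mass)

    def contrast(self, factor: str, level_a, level_b,
                 interval_mass: float = 0.95) -> ContrastSummary:
        """Posterior of (level_a - level_b) for a factor's deflections."""
        d = self._level_draws(factor, level_a) - self._level_draws(factor, level_b)
        s = summarize_draws(d, interval_mass)
        d_eff = s.mean / float(self.draws["sigma_y"].mean())
        return ContrastSummary(mean=s.mean, lower=s.lower, upper=s.upper,
                               effect_size=d_eff)

    def cell_mean(self, load, condition, interval_mass: float = 0.95) -> PosteriorSummary:
        """Two-way designs: posterior mean RT for a (load, condition) cell."""
        if "a_task_load" not in self.draws:
            raise ValueError("cell_mean requires the two-way design")
        loads = self.labels["a_task_load"]
        conds = self.labels["a_condition"]
        li, cj = loads.index(load), conds.index(condition)
        d = (self.draws["a0"] + self.draws["a_task_load"][:, :, li]
             + self.draws["a_condition"][:, :, cj]
             + self.draws["a_interaction"][:, :, li, cj])
        return summarize_draws(d, interval_mass)


# ---------------------------------------------------------------------------
# one-sample model


class OneSampleModel:
    """One-sample normal model Y ~ N(u, sigma^2) with data-scaled priors
    u ~ N(M, (100*SD)^2) and sigma ~ Uniform(SD/1000, SD*1000)."""

    def __init__(self, values):
        y = np.ravel(np.asarray(values, dtype=float))
        if y.size < 2:
            raise ValueError("need at least 2 values")
        if not np.all(np.isfinite(y)):
            raise ValueError("values contain non-finite entries")
        self.y = y
        self.M = float(y.mean())
        sd = float(y.std(ddof=1))
        self.SD = sd if sd > 0 else max(abs(self.M), 1.0) * 1e-6

    def fit(self, mcmc: McmcConfig | None = None) -> "OneSampleResults":
        mcmc = mcmc or McmcConfig()
        y, n = self.y, self.y.size
        M, SD = self.M, self.SD
        a0_var = (100.0 * SD) ** 2
        lo, hi = SD / 1000.0, SD * 1000.0
        total = float(y.sum())
        sumsq = float(np.sum(y * y))
        R = mcmc.retained_per_chain
        out = {"u": np.empty((mcmc.n_chains, R)),
               "sigma": np.empty((mcmc.n_chains, R))}
        for ci, child in enumerate(np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)):
            rng = np.random.default_rng(child)
            u, sig = M + rng.normal(0, SD / 10), SD
            r = 0
            for it in range(mcmc.burn_in + mcmc.steps):
                prec = n / sig**2 + 1.0 / a0_var
                mean = (total / sig**2 + M / a0_var) / prec
                u = rng.normal(mean, 1.0 / math.sqrt(prec))
                sse = sumsq - 2 * u * total + n * u * u
                sig = _sample_sigma_uniform_prior(max(sse, 0.0), n, lo, hi, rng)
                k = it - mcmc.burn_in
                if k >= 0 and (k + 1) % mcmc.thin == 0 and r < R:
                    out["u"][ci, r] = u
                    out["sigma"][ci, r] = sig
                    r += 1
        return OneSampleResults(out, {}, mcmc, n=n)


class OneSampleResults(McmcResults):
    def __init__(self, draws, labels, config, n: int):
        super().__init__(draws, labels, config)
        self.n = n

    def mean_summary(self, interval_mass: float = 0.95) -> PosteriorSummary:
        s = summarize_draws(self.draws["u"], interval_mass)
        d = s.mean / float(self.draws["sigma"].mean())
        return replace(s, effect_size=d)


# ---------------------------------------------------------------------------
# Bayesian correlation


@dataclass(frozen=True)
class CorrelationResult:
    """Posterior of a bivariate-normal correlation."""

    r: float
    lower: float
    upper: float
    n: int

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


class BayesianCorrelation:
    """Bivariate-normal model of paired scores; the correlation gets a
    uniform prior on (-1, 1), means and sds the usual data-scaled vague
    priors.  Sampled by componentwise random-walk Metropolis on
    (mu1, mu2, log s1, log s2, atanh rho)."""

    def __init__(self, x, y):
        x = np.ravel(np.asarray(x, dtype=float))
        y = np.ravel(np.asarray(y, dtype=float))
        if x.size != y.size:
            raise ValueError("x and y must be paired (equal length)")
        if x.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values")
        self.x, self.y = x, y

    def fit(self, mcmc: McmcConfig | None = None) -> CorrelationResult:
        mcmc = mcmc or McmcConfig()
        x, y = self.x, self.y
        n = x.size
        Sx, Sy = float(x.sum()), float(y.sum())
        Sxx, Syy, Sxy = float(x @ x), float(y @ y), float(x @ y)
        Mx, My = Sx / n, Sy / n
        SDx = max(float(x.std(ddof=1)), 1e-9)
        SDy = max(float(y.std(ddof=1)), 1e-9)
        bounds = ((SDx / 1000, SDx * 1000), (SDy / 1000, SDy * 1000))

        def log_post(th) -> float:
            m1, m2, ls1, ls2, z = th
            s1, s2 = math.exp(ls1), math.exp(ls2)
            if not (bounds[0][0] <= s1 <= bounds[0][1]):
                return -math.inf
            if not (bounds[1][0] <= s2 <= bounds[1][1]):
                return -math.inf
            rho = math.tanh(z)
            om = 1.0 - rho * rho
            Qxx = Sxx - 2 * m1 * Sx + n * m1 * m1
            Qyy = Syy - 2 * m2 * Sy + n * m2 * m2
            Qxy = Sxy - m1 * Sy - m2 * Sx + n * m1 * m2
            ll = (-n * (math.log(2 * math.pi) + ls1 + ls2 + 0.5 * math.log(om))
                  - (Qxx / s1**2 - 2 * rho * Qxy / (s1 * s2) + Qyy / s2**2)
                  / (2 * om))
            lp = (-0.5 * (m1 - Mx) ** 2 / (100 * SDx) ** 2
                  - 0.5 * (m2 - My) ** 2 / (100 * SDy) ** 2
                  + math.log(om))  # uniform rho: Jacobian d rho / d z = 1 - rho^2
            return ll + lp

        steps = np.array([SDx / math.sqrt(n), SDy / math.sqrt(n), 0.25, 0.25, 0.3])
        r_emp = float(np.corrcoef(x, y)[0, 1]) if n > 2 else 0.0
        r_emp = float(np.clip(np.nan_to_num(r_emp), -0.99, 0.99))
        R = mcmc.retained_per_chain
        rho_draws = np.empty((mcmc.n_chains, R))
        for ci, child in enumerate(np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)):
            rng = np.random.default_rng(child)
            th = np.array([Mx, My, math.log(SDx), math.log(SDy), math.atanh(r_emp)])
            th += rng.normal(0, 0.05, 5) * np.array([SDx, SDy, 1, 1, 1])
            lp = log_post(th)
            r = 0
            for it in range(mcmc.burn_in + mcmc.steps):
                for j in range(5):
                    prop = th.copy()
                    prop[j] += rng.normal(0.0, steps[j])
                    lp_new = log_post(prop)
                    if math.log(rng.random()) < lp_new - lp:
                        th, lp = prop, lp_new
                k = it - mcmc.burn_in
                if k >= 0 and (k + 1) % mcmc.thin == 0 and r < R:
                    rho_draws[ci, r] = math.tanh(th[4])
                    r += 1
        s = summarize_draws(rho_draws)
        return CorrelationResult(r=s.mean, lower=s.lower, upper=s.upper, n=n)


def fit_one_sample(values, mcmc: McmcConfig | None = None) -> OneSampleResults:
    """Convenience wrapper: fit the one-sample model to per-participant scores."""
    return OneSampleModel(values).fit(mcmc)
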