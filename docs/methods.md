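# Methods

This note records the statistical model behind `workcap`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## Trial scoring and exclusion

A trial presents one of four equiprobable letter-pair conditions — TT
(redundant targets), TL (target left), LT (target right), LL (redundant
distractors) — and times out after 2000 ms. Responses are bimanual; the
analysis RT is the faster of the two button presses. Outcomes follow from
(condition, responded): hits and misses on target-present trials, false
alarms and correct rejections on LL. RT analysis uses correct target-present
trials only.

Error screening: a participant is excluded when their false-alarm rate or
any per-condition miss rate is *strictly greater* than 0.30 (the capacity
measures are robust up to roughly that error level); a rate of exactly 0.30
is retained. Exclusion applies at the participant level — failing in either
task-load block removes both blocks. Responses faster than 100 ms are
flagged anticipatory but kept by default, since the paradigm itself imposes
no floor; `drop_anticipatory=True` removes them.

All times are milliseconds throughout. A log whose RTs all fall below 20 is
rejected as being in seconds (magnitude heuristic), since a silent unit
error would corrupt every downstream hazard.

Single-target conditions are coded two ways: by side (left/right, to test
lateral asymmetries) and by speed (fast/slow single target per participant,
by mean RT). Ties in the speed coding break to the left condition,
deterministically. The redundancy gain is mean(fast single) −
mean(redundant); this is deliberately conservative relative to the
mean-of-both-singles convention, which is also reported.

## Hazard estimation

Cumulative hazards are estimated per participant and condition with the
Nelson–Aalen estimator on correct-response RTs: at each distinct RT the
estimate jumps by d_i / n_i (tied events over the at-risk count). Variance
increments use the Poisson-type form d_i / n_i².

Misses and timeouts are *discarded, not censored*. This mirrors standard
practice for this paradigm (correct trials only) but slightly biases the
hazard upward when miss rates are non-negligible; with the ≤ 0.30 exclusion
rule and the very low miss rates typical of the task the effect is
negligible. This is a known caveat, not a modelling claim.

C(t) and R(t) are pointwise ratios of step functions evaluated on a grid;
the default grid is the pooled distinct RTs between the 1st and 99th
percentile of the combined sample. Grid points where the denominator hazard
is zero are dropped (never imputed) and counted on the returned curve.

## The standardized score (Cz / Rz)

The UCIP null H_AB = H_A + H_B is tested with a counting-process contrast:

    D   = Σ_t L(t) [dN_AB/Y_AB − dN_A/Y_A − dN_B/Y_B]
    Var = Σ_t L(t)² [dN_AB/Y_AB² + dN_A/Y_A² + dN_B/Y_B²]
    z   = D / sqrt(Var)

with the log-rank-type predictable weight L = Y_AB (Y_A + Y_B) /
(Y_AB + Y_A + Y_B). Because L depends only on at-risk counts, D is a
mean-zero martingale under the null and z is asymptotically standard
normal; positive z means super-capacity. The exact weighting used by
published implementations is not specified anywhere we could verify against,
so the statistic is validated by simulation calibration instead: under a
UCIP generator at 72 trials/condition the score has sd ≈ 1.00 and a small
positive finite-sample mean of ≈ +0.03 (10,000 replicates). The raw
contrast D is unbiased; the offset comes from correlation between D and its
variance estimate and shrinks with sample size. Calibration experiments
showed the offset is insensitive to risk-set truncation of the weight, so
the simplest form is kept. Samples below 10 observations per condition are
refused (configurable).

Race-model bounds are computed on empirical CDFs: Miller,
F_AB ≤ min(F_A + F_B, 1); Grice, F_AB ≥ max(F_A, F_B). Note that under
exact UCIP the Miller bound is asymptotically *tight* in the lower tail
(margin F_A·F_B → 0), so pointwise empirical "violations" there are
expected sampling noise; systematic violation is a matter of magnitude,
which is how the tests treat it.

## Synthetic studies

The generator reproduces the paradigm's structure so the full pipeline can
be exercised end to end:

* **Timeline** — each block has 20 intervals of 60 s. Stimulus onsets are
  placed sequentially: next onset = previous stimulus offset (response, or
  the 2000-ms timeout) + 1000 ms fixed delay + Exponential(mean 2000 ms).
  The memoryless exponential makes onsets unpredictable beyond the 1000-ms
  floor; the mean gap is 3000 ms. Whether the paradigm's ISI clock ran from
  onset or offset is not decidable from its description, so both are
  available (`isi_from="offset"` is the default). With these defaults a
  block yields roughly 75–85 correct trials per target condition; observed
  counts are logged, not enforced.
* **Conditions** — drawn uniformly from TT/TL/LT/LL.
* **Responses** — the second button press trails the first by
  |Normal(30, 15)| ms truncated at the timeout, with the leading thumb
  chosen at random; only the minimum enters analysis, so this is cosmetic
  fidelity.
* **Race architectures** — channels default to shifted-exponential
  completion times (rate 1/225 ms⁻¹) plus a shared deterministic
  non-decision time of 350 ms, giving single-target means near 575 ms,
  the scale seen in practice for this task. The shifted exponential is the
  simplest family with closed-form race behaviour, and a deterministic base
  preserves exact hazard additivity under UCIP; lognormal channels are
  offered for realism (additivity then holds only approximately early on).
  `parallel_kappa` scales per-channel rates by κ when both targets are
  present (κ = 1 UCIP, κ = 0.5 fixed). `serial_st` scans items one at a
  time (left first with probability `left_first_prob`, default 0.5), pays
  the distractor-identification time when a distractor is inspected first,
  and stops at the first target. `coactive` pools the two channels'
  activations into one accumulator needing `coactive_criterion` counts.
  Misses arise from a 0.01 lapse rate and responses landing after the
  timeout; LL trials respond with probability `fa_rate` = 0.09. Both rates
  match the low error levels typical of the task.
* **Dual-task load** — derived from the single-task architecture, by
  default as +30 ms of non-decision time (the "slower RTs, unchanged
  efficiency" scenario); a κ reduction is available to generate the
  capacity-drain alternative.
* **Tracking** — the target angle along the arc is a sum of sinusoids at
  0.07, 0.15 and 0.23 Hz with random per-interval phases. Component
  amplitudes are not specified by the paradigm description; the default is
  equal amplitudes summing to the 90° arc half-range. The cursor follows a
  first-order pursuit controller (200-ms lag, gain 0.8, motor noise sd
  1.5°), its speed clamped at 80°/s — the clamp applies to the cursor only.
  Both series sample every 100 ms. An idle cursor (`active=False`) gives
  the chance-level error of a participant ignoring the tracking display.
  RMSE is the root mean squared angular difference over all samples.
* **Seeds** — cohorts spawn per-participant `numpy.random.SeedSequence`
  children from the master seed, so runs are bit-reproducible and
  participants statistically independent.

A serial scan note: with distractors at least as costly as targets, R(t)
exceeds 1 in the early portion of the curve (before distractor-first trials
resolve) and declines later; the time-averaged curve therefore understates
the early super-capacity, while the standardized score weights the early
region by its larger risk sets. R(t) grows monotonically with distractor
cost, from the 0.5 limit at negligible cost.

What the generator does **not** emulate: sequential dependencies and
fatigue across trials, RT–accuracy interactions, visual-crowding
psychophysics (forced-serial processing is represented only by the
`serial_st` architecture switch), eye movements, or motor-response
correlations between the detection and tracking tasks. Passing calibration
tests therefore demonstrates correctness of the estimators under the stated
race models, not robustness to every feature of human data.

## Hierarchical Bayesian models

RTs are modelled as an additive normal ANOVA:

    Y ~ N(a0 + a_participant + a_condition [+ a_load + a_load×condition], σ_y²)

with data-scaled vague priors (M, SD are the observed response mean and sd):
a0 ~ N(M, (100·SD)²); σ_y ~ Uniform(SD/1000, SD·1000); each effect family's
deflections ~ N(0, σ_effect²); σ_effect ~ Gamma. Deflections are
constrained to sum to zero across the cells of the design, enforced by
recentring after every sweep with the absorbed means pushed into a0 (and
double-centring for the interaction) — standard for this model family.
One-sample scores (Rz, RMSE) use Y ~ N(u, σ²) with the same prior pattern.

**Effect-sd prior parameterization.** The prior is specified by the pair
(SD/2, 2·SD). Read literally as gamma shape/rate this concentrates σ_effect
near 0.25 with negligible spread for SD ~ 100 — a strongly informative
prior that shrinks every effect essentially to zero, which contradicts both
the "vague prior" intent and any ability to detect effects. The
convention this model family actually uses (Kruschke's) specifies the gamma
by *mode* SD/2 and *sd* 2·SD, converted to shape/rate; that is the package
default. The literal reading remains available as
`EffectSdPrior("shape_rate")` and is exercised in the tests to document its
shrinkage behaviour.

**Sampling.** Location parameters are conjugate and Gibbs-sampled from
per-cell sufficient statistics (counts, sums), so sweep cost is independent
of trial count. Under the uniform-on-σ prior, σ_y (and the one-sample σ)
has an inverse-gamma conditional for σ² with shape (n−1)/2 and scale SSE/2,
truncated to the prior support and drawn exactly by inverse-CDF
(`gammaincc`/`gammainccinv`). The non-conjugate effect-sds are updated by
stepping-out slice sampling on log σ, which mixes reliably through the
shrinkage funnel that defeats a fixed-step Metropolis kernel; a floor of
1e-12 guards against numerical underflow when an effect family is fully
shrunk. The bivariate-normal correlation model (uniform prior on ρ over
(−1, 1), vague priors on means and sds) is sampled by componentwise
random-walk Metropolis on (μ₁, μ₂, log σ₁, log σ₂, atanh ρ) using O(1)
sufficient statistics.

**Protocol.** The full-scale protocol is 4 chains × 1000 burn-in + 62,500
steps thinned by 5 — 50,000 retained draws per chain set. (The protocol
this follows is described elsewhere as "250,000 steps each … leaving a
total of 50,000 samples", which is internally inconsistent by a factor of
four; the retained total of 50,000 is taken as authoritative.) The package
default is the desk-scale 4 × 25,000/thin 5 (20,000 retained), which on
these conjugate-heavy models yields Gelman–Rubin statistics ≤ 1.01
comfortably; `McmcConfig.full_protocol()` restores the full scale.

**Diagnostics and summaries.** Convergence is monitored with the classic
Gelman–Rubin potential scale reduction factor per parameter, reported on
[1, ∞) (the raw ratio is exactly √((n−1)/n) for identical chains) and
cross-checked against `arviz.rhat` in the tests; ≤ 1.01 is treated as
adequate and failures are reported, never silently accepted. Credible
intervals are central equal-tailed by default — the convention is not
otherwise pinned down — with highest-density intervals available
(`hdi=True`). The effect size d for a contrast is the posterior mean
difference divided by the posterior mean of σ_y; this is one reasonable
standardized-mean-difference convention among several, so printed d values
from other sources are not directly comparable.

## Pipeline

`run_study_analysis` chains the stages (acquire → score → error rates and
exclusions → per-participant coding, gains, Rz, RMSE → group models →
report) and aborts with a stage-named diagnostic on any failure. Reports
are JSON-native and round-trip losslessly; every reported quantity is the
direct output of an upstream operation. The full pipeline is
bit-reproducible under a fixed seed and MCMC scale.

## Problem sizes used in validation

The calibration suite uses 10,000 trials per condition for the C(t)/R(t)
benchmarks, 500 simulated participants × 72 trials/condition for the
standardized-score null calibration, 10⁵ gaps for the timeline floor, a
27-participant × 2-load × 3-condition × 72-trial cohort at 4 × 25,000 MCMC
steps for the convergence check, and 20 replications of a 12-participant
cohort at 4 × 2,500 steps for interval coverage. These sizes give
Monte-Carlo error comfortably inside each stated tolerance while keeping
the suite desk-scale.

## Known limitations

* Hazards treat misses/timeouts as absent rather than censored (see above).
* The standardized score carries a small positive finite-sample offset
  (≈ +0.03 at 72 trials/condition) that vanishes asymptotically.
* The normal likelihood for RTs is the convention of this model family, not
  a claim that RTs are normal; skew mainly inflates σ_y.
* Architecture identification (e.g., survivor-interaction contrasts) is out
  of scope; the measures here quantify efficiency, not architecture.
* The simulator's tracking controller is a deliberately simple first-order
  pursuit law — adequate for RMSE plumbing, not a model of human manual
  control.
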