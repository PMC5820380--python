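# workcap

Workload capacity and resilience analysis of redundant-target response
times under single- and dual-task load.

## The problem

In a redundant-target detection task an observer responds as soon as a
target appears on either of two channels (e.g., letters in the left and
right visual periphery), under a first-terminating (OR) stopping rule.
Redundant targets are usually detected faster than single targets — the
redundant signals effect — but a faster mean tells you nothing about *how
efficiently* the two channels run together. The benchmark is the
unlimited-capacity independent parallel (UCIP) race model, whose only
speed-up is statistical facilitation: the response is the minimum of two
independent channel finishing times, so its integrated hazards are additive,
H_AB(t) = H_A(t) + H_B(t).

The workload capacity coefficient compares an observed redundant-target
hazard against that benchmark:

    C(t) = H_AB(t) / (H_A(t) + H_B(t))

C(t) = 1 is UCIP, C(t) > 1 super-capacity, C(t) < 1 limited capacity, and
C(t) = 0.5 fixed total capacity. When the "empty" location holds a
distractor on single-target trials, the same ratio built from the
distractor-present single-target hazards H_AX, H_XB is called resilience,
R(t); a serial self-terminating scan with negligible distractor cost pins
R(t) at 0.5 and R(t) rises as distractor identification gets costlier. The
curve is summarised by a standardized score (Cz / Rz): a counting-process
contrast of the redundant hazard against the sum of the single hazards,
divided by its estimated standard error — asymptotically standard normal
under UCIP, positive for super-capacity, negative for limited capacity.
The Miller race-model inequality F_AB ≤ F_A + F_B and the Grice inequality
F_AB ≥ max(F_A, F_B) bound UCIP performance at the distribution level.

The package is written for researchers in mathematical psychology and human
factors who want to run this analysis end to end: ingest per-trial logs,
apply standard scoring and exclusion rules (faster of two button presses,
strict 0.30 error-rate cutoff), estimate Nelson–Aalen cumulative hazards
per participant, compute C(t)/R(t), Cz/Rz and the race-model bounds, and
fit hierarchical Bayesian group models (additive participant / condition /
task-load effects with data-scaled vague priors, sum-to-zero constraints,
Gibbs-within-MCMC sampling, Gelman–Rubin diagnostics). A generative
simulator produces complete synthetic studies — parallel (UCIP / fixed /
arbitrary-kappa), serial self-terminating and coactive race architectures
embedded in the paradigm's delayed-exponential stimulus timeline, plus
sum-of-sinusoids pursuit-tracking traces — so every stage is testable
without any data download.

## Worked example

Simulate one participant from a *fixed-capacity* parallel race (the two
channels share a fixed total rate, so each runs at half speed on redundant
trials), then score a group of 25 such participants:

```python
import numpy as np
import workcap as wc

rng = np.random.default_rng(7)
arch = wc.ArchitectureSpec(architecture="parallel_fixed")
rts = wc.simulate_participant_rts(arch, 72, rng)

curve = wc.capacity_from_samples(rts["TT"], rts["TL"], rts["LT"],
                                 kind="resilience")
score = wc.standardized_ucip_z(rts["TT"], rts["TL"], rts["LT"])
print(f"mean RT  left={rts['TL'].mean():.0f} ms  right={rts['LT'].mean():.0f} ms  "
      f"redundant={rts['TT'].mean():.0f} ms")
print(f"time-averaged R(t) = {curve.time_average:.2f}")
print(f"standardized resilience Rz = {score.z:.2f}")

zs = [wc.standardized_ucip_z(*(lambda r: (r["TT"], r["TL"], r["LT"]))(
          wc.simulate_participant_rts(arch, 72, rng))).z
      for _ in range(25)]
res = wc.fit_one_sample(zs, wc.McmcConfig(seed=7))
s = res.mean_summary()
print(f"group Rz = {s.mean:.2f}, 95% BCI [{s.lower:.2f}, {s.upper:.2f}], "
      f"max R-hat = {res.max_rhat:.3f}")
```

Output:

```
mean RT  left=569 ms  right=557 ms  redundant=613 ms
time-averaged R(t) = 0.46
standardized resilience Rz = -5.85
group Rz = -5.18, 95% BCI [-5.49, -4.86], max R-hat = 1.000
```

Redundant trials are *slower* than singles here because halving each
channel's rate more than cancels statistical facilitation; the resilience
curve sits at the fixed-capacity benchmark 0.5 and the group Rz is credibly
below the UCIP value of 0. Re-running with `architecture="parallel_ucip"`
gives R(t) ≈ 1 and a group Rz interval covering 0.

## Command line

```
workcap simulate  -n 25 --seed 1 -o out/        # cohort -> trial log + manifest
workcap analyze   -i out/trial_log.csv -o rep/  # logs -> full study report
workcap calibrate --architecture serial_st      # C/R benchmark table
```

`analyze` runs the whole chain — scoring, exclusions, both RT codings
(left/right and fast/slow single target), redundancy gains under both the
conservative fast-single and the mean-single conventions, per-participant
Rz, tracking RMSE, hierarchical Bayesian group models, and the Rz–RMSE
correlation — and writes `report.json`, `participants.csv` and a
human-readable `summary.txt`.

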