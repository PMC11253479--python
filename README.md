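# hfnctrial

A Bayesian adaptive trial design toolkit for weaning high-flow nasal cannula
(HFNC) support in infants with bronchiolitis.

Pragmatic, EHR-embedded trials of HFNC weaning use a time-to-event primary
endpoint — the duration of HFNC from order placement to final weaning (first
documented flow < 4 L/min with no later flow ≥ 4 L/min, capped at 30 days) —
and adaptive posterior-probability stopping rules. This package provides the
statistical machinery for designing, simulating and analyzing such a trial:

- **`MSplinePHModel` / `MSplinePHResults`** — a semiparametric Bayesian
  proportional-hazards model. The weaning hazard in arm *a* is

  ```
  h(t | a) = exp(β₀) · Σⱼ γⱼ Mⱼ(t) · exp(β·a)
  ```

  with cubic M-splines `Mⱼ` (two boundary knots, two internal knots at
  equally spaced percentiles of the uncensored durations), a flat Dirichlet
  prior on the simplex weights γ, and a weakly informative N(0, 2.5²) prior
  on the log hazard ratio β. `fit()` runs an adaptive Metropolis reference
  sampler (with split-chain R-hat diagnostics) or a fast Laplace
  approximation, and the results object answers the trial's posterior
  queries `P(HR > 1)` and `P(HR < 1.15)`.
- **Decision engine** — the interim rules (stop superior if P(HR > 1) > 0.99;
  stop futile if P(HR < 1.15) > 0.8) and the final four-way classification
  (superior > 0.9, promising > 0.8, futile, inconclusive).
- **Virtual-trial simulator** — Poisson accrual, 1:1 parity randomization,
  a Weibull baseline calibrated to a 35-hour median with a 6.08-hour median
  reduction at HR 1.27, interim analyses at 12/18/24 months, maximum
  enrollment 350, and operating-characteristics aggregation with
  Monte-Carlo standard errors.
- **Endpoint derivation** — the primary-endpoint rule applied to
  flowsheet-style event logs (order rows, flow rows, ventilation-mode rows),
  including the positive-pressure-ventilation clock-restart rule, plus a
  synthetic event-log generator for end-to-end testing.

## Worked example

Generate a 300-encounter synthetic cohort with a true intervention effect of
HR 1.27, derive the primary endpoint from the event logs, and fit the model:

```python
import hfnctrial as ht

baseline = ht.calibrate_baseline()          # Weibull: median 35 h, HR 1.27 ≙ −6.08 h
logs = ht.generate_event_log(ht.CohortSpec(n_encounters=300), baseline,
                             hr_by_arm=(1.0, 1.27), seed=11)
table = ht.derive_cohort_endpoints(logs)    # one row per encounter
ds = ht.endpoints_to_survival(table)        # (time_hours, event, arm)

res = ht.MSplinePHModel(ds).fit(method="mcmc", seed=11)
print("P(HR > 1)    =", round(res.prob_hr_greater(1.0), 3))
print("P(HR < 1.15) =", round(res.prob_hr_less(1.15), 3))
print("posterior HR =", round(res.hr_mean, 3),
      "95% CI", tuple(round(x, 3) for x in res.hr_interval()))
d = ht.evaluate_interim(res.prob_hr_greater(1.0), res.prob_hr_less(1.15),
                        ht.DesignConfig(), stage=1)
print("interim action:", d.action.value)
```

prints

```
P(HR > 1)    = 0.973
P(HR < 1.15) = 0.223
posterior HR = 1.267 95% CI (0.994, 1.602)
interim action: continue
```


The posterior recovers the simulated HR of 1.27; at 300 encounters the
evidence is strong (97% posterior probability of benefit) but does not cross
the strict 0.99 interim superiority threshold, so this interim look would
continue the trial.

The same pipeline is available from the shell:

```
hfnctrial calibrate                 # baseline Weibull and medians at HR 1/1.15/1.27
hfnctrial generate --n 300          # synthetic flowsheet event log
hfnctrial endpoints out/event_log.tsv
hfnctrial km out/survival.tsv
hfnctrial fit out/survival.tsv --method mcmc
hfnctrial oc --replicates 500       # operating characteristics + plots
```

`hfnctrial calibrate` reports the calibrated Weibull (shape 1.2526, scale
46.90 h) whose analytic median is exactly 35.00 h, with reductions of 3.70 h
at HR 1.15 (the ≈4-hour futility margin) and 6.08 h at HR 1.27.

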