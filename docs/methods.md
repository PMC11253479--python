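# Methods

## The model

The primary endpoint is a right-censored duration: hours of HFNC support
from order placement to final weaning, capped at 30 days (720 h). The
intervention effect is modeled with a proportional-hazards regression in
which the hazard of weaning for subject *i* with arm indicator `a_i` is

    h_i(t) = exp(β₀) · Σⱼ γⱼ Mⱼ(t) · exp(β a_i)

`Mⱼ` are cubic M-splines: nonnegative polynomial splines normalized to unit
integral over their support, so the simplex-weighted mixture `Σ γⱼ Mⱼ` is a
density on `[0, U]` and `exp(β₀)` carries the overall hazard scale. The
matching cumulative hazard uses the I-splines (running integrals of the
M-splines), giving the log likelihood

    Σᵢ [ dᵢ (β₀ + log Σⱼ γⱼ Mⱼ(tᵢ) + β aᵢ) − exp(β₀) Σⱼ γⱼ Iⱼ(tᵢ) exp(β aᵢ) ]

with `dᵢ` the event indicator. Because the model is continuous-time, tied
times need no correction. An event time at which the mixture hazard is zero
yields a log likelihood of −∞ (reported, never raised); with strictly
positive simplex weights this cannot occur inside `[0, U]`.

**Basis construction.** The basis has two boundary knots and two internal
knots. Internal knots sit at the 33⅓rd and 66⅔rd percentiles (equally
spaced percentiles for two knots) of the *uncensored* durations, computed by
linear interpolation between order statistics. Boundary knots are 0 and the
maximum observed (event or censored) duration, so the cumulative hazard is
defined at every observation. The basis is rebuilt from each analysis
dataset, so interim and final fits always use knots adapted to the data in
hand. M-splines are computed from scipy's B-spline basis via the identity
`Mⱼ = (d+1)/(t_{j+d+1} − t_j) · Bⱼ` with boundary knots repeated to
multiplicity degree+1; I-splines are exact B-spline antiderivatives, not
quadrature. A degree-0 single-function variant (`constant_basis`) reduces
the model to a constant hazard; it exists for exponential-model
cross-checks.

**Priors.** log HR β ~ N(0, 2.5²) — "N(0, 2.5)" is read as a standard
deviation of 2.5, the convention of survival-regression software that
parameterizes normal priors by scale. γ ~ Dirichlet(1,…,1) (flat on the
simplex). β₀ ~ N(0, 20²), effectively flat; the intercept is needed because
the simplex weights cannot carry overall scale.

## Inference

Both engines work on the unconstrained parameterization
θ = (β, β₀, z₁…z₅) with γ = softmax([z, 0]); the Dirichlet prior combined
with the softmax Jacobian contributes `Σⱼ αⱼ log γⱼ` to the log posterior.
The gradient is analytic.

- **Laplace mode** (default inside simulation loops): BFGS to the posterior
  mode, a central-finite-difference Hessian of the analytic gradient
  (jittered to positive definiteness if needed, which in practice only
  happens in pathological tails), then multivariate-normal draws at the
  mode. A fit takes ~20–50 ms at trial-sized datasets.
- **Reference MCMC**: adaptive random-walk Metropolis preconditioned with
  the Laplace covariance (proposal scale 2.38/√d, Robbins–Monro adaptation
  toward 0.234 acceptance during warmup), 4 chains, 750 warmup iterations
  per chain and ≥ 2000 retained draws by default. Split-chain R-hat on β is
  reported; R-hat > 1.05 flags non-convergence in the results object
  without failing the fit.

On exponential-baseline datasets of n ≤ 20 both engines agree with a dense
two-dimensional grid integration of the (β, β₀) posterior to within 0.03 on
P(HR > 1) (the test suite's oracle); on constant-hazard data with true
HR 1.5 at n = 2000 the posterior mean HR is recovered within 10%. With the
likelihood switched off, draws come directly from the analytic prior
(posterior = prior), which is exact and preserves the seed contract.

Posterior decision quantities are computed as fractions of draws
(`P(HR > 1)`, `P(HR < 1.15)`), so they carry Monte-Carlo noise of order
`1/√n_draws` (≈ 0.008 at the default 4000 draws); decisions for trials whose
true posterior probability sits within that distance of a threshold can
flip between engines or seeds. This is inherent to draw-based rules, not an
implementation artifact.

## Decision rules

Interim: stop superior if P(HR > 1) > 0.99, else stop futile if
P(HR < 1.15) > 0.8, else continue. Final: superior if P(HR > 1) > 0.9,
promising if > 0.8, futile if P(HR < 1.15) > 0.8, else inconclusive. All
thresholds are strict inequalities ("exceeds"). Two choices were genuinely
open and are fixed here: superiority is evaluated before futility (the two
can only both fire through Monte-Carlo noise in the draws, and checking
superiority first is deterministic and conservative for the intervention
question), and the final analysis reuses the interim futility rule to
populate the futile-vs-inconclusive split of the four-way classification.
An HR of 1.15 corresponds to a 3.70-h reduction in the calibrated median —
the "less than about a 4-hour reduction" reading of the futility margin.

## Baseline calibration and the synthetic cohort

The baseline time-to-wean distribution is Weibull — the standard
two-parameter family closed under proportional hazards — pinned uniquely by
two constraints: median 35 h, and a median reduction of exactly 6.08 h when
the hazard is multiplied by 1.27. Closed forms: median = λ(ln 2)^(1/k);
under hazard multiplier h the median scales by h^(−1/k); hence
k = ln(1.27)/ln(35/28.92) ≈ 1.2526 and λ ≈ 46.90 h (both computed, never
hard-coded). The default cohort size is 549 encounters, the size of the
observational extract the design was informed by; it is configurable.

The synthetic event-log generator emulates flowsheet data: one order row at
t = 0, hourly flow rows ≥ 4 L/min while on support, a sub-4 L/min row at the
drawn weaning time (omitted beyond the 720-h cap, emulating administrative
censoring), and optional positive-pressure interludes (paired BiPAP mode
rows before the midpoint of the stay) with subsequent HFNC resumption. The
hourly cadence is finer than the 2-hourly assessment cadence of the
intervention workflow, keeping discretization below the endpoint's
resolution of interest. What the generator does *not* emulate: charting
noise and gaps, real ventilation-mode label dialects, flow taper profiles,
seasonality of bronchiolitis admissions, and crossover/non-adherence.
Passing round-trip tests therefore demonstrates correctness of the
derivation rule, not robustness to messy real-world documentation.

## Endpoint derivation

Final weaning is operationalized as the earliest sub-4 L/min flow row never
followed by a ≥ 4 L/min flow row within the follow-up window — the only
reading of "final weaning off" that is a pure function of the log. If
positive-pressure ventilation (configurable label set; default invasive
ventilation, BiPAP, CPAP, NIV) is documented after the order, the clock
restarts at the last such row preceding the final HFNC period. The 30-day
cap is anchored at the (possibly restarted) clock start; because the
restart shifts the window and the window determines which weaning row is
final, the implementation iterates these two rules to a fixed point (the
clock only moves forward, so termination is guaranteed). Readings after the
cap are ignored entirely: a late readmission to HFNC cannot undo a
qualifying wean. Times are real-valued hours with a half-open `[start, end)`
convention.

## Virtual trials and operating characteristics

Each replicate: enrollment times from a homogeneous Poisson process at the
configured accrual (default 125/year, the middle of the 100–150 range; an
optional sinusoidal 12-month thinning modulation exists but is off by
default, since seasonal accrual was never quantified); arms by independent
Bernoulli(0.5), which is what parity of sequentially assigned hospital-wide
encounter identifiers induces on the trial subsample; weaning times from
the calibrated Weibull with the arm's hazard multiplier (scale divided by
HR^(1/k)); administrative censoring at 720 h. Interim snapshots at 12, 18
and 24 calendar months (1 month = 365.25/12 days) include only subjects
enrolled before the snapshot, right-censored at their elapsed follow-up;
the model is refit per snapshot with recomputed knots. A snapshot with no
events or with fewer than three distinct uncensored durations (knots
undefined) defers the decision to the next analysis. The final analysis
runs when the last of the 350 subjects completes follow-up, or at an
optional maximum calendar time. One integer seed determines a replicate
end-to-end, and per-replicate seeds are derived from the scenario seed
independently of the scenario's truth, so different effect sizes can be
compared with common random numbers.

Operating characteristics aggregate per-stage and overall decision-class
fractions (each with binomial Monte-Carlo standard errors) plus the
distributions of total enrollment and calendar duration. Simulation studies
in this package default to 500 replicates with Laplace-mode fits (≈ 15–25 s
on one CPU), with the reference MCMC used for spot checks; fraction
estimates then carry MC standard errors near 0.02, which the tests account
for explicitly. At 500 replicates under the HR 1.27 truth the design
declares superiority in roughly 75–80% of replicates and superiority-or-
promising in roughly 82–85%, consistent with the published design's
"> 0.75" and "> 0.85" statements once MC error is accounted for. Under the
null (HR 1.0) the superiority fraction is ≈ 0.09 (2000 replicates), about
what the strict final 0.9 threshold implies after futility stopping.

## Known limitations

- The Laplace mode is a normal approximation; its tail probabilities match
  the reference sampler to ~0.002 at trial-sized datasets but it is not a
  substitute for MCMC on very small or very sparse snapshots.
- The simulator models the ITT estimand only: no crossover, no changed
  pre-selections, no eligibility screening upstream of the log.
- Covariates beyond the arm indicator, time-varying effects and frailty
  terms are out of scope.
- The endpoint deriver expects the package's log schema; real EHR dialects
  (mixed units, free-text modes) need upstream normalization.
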