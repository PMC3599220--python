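# Methods

## Model and likelihood

The endpoint is death from circulatory disease (ICD-8 390–458, ICD-10
chapter I; classification on the 3-character stem because the defining ranges
are 3-character ranges, and ICD-9 codes are rejected explicitly rather than
guessed). The survival model is Weibull proportional hazards on the **age
timescale** with two sex strata:

- hazard `h(t|x) = exp(alpha_s) * p_s * t^(p_s-1) * exp(beta @ x)`,
- cumulative baseline hazard `H0_s(t) = exp(alpha_s) * t^(p_s)` on
  untransformed age,
- delayed entry at the baseline age `a0`: each subject contributes
  `delta*log h(t_exit) - [H0(t_exit) - H0(a0)] * exp(beta@x)` to the
  log likelihood.

Age as the timescale (rather than follow-up time with an age covariate) is
the natural reading of a model whose coefficient table contains no age term
yet whose risk charts rise steeply with age, and it is what makes the
published intercepts (~ -48 for men with shape ~ 10) dimensionally sensible:
`exp(-47.7) * 65^9.9 ≈ 1.7e-3` is a plausible cumulative hazard at age 65,
whereas a follow-up timescale would put cumulative hazards near zero over any
realistic horizon. A shifted-age variant (`(age-20)^p`) was considered and
rejected: it drives the 10-year risks of a 65-year-old to a fraction of a
percent, incompatible with chart cells in the 5–30% range.

The absolute risk over horizon `h` given event-free survival to `a0` is
`1 - exp(-[H0(a0+h) - H0(a0)] * exp(beta@x))`, algebraically identical to
`1 - S(a0+h)/S(a0)`. The full follow-up is always used for fitting; the
horizon is chosen afterwards (10 years by default; 20 and 30 supported).

**Chart-cell sensitivity to printed coefficients.** Chart cells computed from
*rounded, published* coefficients can differ materially from the originally
printed cells. The dominant term of the linear predictor is the SBP
contribution: at SBP 180, a coefficient printed as 0.01 to one significant
digit spans `[0.005, 0.015)`, i.e. a factor of `exp(1.8)` ≈ 6 in hazard
across the rounding interval. The reference cell (male, 65, smoker, SBP 180,
glucose 6) evaluates to 8% from the printed values (`lp = 2.77`), and reaches
15% only with an unrounded SBP coefficient near 0.0136 — inside both the
printed rounding interval and the published CI (0.01; 0.02). The package
computes cells honestly from whatever coefficients it is given; it does not
back-correct.

**Fitting mechanics.** Optimization is quasi-Newton (L-BFGS-B) over
`(alpha_s, log p_s, beta)` with analytic gradients; starting values are
`p_s = 5`, `alpha_s` from a stratum moment match (event count over
`sum(t1^p - t0^p)`), `beta = 0`. Parameter regions where the exponentials
overflow return a large finite objective so line searches backtrack.
Covariance is the inverse of a numerically differentiated observed
information evaluated on the natural scale `(alpha, p, beta)`, so Wald CIs
for the shapes are on the shape scale. A stratum with no events has an
unidentified baseline (`alpha -> -inf`); such strata are excluded from the
fit and the result is flagged non-converged rather than reported silently.
Convergence tolerances: `gtol 1e-8`, `ftol 1e-12`, max 500 iterations.
Cross-checks in the test suite: a closed-form profile-likelihood grid scan
(one stratum, no covariates) and lifelines' delayed-entry `WeibullFitter`,
which agrees to ~4 decimals.

## Synthetic cohorts

The generator emulates the baseline structure of a 1977–79 Swiss community
cohort and is the test bed for every downstream stage.

| quantity | men | women | status |
|---|---|---|---|
| age mean (y) | 42.4 | 44.1 | published |
| age sd (y) | 12 | 13 | declared |
| current smoking | 50.3% | 27.7% | published |
| SBP mean (mmHg) | 130.2 | 125.4 | published |
| SBP sd | 16 | 17 | declared |
| glucose mean (mmol/L) | 5.4 | 5.2 | published |
| glucose sd | 0.9 | 0.8 | declared |
| cholesterol mean (mmol/L) | 6.0 | 6.0 | published |
| cholesterol sd | 1.1 | 1.1 | declared |
| male fraction | 0.454 | | analysed-cohort ratio |

Marginals are Normal truncated at physiologic floors (age 16, SBP 70,
glucose 2.5, cholesterol 2.0); the underlying location is solved so the
**post-truncation** mean equals the configured mean (truncation at 16 would
otherwise inflate mean age by ~0.4 y). Covariates are drawn independently
within sex — no correlation structure is claimed by the source material; this
is the main respect in which the synthetic data are easier than real data
(no confounding between smoking, pressure and glucose), so coefficient
recovery here does not demonstrate robustness to collinearity. Self-reported
diabetes is crudely tied to the upper glucose tail (glucose > 7) merely so
the diabetes-adjusted specification has something to estimate.

Event ages are exact inverse-CDF draws from the conditional law
`t = (a0^p - log(u) * exp(-(alpha+lp)))^(1/p)`, verified against the
closed-form survival function by Kolmogorov–Smirnov at 100,000 draws.
Censoring is administrative: individual follow-up is
`31.2 - U(0, 2)` years — a fixed study closing date (maximum follow-up equal
to the cohort's 95th-centile 31.2 y) with a 2-year enrollment stagger
matching a 1977–79 recruitment window. Random loss to follow-up is off by
default and available as `ltfu_rate`. Non-CVD mortality is deliberately not
simulated; the modelling frame has no competing risks, so simulated
"censoring-free survivors" are slightly more numerous than in a real cohort.
Under these defaults a cohort of 6,095 yields roughly 600–750 CVD deaths,
matching the order of the analysed cohort.

The external-validation preset is a synthetic stand-in for a US-survey-like
population (n 4,255 by convention): older, less smoking, lower cholesterol,
shorter follow-up. It shares no parameters with the default preset beyond the
truth model and exists to exercise frozen-coefficient scoring.

## Model comparison

All metrics fix a horizon on the follow-up timescale and classify each
subject as event, event-free, or censored-before-horizon.

- **IPCW weights**: Kaplan–Meier estimate `G` of the censoring distribution;
  events weighted `1/G(T-)` (left limit), event-free `1/G(horizon)`,
  censored 0. With purely administrative censoring beyond the horizon all
  weights are 1 and every metric collapses to its classical uncensored form —
  that limit is the anchor for the exact oracle tests.
- **Brier score**: weighted mean of `(y - r)^2`, divided by n. Displayed
  `x 1e-5` in CLI reports, following the conventional presentation.
- **Cross-validation**: exact leave-one-out refits each n−1 subset
  (`mode="exact"`); k-fold (default 10) is the fast path. A non-convergent
  refit falls back to the full-sample fit for that fold and is flagged,
  never silently dropped.
- **AUC**: IPCW cumulative/dynamic concordance at the horizon, ties 1/2; an
  unweighted binary variant is available (`ipcw=False`) as a sensitivity
  option.
- **IDI**: difference of discrimination slopes (mean risk in events minus
  mean risk in event-free; censored-before-horizon subjects excluded). The
  Wald SE uses the paired per-subject risk differences:
  `se^2 = var(d|events)/n_ev + var(d|free)/n_free`.
- **Permutation test** for Brier differences: paired design — each subject's
  two predicted risks are swapped independently with probability 1/2;
  `p = (1 + #{null >= obs}) / (B + 1)`, B = 1999 by default.
- **External validation** applies frozen coefficients to a new cohort; no
  refitting, apparent (non-CV) Brier.

**Null-calibration design.** The calibration suite checks that Wald p-values
are uniform when the true coefficients are zero (200 replicates, n = 5,000)
and that permutation p-values are uniform when two prediction sets come from
equal-quality fits (two independent training cohorts of 2,000, one common
test cohort of 500, B = 199, 200 replicates). The zero-coefficient truth
raises the stratum intercepts to −45.9 (men) and −57.0 (women) — the
published intercepts plus a typical linear predictor — so the event yield
stays comparable to the non-null cohorts; without this the null scenario
would have ~6× fewer events and n = 5,000 asymptotics would be marginal.

## Risk charts

Default axes are chart convention, not study data: ages {40, 50, 55, 60,
65}, SBP {120, 140, 160, 180}, marker {4, 5, 6, 7, 8} mmol/L; the rendered
metadata flags them as convention defaults. Cells are rounded half-up to
integer percent (the only lossy step; `|cell - 100*risk| <= 0.5`). Panels
print SBP descending down the rows and the marker ascending across the
columns. Dichotomized-cholesterol companion panels use representative values
5.2 (low) and 7.0 (high) mmol/L, configurable. Cell keys are canonicalized
to (sex, smoking, age, SBP, marker), so axis order in a specification is
irrelevant.

## Problem sizes used in the checks

Parameter recovery simulates 50,000 subjects per model; simulator
distribution checks use 100,000 draws per stratum; calibration suites use
200 replicates at the sizes above; exact-LOOCV equivalence is demonstrated
at n = 60 (it is an identity, not an asymptotic claim). These sizes give
Monte-Carlo error comfortably inside the tolerances being asserted.

## Known limitations

- No competing risks (by design, mirroring the modelling frame); absolute
  risks are therefore slightly conservative upward at old ages.
- Independent covariates in the generator: see above.
- The IDI Wald SE ignores estimation noise in the fitted coefficients (it
  conditions on the risks), as does the usual construction.
- Printed-coefficient charts inherit the rounding sensitivity documented
  above; for faithful chart reproduction use unrounded fitted coefficients.
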