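# Methods

## Model

`gbtm` fits a finite mixture of polynomial growth curves to long-format
longitudinal data (one row per subject per study day). Group j's mean is a
polynomial mu_j(t) of order 0–4 in the raw study day (day 1 = first study
day, so the intercept is the extrapolated day-0 level), with a single
residual SD sigma shared across groups — the convention of standard
group-based trajectory modeling (GBTM) reports, which print one Sigma row.
The outcome is a censored normal (Tobit): consumption cannot fall below the
floor (0 g/kg/day by default, because an animal cannot drink a negative
amount), so values recorded exactly at a bound contribute the Gaussian tail
mass log Φ((lower−mu)/sigma) (or the upper mirror) instead of a density.
The upper bound defaults to +inf; intake has no physical ceiling. Repeated
measures are conditionally independent given the latent group, so a
subject's group-conditional log-likelihood is the sum of the per-day terms,
and the cohort log-likelihood is the log-sum-exp–stabilized mixture over
groups weighted by the membership proportions pi_j.

Assumptions worth keeping in mind: conditional independence over time
within group (no subject-level random effects or serial correlation),
shared sigma, polynomial mean shapes, and missingness at random.

## Estimation

Maximum likelihood via EM:

- **E-step** — Bayesian posterior membership probabilities (BPPs) by Bayes'
  rule on the log scale; extreme likelihood ratios give exact 0/1 rows
  without overflow.
- **M-step** — pi_j is the mean posterior weight; the coefficients and
  sigma maximize the posterior-weighted censored-normal log-likelihood via
  L-BFGS-B with analytic gradients, warm-started from the previous values
  (censoring removes the weighted-least-squares closed form). A step is
  accepted only if it does not decrease the M-step objective, making the
  sweep a generalized EM whose observed log-likelihood is non-decreasing;
  the test suite asserts this on every recorded path.
- Time is rescaled internally to u = t/t_max so the polynomial basis is
  well conditioned; coefficients and their SEs are reported in raw-day
  units.
- **Multi-start** — the first start splits subjects into k quantile groups
  of their mean level and fits per-group polynomials; the remaining
  n_starts−1 starts jitter the subject means before splitting. Every start
  runs a short EM (default 25 iterations), then the two best short runs are
  polished to full convergence and the better one is kept. Defaults:
  n_starts = 20 for a final fit, 8 for group-number scans (on
  reference-truth cohorts 8+ starts reproducibly reach the optimum that 20
  starts find; 5 occasionally collapses two groups, which is why the scan
  default is above that). Convergence: relative |ΔL| < 1e-8 or 500
  iterations, inner optimizer capped at 50 iterations per sweep.
- Groups are reported in canonical ascending-intercept order — a reporting
  convention only; see "Group identification" below.

**Wald tests.** Standard errors come from the inverse observed information:
the numerical Hessian (central differences of the analytic gradient) of the
observed mixture log-likelihood at the optimum, with memberships
parameterized as multinomial logits and delta-method back-transformed to
the percent scale. t = estimate/SE is referred to the standard normal
(two-sided); with no degrees-of-freedom convention for mixture Wald tests,
last-digit differences from t-distribution-based software are expected.
A singular information matrix yields undefined (NaN) SEs plus a diagnostic
message, never fabricated values.

**Information criteria.** Reported larger-is-better: AIC = L − p and
BIC = L − (p/2) ln N under both N conventions (total observations and
subjects), p = Σ_j(order_j+1) + 1 + (k−1). For the 3-group quadratic model
p = 12, which the published footer values verify exactly.

## Group-number selection

Candidates k = k_min..k_max are each fit and flagged by three strict
criteria: all membership proportions > 10%, all membership Wald p-values
< 0.1, and every subject's best BPP > 0.95 (k = 1 is always an eligible
baseline with these flags not applicable). Among passing candidates the
largest observation-count BIC wins; homogeneity is rejected iff the winner
has k > 1 and beats the k = 1 BIC by more than 10. The criteria apply to
membership parameters only — retaining a trajectory coefficient with
p > 0.1 does not disqualify a model. Non-convergent candidates are
excluded and reported. All thresholds are configurable; the defaults are
the conventional printed values.

## Synthetic cohorts

The generator emulates a 35-mouse two-bottle free-choice study: three
latent groups of sizes 4/26/5 (late drinkers, non-drinkers, early
drinkers) on quadratic curves with the reference fitted coefficients,
sigma = 1.60771 g/kg/day, left-censoring at 0, daily observations on study
days 6–57 (the two-bottle era after the water-only lead-in) and 15 cells
missing at random — 1805 observations, matching the reference
observation count. The published per-regimen alcohol-availability days
would give 1730 observations and days 6–57 give 1820, so the 1820−15
schedule is a documented reconstruction; schedule and missingness are
configurable. Daily values (not 5-day averages) enter the model, as the
observation count implies. The default cohort places the late/early
drinkers on the published subject numbers so the regimen cross-tab
(5% regimen = subjects 1–18) matches the reference counts; alternative
scenarios (`homogeneous`, `two_group`) support selection-procedure tests.
Side channels (body weight, food, water) are group mean + Gaussian noise
with defaults chosen to mimic the reference phenotypes (indistinguishable
growth and food intake; lower water intake for early drinkers): body
weight grows ~16→36 g over the study, food ~5 g/day, water ~150 vs
110 mL/kg/day.

What the generator does **not** emulate: within-subject serial
correlation, the 2%-alcohol ramp days, regimen effects on consumption
(none were reported), attrition, or heavy-tailed measurement error. Tests
passing on these cohorts therefore validate the estimation machinery under
the model's own assumptions, not robustness to real-data violations.

## Replication studies and problem sizes

The calibration suite and the reproduction script refit the 3-group model
on 20 independently seeded reference-truth cohorts (20-start EM each, plus
a k=1 baseline) and report medians; the selection study scans k = 1..4 on
20 cohorts, and the null study scans 50 single-group-truth cohorts (3
starts — under homogeneity there is no group structure for extra starts to
find). These sizes give stable medians while keeping a full run in minutes
on one CPU.

## Group identification in recovery studies

When fitted groups must be identified with generating groups (parameter
recovery, late-drinker counts), matching is by whole-curve proximity: the
one-to-one assignment minimizing the total squared distance between fitted
and generating mean curves over the observed days (`match_groups`).
Intercept rank is not reliable for this — the late- and non-drinker
intercepts (1.39 vs 1.61) differ by far less than their SEs (~0.50/0.20),
so their ranks swap in roughly a third of replicates even at the exact
MLE, while the full curves are unambiguous.

## Numerical notes and edge cases

- Censored log-masses use the scipy log-CDF, finite out to standardized
  distances of several tens.
- Posterior rows sum to 1 within 1e-12; classification ties break toward
  the lowest group index.
- Mixture proportions are floored at 1e-10 during EM; a collapsed group
  then fails the membership criteria downstream rather than crashing.
- Empty (group, bin) cells fail the ANOVA with the offending cell named;
  single-subject bins report a missing SEM rather than 0.
- Subjects are processed in sorted-identifier order; all randomness flows
  from explicit seeds (`numpy.random.default_rng`), so every artifact is
  bit-reproducible given its config.

## Comparison stage

Group phenotype comparison uses subject-level 5-day bin means as the
observational unit: a group × time factorial ANOVA (statsmodels OLS,
type-II tests) and Tukey HSD among groups within each bin (studentized
range on the within-bin error). This approximates, but is not identical
to, repeated-measures ANOVA conventions of GUI statistics packages; the
contract is the directional significance pattern, not exact p-values.
Per-bin patterns are labeled by ranking groups on their bin means:
`early` (bottom two indistinguishable, both below the top), `transition`
(all distinct), `end` (top two indistinguishable, both above the bottom),
otherwise `other`.

## Known limitations

- No covariates on membership, no time-varying covariates, no
  non-ignorable dropout modeling.
- Per-group polynomial orders are configuration, not searched
  automatically.
- SEs are asymptotic observed-information values; with 35 subjects the
  membership SEs in particular are approximate, and software using other
  parameterizations will differ in the last digits.
- Absolute fit values of the unreleased reference dataset cannot be
  reproduced; the package validates against it through analytic identities
  on published summaries and through simulation-based recovery.
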