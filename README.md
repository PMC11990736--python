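# gbtm — group-based trajectory modeling of longitudinal consumption data

`gbtm` identifies latent subgroups of subjects that follow distinct
developmental trajectories in longitudinal behavioral data — the motivating
use case is voluntary alcohol consumption of adolescent mice in a two-bottle
free-choice paradigm, where a cohort typically mixes non-drinkers with
animals that drink heavily from the start and animals that escalate late.
It is aimed at behavioral neuroscientists and biostatisticians who want a
scriptable, reproducible alternative to running this analysis through
proprietary trajectory-modeling software.

## The model

Each of k latent groups j has a polynomial mean curve over study day t,

    mu_j(t) = beta_j0 + beta_j1 t + beta_j2 t^2 + ...   (order <= 4)

and the observed outcome y_it (g alcohol / kg body weight / day) is a
censored normal (Tobit): the latent draw N(mu_j(t), sigma^2) is observed
exactly when it lies inside the censoring bounds, while values at a bound
(consumption cannot be negative, so the floor is 0) contribute cumulative
tail mass to the likelihood instead of density. With membership proportions
pi_j, the cohort log-likelihood is

    L = sum_i log sum_j pi_j exp( sum_t log f_cnorm(y_it | beta_j, sigma) ).

Fitting is maximum likelihood by multi-start EM; each subject's Bayesian
posterior probability (BPP) of group membership comes from Bayes' rule, and
subjects are classified to their maximum-BPP group. The number of groups is
chosen by a parsimony scan: a candidate k is acceptable when every
membership percentage exceeds 10% with Wald p-value below 0.1 and every
subject's best BPP exceeds 0.95; among acceptable candidates the largest
BIC (reported as L − (p/2) ln N, larger is better) wins, and homogeneity
(k = 1) is rejected when the winner beats the single-group BIC by more
than 10. Classified groups are then compared phenotype-wise: 5-day-binned
means ± SEM, group × time ANOVA with per-bin Tukey HSD contrasts, phase
labels (early / transition / end), and a group × regimen cross-tab.

## Worked example

```python
from gbtm import (CensoredTrajectoryMixture, TrajectoryGroupSelector,
                  default_design, default_generating_model, generate_cohort)

# a synthetic 35-mouse cohort with the reference study's structure:
# groups of 4/26/5, quadratic curves, sigma 1.608, days 6-57, 1805 rows
data = generate_cohort(default_design(seed=1), default_generating_model())

sel = TrajectoryGroupSelector(k_min=1, k_max=4, random_state=1).fit(data)
print(sel.report_.to_frame()[["k", "BIC"]])
print("selected k =", sel.selected_k_,
      " BIC gain over k=1 =", round(sel.report_.delta_bic_vs_k1, 1))

est = CensoredTrajectoryMixture(n_groups=3, order=2, n_starts=20, random_state=1)
est.fit(data)
print("sigma =", round(est.sigma_, 3))
print("membership % =", (100 * est.weights_).round(2))
print("classified sizes:", est.predict(data).value_counts().sort_index().to_dict())
```

prints

```
   k          BIC
0  1 -3740.425105
1  2 -3313.646837
2  3 -3126.876586
3  4 -3141.873268
selected k = 3  BIC gain over k=1 = 613.5
sigma = 1.622
membership % = [74.29 11.43 14.29]
classified sizes: {1: 26, 2: 4, 3: 5}
```

The scan accepts k = 2 and 3 and stops at 3 (k = 4 has a membership whose
Wald p-value exceeds 0.1, and a lower BIC); the ~600-point BIC gain over a
single group rejects homogeneity. The refit recovers the generating residual
SD (1.608) within one standard error, and the three classified groups
(canonically ordered by ascending intercept: here non-drinkers, late
drinkers, early drinkers) reproduce the generating 26/4/5 split exactly —
every subject with a posterior probability ≥ 0.999.

A command-line interface mirrors the library:

```sh
gbtm simulate --seed 1 --out cohort.csv
gbtm scan cohort.csv --k-min 1 --k-max 4
gbtm run --seed 1 --out results/
```

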