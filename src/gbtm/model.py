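"""Maximum-likelihood fitting of censored-normal trajectory mixtures.

The estimator implements group-based trajectory modeling: a finite mixture in
which each latent group's longitudinal mean is a polynomial in study day and
the outcome follows a censored normal (Tobit) distribution with a shared
residual SD. Fitting is EM: the E-step computes Bayesian posterior membership
probabilities, the M-step re-estimates mixture proportions in closed form and
maximizes the posterior-weighted censored-normal log-likelihood over the
polynomial coefficients and sigma with a warm-started quasi-Newton solver
(censoring removes the weighted-least-squares closed form). Multi-start
initialization guards against local optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .likelihood import (
    ParameterSet,
    TrajectoryModelSpec,
    cnorm_loglik_terms,
    design_matrix,
    information_criteria,
    n_free_parameters,
)

__all__ = ["CensoredTrajectoryMixture", "FitResult", "fit", "classify", "wald_tests",
           "match_groups"]

_LOG2PI = np.log(2 * np.pi)


@dataclass
class FitResult:
    """Summary of one maximum-likelihood fit."""

    spec: TrajectoryModelSpec
    params: ParameterSet
    loglik: float
    bic_obs: float
    bic_subj: float
    aic: float
    n_obs: int
    n_subjects: int
    n_params: int
    converged: bool
    n_iter: int
    n_starts_used: int
    params_table: pd.DataFrame = None  # estimate / SE / t / p per parameter
    se_message: str = ""


def classify(posterior: np.ndarray) -> np.ndarray:
    """Hard assignment by maximum posterior probability (1-based group labels).

    Ties break toward the lowest group index.
    """
    posterior = np.asarray(posterior, dtype=float)
    return np.argmax(posterior, axis=1) + 1


class _PreparedData:
    """Long table unpacked into arrays sorted by subject, with scaled time basis."""

    def __init__(self, data: pd.DataFrame, max_order: int, lower: float, upper: float,
                 t_scale: float | None = None):
        for col in ("subject_id", "day", "value"):
            if col not in data.columns:
                raise ValueError(f"input table lacks required column '{col}'")
        subject_ids, codes = np.unique(np.asarray(data["subject_id"]), return_inverse=True)
        order_idx = np.argsort(codes, kind="stable")
        self.codes = codes[order_idx]
        self.days = np.asarray(data["day"], dtype=float)[order_idx]
        self.y = np.asarray(data["value"], dtype=float)[order_idx]
        if np.any(self.y < lower) or np.any(self.y > upper):
            raise ValueError("observed values must lie within the censoring bounds")
        self.subject_ids = subject_ids
        self.n_subjects = len(subject_ids)
        self.n_obs = len(self.y)
        counts = np.bincount(self.codes, minlength=self.n_subjects)
        if np.any(counts == 0):
            raise ValueError("every subject needs at least one observation")
        self.t_scale = float(t_scale if t_scale is not None else max(self.days.max(), 1.0))
        self.U = design_matrix(self.days / self.t_scale, max_order)  # scaled basis
        self.at_lower = self.y <= lower if np.isfinite(lower) else np.zeros(self.n_obs, bool)
        self.at_upper = self.y >= upper if np.isfinite(upper) else np.zeros(self.n_obs, bool)
        self.subject_means = np.bincount(self.codes, weights=self.y) / counts


class CensoredTrajectoryMixture(BaseEstimator):
    """Censored-normal finite mixture of polynomial growth curves.

    Parameters
    ----------
    n_groups : number of latent trajectory groups (k >= 1).
    order : polynomial order of the group mean curves, 0-4; a scalar applies
        to every group, a sequence gives one order per group.
    lower_bound, upper_bound : censoring limits in outcome units. Values
        recorded exactly at a bound contribute tail mass, not density.
    n_starts : number of EM initializations; the first is a k-quantile split
        of subject mean levels, the rest are seeded random perturbations of it.
    short_run_iters : EM iterations granted to each start before the best
        start is polished to full convergence.
    tol : relative log-likelihood change declaring EM convergence.
    max_iter : EM iteration cap for the polishing run.
    inner_maxiter : iteration cap of the quasi-Newton M-step solver.
    random_state : seed for the multi-start draws.

    Attributes (after fit)
    ----------------------
    coefficients_ : list of per-group coefficient arrays in raw day units,
        groups in canonical ascending-intercept order.
    sigma_, weights_ : shared residual SD and membership proportions.
    loglik_, bic_, bic_subject_, aic_ : maximized log-likelihood and
        larger-is-better information criteria (observation- and
        subject-count BIC conventions).
    params_table_ : per-parameter estimate / SE / t / p table (memberships on
        the percent scale).
    loglik_path_ : log-likelihood after each EM iteration of the retained run.
    converged_, n_iter_, n_starts_used_ : convergence diagnostics.
    """

    def __init__(self, n_groups=3, order=2, lower_bound=0.0, upper_bound=np.inf,
                 n_starts=20, short_run_iters=25, tol=1e-8, max_iter=500,
                 inner_maxiter=50, random_state=None, compute_se=True):
        self.n_groups = n_groups
        self.order = order
        self.lower_bound = lower_bound
        self.upper_bound = upper_bound
        self.n_starts = n_starts
        self.short_run_iters = short_run_iters
        self.tol = tol
        self.max_iter = max_iter
        self.inner_maxiter = inner_maxiter
        self.random_state = random_state
        self.compute_se = compute_se

    # ------------------------------------------------------------------ fit

    def _spec(self) -> TrajectoryModelSpec:
        orders = self.order if not np.isscalar(self.order) else (int(self.order),) * int(self.n_groups)
        return TrajectoryModelSpec(int(self.n_groups), tuple(orders),
                                   float(self.lower_bound), float(self.upper_bound))

    def fit(self, data: pd.DataFrame, y=None):
        """Fit by multi-start EM on a long-format table (subject_id, day, value)."""
        spec = self._spec()
        prep = _PreparedData(data, max(spec.orders), spec.lower_bound, spec.upper_bound)
        if spec.k > prep.n_subjects:
            raise ValueError(f"k={spec.k} exceeds the number of subjects ({prep.n_subjects})")
        rng = np.random.default_rng(self.random_state)

        starts = [self._initial_params(prep, spec, rng, perturb=(s > 0)) for s in range(max(1, self.n_starts))]
        short_runs = [self._em(prep, spec, B, logsig, pi, max_iter=self.short_run_iters)
                      for B, logsig, pi in starts]
        short_runs.sort(key=lambda r: r["loglik"], reverse=True)
        # polish the best short runs to full convergence; short-run rank is a
        # noisy predictor of the final basin, so polishing two is cheap insurance
        run = None
        for candidate in short_runs[:min(2, len(short_runs))]:
            polished = self._em(prep, spec, candidate["B"], candidate["logsig"],
                                candidate["pi"], max_iter=self.max_iter,
                                path=candidate["path"])
            if run is None or polished["loglik"] > run["loglik"]:
                run = polished
        if not run["converged"]:
            warnings.warn("EM did not converge within max_iter; result flagged converged=False")

        self._finalize(prep, spec, run, n_starts_used=len(starts))
        return self

    # ---------------------------------------------------------- EM internals

    def _initial_params(self, prep, spec, rng, perturb):
        """k-quantile split of subject mean levels; perturbed copies jitter the ranks."""
        means = prep.subject_means
        if perturb:
            means = means + rng.standard_normal(len(means)) * (np.std(means) + 1e-6)
        order_idx = np.argsort(means, kind="stable")
        splits = np.array_split(order_idx, spec.k)
        d = max(spec.orders) + 1
        B = np.zeros((spec.k, d))
        u = prep.U[:, 1] if d > 1 else None
        resid_ss, resid_n = 0.0, 0
        for j, members in enumerate(splits):
            mask = np.isin(prep.codes, members)
            oj = spec.orders[j]
            try:
                if oj > 0 and mask.sum() > oj:
                    coef = np.polyfit(prep.U[mask, 1], prep.y[mask], oj)
                    B[j, : oj + 1] = np.asarray(coef)[::-1]
                else:
                    B[j, 0] = prep.y[mask].mean() if mask.any() else prep.y.mean()
            except (np.linalg.LinAlgError, SystemError):
                B[j, 0] = prep.y[mask].mean() if mask.any() else prep.y.mean()
            fitted = prep.U[mask, : oj + 1] @ B[j, : oj + 1]
            resid_ss += np.sum((prep.y[mask] - fitted) ** 2)
            resid_n += mask.sum()
        sigma0 = max(np.sqrt(resid_ss / max(resid_n, 1)), 0.05)
        pi0 = np.array([max(len(m), 1) for m in splits], dtype=float)
        pi0 /= pi0.sum()
        return B, np.log(sigma0), pi0

    def _obs_loglik_matrix(self, prep, spec, B, sigma, with_grad=False):
        mu = prep.U @ B.T  # (n_obs, k); padded coefficients are zero
        return cnorm_loglik_terms(prep.y, mu, sigma, prep.at_lower, prep.at_upper,
                                  with_grad=with_grad)

    def _subject_loglik(self, prep, spec, ll_obs):
        l_ij = np.empty((prep.n_subjects, spec.k))
        for j in range(spec.k):
            l_ij[:, j] = np.bincount(prep.codes, weights=ll_obs[:, j],
                                     minlength=prep.n_subjects)
        return l_ij

    def _em(self, prep, spec, B, logsig, pi, max_iter, path=None):
        d = max(spec.orders) + 1
        coef_mask = np.zeros((spec.k, d), dtype=bool)
        for j, oj in enumerate(spec.orders):
            coef_mask[j, : oj + 1] = True
        theta = np.concatenate([B[coef_mask], [logsig]])
        path = list(path) if path else []
        loglik = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            B = self._unflatten(theta, coef_mask)
            sigma = np.exp(theta[-1])
            l_ij = self._subject_loglik(prep, spec, self._obs_loglik_matrix(prep, spec, B, sigma))
            logw = l_ij + np.log(pi)
            norm_ = logsumexp(logw, axis=1, keepdims=True)
            new_loglik = float(norm_.sum())
            W = np.exp(logw - norm_)
            path.append(new_loglik)
            if np.isfinite(loglik) and abs(new_loglik - loglik) <= self.tol * (abs(loglik) + 1e-3):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
            # M-step: closed-form proportions, quasi-Newton for (beta, log sigma)
            pi = np.clip(W.mean(axis=0), 1e-10, None)
            pi /= pi.sum()
            obsw = W[prep.codes]

            def negQ(th):
                Bm = self._unflatten(th, coef_mask)
                sig = np.exp(th[-1])
                ll, dmu, dlogsig = cnorm_loglik_terms(
                    prep.y, prep.U @ Bm.T, sig, prep.at_lower, prep.at_upper, with_grad=True)
                gB = prep.U.T @ (obsw * dmu)  # (d, k)
                grad = np.concatenate([gB.T[coef_mask], [(obsw * dlogsig).sum()]])
                return -float((obsw * ll).sum()), -grad

            q0 = negQ(theta)[0]
            res = minimize(negQ, theta, jac=True, method="L-BFGS-B",
                           options={"maxiter": self.inner_maxiter, "ftol": 1e-12, "gtol": 1e-10})
            if res.fun <= q0:  # generalized EM: only accept non-decreasing Q
                theta = res.x
        return {"B": self._unflatten(theta, coef_mask), "logsig": theta[-1], "pi": pi,
                "loglik": loglik, "path": path, "converged": converged, "n_iter": it,
                "coef_mask": coef_mask, "theta": theta}

    @staticmethod
    def _unflatten(theta, coef_mask):
        B = np.zeros(coef_mask.shape)
        B[coef_mask] = theta[:-1]
        return B

    # ------------------------------------------------------------- finalize

    def _finalize(self, prep, spec, run, n_starts_used):
        sigma = float(np.exp(run["logsig"]))
        B, pi = run["B"], run["pi"]
        # canonical order: ascending intercept (reporting convention)
        order_idx = np.argsort(B[:, 0], kind="stable")
        B = B[order_idx]
        pi = pi[order_idx]
        orders = tuple(spec.orders[j] for j in order_idx)
        spec = TrajectoryModelSpec(spec.k, orders, spec.lower_bound, spec.upper_bound)

        scale = prep.t_scale ** np.arange(B.shape[1])
        beta_raw = [B[j, : orders[j] + 1] / scale[: orders[j] + 1] for j in range(spec.k)]
        self.spec_ = spec
        self.coefficients_ = beta_raw
        self.sigma_ = sigma
        self.weights_ = pi
        self.loglik_ = run["loglik"]
        self.n_params_ = n_free_parameters(orders, spec.k)
        self.bic_, self.bic_subject_, self.aic_ = information_criteria(
            self.loglik_, self.n_params_, prep.n_obs, prep.n_subjects)
        self.converged_ = run["converged"]
        self.n_iter_ = run["n_iter"]
        self.n_starts_used_ = n_starts_used
        self.loglik_path_ = np.asarray(run["path"])
        self.n_obs_ = prep.n_obs
        self.n_subjects_ = prep.n_subjects
        self.subject_ids_ = prep.subject_ids
        self.t_scale_ = prep.t_scale
        self._B_int = np.zeros_like(B)
        for j in range(spec.k):
            self._B_int[j, : orders[j] + 1] = B[j, : orders[j] + 1]
        self._prep_train = prep
        self.se_message_ = ""
        if self.compute_se:
            self.params_table_ = self._wald_table(prep, spec)
        else:
            self.params_table_ = None

    # ----------------------------------------------------- posterior/predict

    def _require_fitted(self):
        if not hasattr(self, "coefficients_"):
            raise ValueError("this estimator is not fitted yet; call fit first")

    def _posterior(self, prep):
        spec = self.spec_
        l_ij = self._subject_loglik(prep, spec,
                                    self._obs_loglik_matrix(prep, spec, self._B_int, self.sigma_))
        logw = l_ij + np.log(self.weights_)
        return np.exp(logw - logsumexp(logw, axis=1, keepdims=True)), l_ij

    def predict_proba(self, data: pd.DataFrame) -> pd.DataFrame:
        """Bayesian posterior membership probabilities, one row per subject."""
        self._require_fitted()
        prep = _PreparedData(data, max(self.spec_.orders), self.spec_.lower_bound,
                             self.spec_.upper_bound, t_scale=self.t_scale_)
        probs, _ = self._posterior(prep)
        return pd.DataFrame(probs, index=pd.Index(prep.subject_ids, name="subject_id"),
                            columns=[f"group_{j + 1}" for j in range(self.spec_.k)])

    def predict(self, data: pd.DataFrame) -> pd.Series:
        """Hard group assignment (1-based) by maximum posterior probability."""
        probs = self.predict_proba(data)
        return pd.Series(classify(probs.to_numpy()), index=probs.index, name="group")

    def score(self, data: pd.DataFrame, y=None) -> float:
        """Total mixture log-likelihood of a table under the fitted parameters."""
        self._require_fitted()
        prep = _PreparedData(data, max(self.spec_.orders), self.spec_.lower_bound,
                             self.spec_.upper_bound, t_scale=self.t_scale_)
        _, l_ij = self._posterior(prep)
        return float(np.sum(logsumexp(l_ij + np.log(self.weights_), axis=1)))

    @property
    def params_(self) -> ParameterSet:
        self._require_fitted()
        return ParameterSet(beta=self.coefficients_, sigma=self.sigma_, pi=self.weights_)

    @property
    def result_(self) -> FitResult:
        self._require_fitted()
        return FitResult(
            spec=self.spec_, params=self.params_, loglik=self.loglik_,
            bic_obs=self.bic_, bic_subj=self.bic_subject_, aic=self.aic_,
            n_obs=self.n_obs_, n_subjects=self.n_subjects_, n_params=self.n_params_,
            converged=self.converged_, n_iter=self.n_iter_,
            n_starts_used=self.n_starts_used_, params_table=self.params_table_,
            se_message=self.se_message_,
        )

    # ----------------------------------------------------------- Wald tests

    def _observed_loglik_grad(self, prep, spec, theta, coef_mask):
        """Analytic gradient of the observed mixture log-likelihood.

        Parameterization: scaled-basis coefficients, sigma (natural scale),
        multinomial logits of the memberships (last group is reference).
        """
        k = spec.k
        n_coef = int(coef_mask.sum())
        B = np.zeros(coef_mask.shape)
        B[coef_mask] = theta[:n_coef]
        sigma = theta[n_coef]
        alpha = theta[n_coef + 1:]
        logits = np.concatenate([alpha, [0.0]])
        pi = np.exp(logits - logsumexp(logits))
        ll, dmu, dlogsig = cnorm_loglik_terms(prep.y, prep.U @ B.T, sigma,
                                              prep.at_lower, prep.at_upper, with_grad=True)
        l_ij = self._subject_loglik(prep, spec, ll)
        logw = l_ij + np.log(pi)
        norm_ = logsumexp(logw, axis=1, keepdims=True)
        L = float(norm_.sum())
        W = np.exp(logw - norm_)
        obsw = W[prep.codes]
        gB = (prep.U.T @ (obsw * dmu)).T[coef_mask]
        gsigma = (obsw * dlogsig).sum() / sigma
        galpha = (W - pi).sum(axis=0)[:-1]
        return L, np.concatenate([gB, [gsigma], galpha])

    def _wald_table(self, prep, spec) -> pd.DataFrame:
        k = spec.k
        coef_mask = np.zeros((k, max(spec.orders) + 1), dtype=bool)
        for j, oj in enumerate(spec.orders):
            coef_mask[j, : oj + 1] = True
        n_coef = int(coef_mask.sum())
        logits = np.log(self.weights_) - np.log(self.weights_[-1])
        theta = np.concatenate([self._B_int[coef_mask], [self.sigma_], logits[:-1]])
        p = len(theta)

        def grad(th):
            return self._observed_loglik_grad(prep, spec, th, coef_mask)[1]

        # observed information from central differences of the analytic gradient
        H = np.zeros((p, p))
        for a in range(p):
            h = 1e-5 * max(1.0, abs(theta[a]))
            tp, tm = theta.copy(), theta.copy()
            tp[a] += h
            tm[a] -= h
            H[:, a] = (grad(tp) - grad(tm)) / (2 * h)
        H = 0.5 * (H + H.T)
        info = -H
        names, estimates, scale_div = [], [], []
        term_names = ["Intercept", "Linear", "Quadratic", "Cubic", "Quartic"]
        scale = self.t_scale_ ** np.arange(coef_mask.shape[1])
        for j in range(k):
            for m in range(spec.orders[j] + 1):
                names.append((j + 1, term_names[m]))
                estimates.append(self.coefficients_[j][m])
                scale_div.append(scale[m])
        names.append((None, "Sigma"))
        estimates.append(self.sigma_)
        scale_div.append(1.0)

        se = np.full(p, np.nan)
        cov = None
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            se = np.sqrt(diag)
        except np.linalg.LinAlgError as exc:
            self.se_message_ = f"observed information is singular or indefinite ({exc}); SEs undefined"

        rows = []
        for idx, ((grp, name), est, sdiv) in enumerate(zip(names, estimates, scale_div)):
            s = se[idx] / sdiv if np.isfinite(se[idx]) else np.nan
            t = est / s if s and np.isfinite(s) and s > 0 else np.nan
            pv = 2 * norm.sf(abs(t)) if np.isfinite(t) else np.nan
            rows.append({"group": grp, "parameter": name, "estimate": est,
                         "se": s, "t": t, "p": pv})
        # membership percentages via delta method from the logit block
        if k > 1 and cov is not None:
            cov_alpha = cov[n_coef + 1:, n_coef + 1:]
            pi = self.weights_
            for j in range(k):
                # dpi_j / dalpha_a over the k-1 free logits
                g = np.array([pi[j] * ((1.0 if a == j else 0.0) - pi[a]) for a in range(k - 1)])
                var = float(g @ cov_alpha @ g)
                s = 100.0 * np.sqrt(var) if var > 0 else np.nan
                est = 100.0 * pi[j]
                t = est / s if np.isfinite(s) and s > 0 else np.nan
                pv = 2 * norm.sf(abs(t)) if np.isfinite(t) else np.nan
                rows.append({"group": j + 1, "parameter": "Membership (%)",
                             "estimate": est, "se": s, "t": t, "p": pv})
        elif k > 1:
            for j in range(k):
                rows.append({"group": j + 1, "parameter": "Membership (%)",
                             "estimate": 100.0 * self.weights_[j], "se": np.nan,
                             "t": np.nan, "p": np.nan})
        else:
            rows.append({"group": 1, "parameter": "Membership (%)", "estimate": 100.0,
                         "se": np.nan, "t": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


# ----------------------------------------------------------- thin wrappers


def fit(data, spec: TrajectoryModelSpec, **options) -> FitResult:
    """Functional wrapper: fit a censored trajectory mixture and return its summary."""
    est = CensoredTrajectoryMixture(
        n_groups=spec.k, order=spec.orders, lower_bound=spec.lower_bound,
        upper_bound=spec.upper_bound, **options)
    est.fit(data)
    return est.result_


def match_groups(coefficients, reference_coefficients, days) -> list[int]:
    """Match fitted groups to reference groups by mean-curve proximity.

    Returns, for each reference group g, the index of the fitted group whose
    mean curve over ``days`` is closest under the total squared distance of
    the best overall one-to-one matching. Curve matching is used instead of
    intercept ranking because intercepts of groups whose curves separate only
    late in the study are estimated with large uncertainty, while the curves
    as a whole are well separated.
    """
    from itertools import permutations

    days = np.asarray(days, dtype=float)
    fitted = np.vstack([design_matrix(days, len(b) - 1) @ np.asarray(b, float)
                        for b in coefficients])
    ref = np.vstack([design_matrix(days, len(b) - 1) @ np.asarray(b, float)
                     for b in reference_coefficients])
    if len(fitted) != len(ref):
        raise ValueError("group counts differ; cannot match")
    best = min(permutations(range(len(ref))),
               key=lambda p: float(((fitted[list(p)] - ref) ** 2).sum()))
    return list(best)


def wald_tests(fitted) -> pd.DataFrame:
    """Per-parameter estimate / SE / t / two-sided normal p table of a fitted model."""
    table = fitted.params_table if isinstance(fitted, FitResult) else fitted.params_table_
    if table is None:
        raise ValueError("fit was run with compute_se=False; no Wald table available")
    return table
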