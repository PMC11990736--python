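"""Parsimony-based choice of the number of trajectory groups.

A candidate group number k is acceptable when (i) every estimated membership
percentage exceeds 10%, (ii) every membership p-value is below 0.1, and
(iii) every subject has a maximum posterior probability above 0.95. Among
acceptable candidates (k = 1 is always an eligible baseline) the one with the
largest observation-count BIC is the most parsimonious model. Homogeneity
(a single group) is rejected when the selected k exceeds 1 and its BIC beats
the k = 1 BIC by more than 10. All thresholds are strict inequalities and
configurable; the criteria apply to membership parameters only, never to
trajectory coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import CensoredTrajectoryMixture

__all__ = [
    "Thresholds",
    "CandidateSummary",
    "SelectionReport",
    "apply_parsimony_criteria",
    "scan_candidates",
    "select_most_parsimonious",
    "TrajectoryGroupSelector",
]


@dataclass(frozen=True)
class Thresholds:
    """Strict-inequality acceptance thresholds of the parsimony procedure."""

    membership_min: float = 0.10   # every group proportion must exceed this
    pvalue_max: float = 0.1        # every membership p-value must be below this
    bpp_min: float = 0.95          # every subject's max BPP must exceed this
    delta_bic: float = 10.0        # BIC gain over k=1 needed to reject homogeneity


@dataclass
class CandidateSummary:
    """One row of the group-number scan. Flags are None (N/A) for k = 1."""

    k: int
    bic_obs: float
    memberships_ok: bool | None = None
    membership_pvalues_ok: bool | None = None
    bpp_ok: bool | None = None
    converged: bool = True
    fit: object = None  # fitted CensoredTrajectoryMixture or FitResult, optional

    @property
    def passes(self) -> bool:
        if self.k == 1:
            return self.converged
        return bool(self.converged and self.memberships_ok
                    and self.membership_pvalues_ok and self.bpp_ok)


@dataclass
class SelectionReport:
    candidates: list
    selected_k: int
    delta_bic_vs_k1: float | None
    homogeneity_rejected: bool
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Scan summary in the layout of the published group-number table."""
        def fmt(flag):
            return "N/A" if flag is None else ("YES" if flag else "NO")
        rows = [
            {
                "k": c.k,
                "all_memberships_gt_10pct": fmt(c.memberships_ok),
                "membership_pvalues_lt_0.1": fmt(c.membership_pvalues_ok),
                "all_bpp_gt_95pct": fmt(c.bpp_ok),
                "BIC": c.bic_obs,
                "converged": c.converged,
            }
            for c in sorted(self.candidates, key=lambda c: c.k)
        ]
        return pd.DataFrame(rows)


def apply_parsimony_criteria(estimator, data=None, thresholds: Thresholds = Thresholds()) -> CandidateSummary:
    """Evaluate the three acceptance criteria on a fitted mixture.

    ``data`` defaults to the training table retained by the estimator; it is
    only needed for the per-subject posterior criterion.
    """
    k = estimator.spec_.k
    cand = CandidateSummary(k=k, bic_obs=estimator.bic_, converged=estimator.converged_,
                            fit=estimator)
    if k == 1:
        return cand
    cand.memberships_ok = bool(np.all(estimator.weights_ > thresholds.membership_min))
    table = estimator.params_table_
    if table is None:
        raise ValueError("candidate was fitted with compute_se=False; membership p-values unavailable")
    pvals = table.loc[table["parameter"] == "Membership (%)", "p"].to_numpy()
    cand.membership_pvalues_ok = bool(np.all(np.isfinite(pvals)) and np.all(pvals < thresholds.pvalue_max))
    if data is None:
        probs, _ = estimator._posterior(estimator._prep_train)
    else:
        probs = estimator.predict_proba(data).to_numpy()
    cand.bpp_ok = bool(np.all(probs.max(axis=1) > thresholds.bpp_min))
    return cand


def scan_candidates(data, k_values, order=2, thresholds: Thresholds = Thresholds(),
                    **fit_options) -> list[CandidateSummary]:
    """Fit one candidate mixture per group number and flag the criteria.

    Non-convergent candidates are reported with converged=False (and are
    never selected). Deterministic given the random_state in fit_options.
    """
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values or k_values[0] < 1:
        raise ValueError("k_values must be a non-empty collection of integers >= 1")
    out = []
    for k in k_values:
        est = CensoredTrajectoryMixture(n_groups=k, order=order, **fit_options)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(data)
        out.append(apply_parsimony_criteria(est, thresholds=thresholds))
    return out


def select_most_parsimonious(candidates, thresholds: Thresholds = Thresholds()) -> SelectionReport:
    """Pick the acceptable candidate with the largest BIC and test homogeneity."""
    if not candidates:
        raise ValueError("need at least one candidate")
    notes = []
    eligible = [c for c in candidates if c.passes]
    k1 = next((c for c in candidates if c.k == 1), None)
    if not eligible:
        notes.append("no candidate passed the acceptance criteria; falling back to k=1")
        selected = k1 if k1 is not None else min(candidates, key=lambda c: c.k)
        return SelectionReport(list(candidates), selected.k, 0.0 if k1 else None, False, notes)
    selected = max(eligible, key=lambda c: (c.bic_obs, -c.k))
    delta = None
    if k1 is not None:
        delta = float(selected.bic_obs - k1.bic_obs)
    else:
        notes.append("k=1 baseline absent from the scan; homogeneity not testable")
    rejected = bool(selected.k > 1 and delta is not None and delta > thresholds.delta_bic)
    return SelectionReport(list(candidates), selected.k, delta, rejected, notes)


class TrajectoryGroupSelector(BaseEstimator):
    """Scan k = k_min..k_max, apply the parsimony criteria, keep the best fit.

    After ``fit``, ``selected_k_``, ``report_`` and ``best_estimator_`` hold
    the chosen group number, the full scan report, and the fitted mixture for
    the selected k.
    """

    def __init__(self, k_min=1, k_max=4, order=2, membership_min=0.10, pvalue_max=0.1,
                 bpp_min=0.95, delta_bic=10.0, n_starts=8, short_run_iters=25,
                 tol=1e-8, max_iter=500, random_state=None):
        self.k_min = k_min
        self.k_max = k_max
        self.order = order
        self.membership_min = membership_min
        self.pvalue_max = pvalue_max
        self.bpp_min = bpp_min
        self.delta_bic = delta_bic
        self.n_starts = n_starts
        self.short_run_iters = short_run_iters
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, data, y=None):
        thresholds = Thresholds(self.membership_min, self.pvalue_max,
                                self.bpp_min, self.delta_bic)
        candidates = scan_candidates(
            data, range(self.k_min, self.k_max + 1), order=self.order,
            thresholds=thresholds, n_starts=self.n_starts,
            short_run_iters=self.short_run_iters, tol=self.tol,
            max_iter=self.max_iter, random_state=self.random_state)
        report = select_most_parsimonious(candidates, thresholds)
        self.report_ = report
        self.selected_k_ = report.selected_k
        self.best_estimator_ = next(c.fit for c in candidates if c.k == report.selected_k)
        return self

    def predict(self, data):
        return self.best_estimator_.predict(data)

    def predict_proba(self, data):
        return self.best_estimator_.predict_proba(data)
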