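"""Censored-normal (Tobit) likelihood primitives for trajectory mixtures.

A trajectory group j is a polynomial mean curve mu_j(t) = x(t)' beta_j with a
shared residual standard deviation sigma. Observed consumption is the latent
normal draw clipped to [lower, upper]; values recorded exactly at a bound
contribute cumulative probability mass instead of density (the CNORM model).
Subjects' repeated measures are conditionally independent given their latent
group, so a subject's group-conditional log-likelihood is the sum of the
per-observation censored-normal log-densities along their series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, logsumexp
from scipy.stats import norm

__all__ = [
    "TrajectoryModelSpec",
    "ParameterSet",
    "design_row",
    "design_matrix",
    "trajectory_mean",
    "cnorm_logdensity",
    "subject_group_loglik",
    "mixture_loglik",
    "posterior_probs",
    "information_criteria",
    "n_free_parameters",
]

MAX_ORDER = 4


@dataclass(frozen=True)
class TrajectoryModelSpec:
    """Model family: number of groups, per-group polynomial order, censoring bounds."""

    k: int
    orders: tuple[int, ...]
    lower_bound: float = 0.0
    upper_bound: float = np.inf

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        orders = self.orders
        if np.isscalar(orders):
            orders = (int(orders),) * self.k
        else:
            orders = tuple(int(o) for o in orders)
        if len(orders) != self.k:
            raise ValueError(f"need one polynomial order per group: k={self.k}, got {len(orders)}")
        for o in orders:
            if not 0 <= o <= MAX_ORDER:
                raise ValueError(f"polynomial order must be in 0..{MAX_ORDER}, got {o}")
        object.__setattr__(self, "orders", orders)
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be strictly below upper_bound")

    @property
    def n_free_parameters(self) -> int:
        return n_free_parameters(self.orders, self.k)


def n_free_parameters(orders, k: int) -> int:
    """Free-parameter count p: all polynomial coefficients + sigma + (k-1) proportions."""
    return int(sum(o + 1 for o in orders)) + 1 + (k - 1)


@dataclass
class ParameterSet:
    """Mixture parameters: per-group coefficients, shared sigma, membership proportions."""

    beta: list = field(default_factory=list)  # one 1-D coefficient array per group
    sigma: float = 1.0
    pi: np.ndarray = None

    def __post_init__(self):
        self.beta = [np.asarray(b, dtype=float) for b in self.beta]
        self.pi = np.asarray(self.pi, dtype=float)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if np.any(self.pi <= 0):
            raise ValueError("all membership proportions must be > 0")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"membership proportions must sum to 1, got {self.pi.sum()!r}")
        if len(self.beta) != len(self.pi):
            raise ValueError("beta and pi must have one entry per group")


def design_row(t: float, order: int) -> np.ndarray:
    """Polynomial basis (1, t, t^2, ..., t^order) at a single time point."""
    if not 0 <= order <= MAX_ORDER:
        raise ValueError(f"polynomial order must be in 0..{MAX_ORDER}, got {order}")
    return np.power(float(t), np.arange(order + 1))


def design_matrix(t, order: int) -> np.ndarray:
    """Stacked design rows for a vector of time points, shape (len(t), order + 1)."""
    if not 0 <= order <= MAX_ORDER:
        raise ValueError(f"polynomial order must be in 0..{MAX_ORDER}, got {order}")
    t = np.asarray(t, dtype=float)
    return np.power.outer(t, np.arange(order + 1))


def trajectory_mean(beta, t):
    """Latent (pre-censoring) mean of a trajectory group at time t."""
    beta = np.asarray(beta, dtype=float)
    if np.ndim(t) == 0:
        return float(design_row(float(t), len(beta) - 1) @ beta)
    return design_matrix(t, len(beta) - 1) @ beta


def _censor_masks(y: np.ndarray, lower: float, upper: float):
    at_lower = y <= lower if np.isfinite(lower) else np.zeros(y.shape, bool)
    at_upper = y >= upper if np.isfinite(upper) else np.zeros(y.shape, bool)
    return at_lower, at_upper


def cnorm_logdensity(y, mu, sigma, lower=0.0, upper=np.inf):
    """Censored-normal log density/mass of observed values.

    Interior values get the Gaussian log pdf; values at the lower bound get
    log Phi((lower - mu)/sigma); values at the upper bound get the matching
    upper-tail log mass. Evaluated through the log-CDF so it stays finite for
    standardized distances up to several tens.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    y = np.asarray(y, dtype=float)
    if np.any(y < lower) or np.any(y > upper):
        raise ValueError("observed values must lie within the censoring bounds")
    mu = np.broadcast_to(np.asarray(mu, dtype=float), np.broadcast_shapes(y.shape, np.shape(mu)))
    yb = np.broadcast_to(y, mu.shape)
    at_lower, at_upper = _censor_masks(yb, lower, upper)
    out = norm.logpdf(yb, loc=mu, scale=sigma)
    if at_lower.any():
        out = np.where(at_lower, log_ndtr((lower - mu) / sigma), out)
    if at_upper.any():
        out = np.where(at_upper, log_ndtr(-(upper - mu) / sigma), out)
    return out if out.shape else float(out)


def cnorm_loglik_terms(y, mu, sigma, at_lower, at_upper, with_grad=False):
    """Vectorized censored-normal log-likelihood terms with optional gradients.

    `mu` may be (n,) or (n, k); masks refer to y and broadcast along groups.
    Returns ll (same shape as mu) and, if requested, d ll/d mu and
    d ll/d log sigma.
    """
    if mu.ndim > y.ndim:
        y = y[:, None]
        at_lower = at_lower[:, None]
        at_upper = at_upper[:, None]
    r = (y - mu) / sigma
    ll = -np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * r * r
    dmu = r / sigma
    dlogsig = r * r - 1.0
    if at_lower.any():
        # at the lower bound y == lower, so r is already (lower - mu)/sigma
        zl = np.where(at_lower, r, 0.0)
        log_cdf = log_ndtr(zl)
        ll = np.where(at_lower, log_cdf, ll)
        if with_grad:
            h = np.exp(norm.logpdf(zl) - log_cdf)
            dmu = np.where(at_lower, -h / sigma, dmu)
            dlogsig = np.where(at_lower, -h * zl, dlogsig)
    if at_upper.any():
        zu = np.where(at_upper, r, 0.0)
        log_sf = log_ndtr(-zu)
        ll = np.where(at_upper, log_sf, ll)
        if with_grad:
            h = np.exp(norm.logpdf(zu) - log_sf)
            dmu = np.where(at_upper, h / sigma, dmu)
            dlogsig = np.where(at_upper, h * zu, dlogsig)
    if with_grad:
        return ll, dmu, dlogsig
    return ll


def subject_group_loglik(series, beta, sigma, lower=0.0, upper=np.inf) -> float:
    """Log-likelihood of one subject's (day, value) series under one group's curve."""
    series = list(series)
    if not series:
        raise ValueError("subject series must be non-empty")
    days = np.array([d for d, _ in series], dtype=float)
    values = np.array([v for _, v in series], dtype=float)
    mu = design_matrix(days, len(np.asarray(beta)) - 1) @ np.asarray(beta, dtype=float)
    return float(np.sum(cnorm_logdensity(values, mu, sigma, lower, upper)))


def _subject_group_loglik_matrix(data, spec: TrajectoryModelSpec, params: ParameterSet):
    """l_ij matrix (subjects x groups) from a long-format table."""
    subj, codes = np.unique(np.asarray(data["subject_id"]), return_inverse=True)
    days = np.asarray(data["day"], dtype=float)
    y = np.asarray(data["value"], dtype=float)
    at_lower, at_upper = _censor_masks(y, spec.lower_bound, spec.upper_bound)
    X = design_matrix(days, max(spec.orders))
    mu = np.column_stack([X[:, : len(b)] @ b for b in params.beta])
    ll_obs = cnorm_loglik_terms(y, mu, params.sigma, at_lower, at_upper)
    l_ij = np.zeros((len(subj), spec.k))
    for j in range(spec.k):
        l_ij[:, j] = np.bincount(codes, weights=ll_obs[:, j], minlength=len(subj))
    return subj, l_ij


def mixture_loglik(data, spec: TrajectoryModelSpec, params: ParameterSet) -> float:
    """Total mixture log-likelihood L = sum_i log sum_j pi_j exp(l_ij)."""
    _check_consistent(spec, params)
    _, l_ij = _subject_group_loglik_matrix(data, spec, params)
    return float(np.sum(logsumexp(l_ij + np.log(params.pi), axis=1)))


def posterior_probs(data, spec: TrajectoryModelSpec, params: ParameterSet):
    """Bayesian posterior membership probabilities, one row per subject.

    Returns (subject_ids, matrix) with rows summing to 1; computed on the log
    scale so extreme likelihood ratios give exact 0/1 without overflow.
    """
    _check_consistent(spec, params)
    subj, l_ij = _subject_group_loglik_matrix(data, spec, params)
    logw = l_ij + np.log(params.pi)
    probs = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    return subj, probs


def _check_consistent(spec: TrajectoryModelSpec, params: ParameterSet):
    if len(params.beta) != spec.k or len(params.pi) != spec.k:
        raise ValueError("parameter set does not match model spec (group count)")
    for b, o in zip(params.beta, spec.orders):
        if len(b) != o + 1:
            raise ValueError(f"coefficient vector length {len(b)} does not match order {o}")


def information_criteria(loglik: float, p: int, n_obs: int, n_subj: int):
    """Penalized criteria in larger-is-better form.

    bic_obs = L - (p/2) ln N_obs, bic_subj = L - (p/2) ln N_subj, aic = L - p.
    Both sample-size conventions are reported because GBTM practice quotes
    either the observation count or the subject count.
    """
    if p < 0 or n_obs < n_subj or n_subj < 1:
        raise ValueError("need p >= 0 and n_obs >= n_subj >= 1")
    if p == 0:
        return loglik, loglik, loglik
    bic_obs = loglik - (p / 2.0) * np.log(n_obs)
    bic_subj = loglik - (p / 2.0) * np.log(n_subj)
    aic = loglik - p
    return float(bic_obs), float(bic_subj), float(aic)
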