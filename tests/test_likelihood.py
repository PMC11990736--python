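"""Censored-normal likelihood primitives: closed-form values, stability, identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from gbtm.likelihood import (
    ParameterSet,
    TrajectoryModelSpec,
    cnorm_logdensity,
    design_row,
    information_criteria,
    mixture_loglik,
    posterior_probs,
    subject_group_loglik,
    trajectory_mean,
)

# Fitted quadratic coefficients of the reference cohort's groups
BETA_G2 = (1.61339, -0.061, 0.00109)
BETA_G3 = (2.4755, 0.19721, -0.00225)


class TestPolynomialBasis:
    @pytest.mark.parametrize(
        "t, order, expected",
        [(0, 2, [1, 0, 0]), (57, 2, [1, 57, 3249]), (5, 0, [1]), (2, 4, [1, 2, 4, 8, 16])],
    )
    def test_design_row(self, t, order, expected):
        np.testing.assert_allclose(design_row(t, order), expected)

    @pytest.mark.parametrize("order", [-1, 5])
    def test_order_out_of_range(self, order):
        with pytest.raises(ValueError, match="order"):
            design_row(3, order)

    @pytest.mark.parametrize(
        "beta, t, expected",
        [
            (BETA_G3, 0, 2.4755),        # intercept is the extrapolated day-0 value
            (BETA_G3, 57, 6.4062),       # early drinkers end the study high
            (BETA_G2, 57, 1.6778),       # non-drinkers stay low throughout
        ],
    )
    def test_trajectory_mean(self, beta, t, expected):
        assert trajectory_mean(beta, t) == pytest.approx(expected, abs=5e-5)


class TestCnormLogdensity:
    def test_interior_peak(self):
        assert cnorm_logdensity(1.0, 1.0, 1.0, lower=-np.inf) == pytest.approx(
            -0.5 * np.log(2 * np.pi))

    def test_mass_at_bound_symmetric(self):
        assert cnorm_logdensity(0.0, 0.0, 1.0, lower=0.0) == pytest.approx(np.log(0.5))

    def test_mass_at_bound_matches_gaussian_cdf_oracle(self):
        # numerical integration of the latent normal below the bound
        mu, sigma = 1.61339, 1.60771
        mass, _ = quad(lambda x: norm.pdf(x, mu, sigma), -30, 0.0)
        got = cnorm_logdensity(0.0, mu, sigma, lower=0.0)
        assert got == pytest.approx(np.log(mass), abs=1e-8)
        assert got == pytest.approx(-1.8466, abs=5e-4)

    def test_upper_censoring_mirror(self):
        low = cnorm_logdensity(0.0, 0.3, 1.2, lower=0.0)
        high = cnorm_logdensity(0.0, -0.3, 1.2, lower=-np.inf, upper=0.0)
        assert low == pytest.approx(high)

    def test_extreme_standardized_distance_stays_finite(self):
        val = cnorm_logdensity(0.0, 55.0, 1.5, lower=0.0)  # z about -36.7
        assert np.isfinite(val) and val < -600

    def test_invalid_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            cnorm_logdensity(1.0, 0.0, 0.0)

    def test_value_outside_bounds(self):
        with pytest.raises(ValueError, match="bounds"):
            cnorm_logdensity(-0.5, 0.0, 1.0, lower=0.0)


class TestSubjectLoglik:
    def test_single_observation_equals_density(self):
        series = [(10.0, 1.2)]
        expected = cnorm_logdensity(1.2, trajectory_mean(BETA_G2, 10.0), 1.6, lower=0.0)
        assert subject_group_loglik(series, BETA_G2, 1.6) == pytest.approx(expected)

    def test_two_identical_interior_observations(self):
        mu0 = trajectory_mean((3.0,), 1.0)
        series = [(1.0, mu0), (2.0, mu0)]
        got = subject_group_loglik(series, (3.0,), 2.0, lower=-np.inf)
        assert got == pytest.approx(2 * (-0.5 * np.log(2 * np.pi * 4.0)))

    def test_density_peak_decreases_with_sigma(self):
        series = [(5.0, trajectory_mean(BETA_G3, 5.0)), (6.0, trajectory_mean(BETA_G3, 6.0))]
        assert subject_group_loglik(series, BETA_G3, 1.0) > subject_group_loglik(
            series, BETA_G3, 10.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            subject_group_loglik([], BETA_G2, 1.0)


def _toy_table(values_by_subject):
    rows = []
    for sid, series in values_by_subject.items():
        for day, value in series:
            rows.append({"subject_id": sid, "day": day, "value": value})
    return pd.DataFrame(rows)


class TestMixtureLoglik:
    spec1 = TrajectoryModelSpec(1, (1,), 0.0, np.inf)
    spec2 = TrajectoryModelSpec(2, (1, 1), 0.0, np.inf)

    data = _toy_table({
        "a": [(1, 0.5), (2, 0.0), (3, 1.4)],
        "b": [(1, 2.2), (3, 3.1)],
        "c": [(2, 0.0), (3, 0.2)],
    })

    def test_degenerate_mixture_is_censored_regression(self):
        beta = (0.4, 0.3)
        p1 = ParameterSet(beta=[beta], sigma=0.9, pi=[1.0])
        expected = sum(
            subject_group_loglik([(d, v) for d, v in zip(sub["day"], sub["value"])],
                                 beta, 0.9)
            for _, sub in self.data.groupby("subject_id"))
        assert mixture_loglik(self.data, self.spec1, p1) == pytest.approx(expected)

    def test_identical_groups_collapse_to_single_group(self):
        beta = (0.4, 0.3)
        p1 = ParameterSet(beta=[beta], sigma=0.9, pi=[1.0])
        p2 = ParameterSet(beta=[beta, beta], sigma=0.9, pi=[0.5, 0.5])
        assert mixture_loglik(self.data, self.spec2, p2) == pytest.approx(
            mixture_loglik(self.data, self.spec1, p1))

    def test_duplicating_subjects_doubles_loglik(self):
        p2 = ParameterSet(beta=[(0.2, 0.1), (1.5, 0.4)], sigma=0.8, pi=[0.3, 0.7])
        doubled = pd.concat([self.data, self.data.assign(subject_id=self.data.subject_id + "_copy")])
        assert mixture_loglik(doubled, self.spec2, p2) == pytest.approx(
            2 * mixture_loglik(self.data, self.spec2, p2))

    @pytest.mark.parametrize("censored", [False, True])
    def test_matches_brute_force_assignment_enumeration(self, censored):
        """Mixture likelihood equals the sum over all group-assignment vectors
        of the pi-weighted product of subject likelihoods."""
        from itertools import product

        lower = 0.0 if censored else -np.inf
        spec = TrajectoryModelSpec(3, (1, 1, 1), lower, np.inf)
        params = ParameterSet(beta=[(0.2, 0.05), (1.0, -0.1), (2.0, 0.3)],
                              sigma=0.7, pi=[0.2, 0.5, 0.3])
        subjects = list(self.data.groupby("subject_id"))
        lik = np.zeros((len(subjects), 3))
        for i, (_, sub) in enumerate(subjects):
            for j in range(3):
                series = list(zip(sub["day"], sub["value"]))
                lik[i, j] = np.exp(subject_group_loglik(series, params.beta[j],
                                                        params.sigma, lower))
        total = 0.0
        for assignment in product(range(3), repeat=len(subjects)):
            total += np.prod([params.pi[j] * lik[i, j] for i, j in enumerate(assignment)])
        assert mixture_loglik(self.data, spec, params) == pytest.approx(
            np.log(total), abs=1e-10)

    def test_label_permutation_invariance(self):
        params = ParameterSet(beta=[(0.2, 0.05), (1.0, -0.1), (2.0, 0.3)],
                              sigma=0.7, pi=[0.2, 0.5, 0.3])
        spec = TrajectoryModelSpec(3, (1, 1, 1), 0.0, np.inf)
        perm = [2, 0, 1]
        permuted = ParameterSet(beta=[params.beta[j] for j in perm], sigma=0.7,
                                pi=params.pi[perm])
        assert mixture_loglik(self.data, spec, permuted) == pytest.approx(
            mixture_loglik(self.data, spec, params))

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ParameterSet(beta=[(0.2, 0.05), (1.0, -0.1)], sigma=0.7, pi=[0.5, 0.6])


class TestPosteriors:
    def test_equal_likelihoods_return_prior(self):
        beta = (0.4, 0.3)
        spec = TrajectoryModelSpec(3, (1, 1, 1), 0.0, np.inf)
        params = ParameterSet(beta=[beta, beta, beta], sigma=0.9, pi=[0.3, 0.5, 0.2])
        data = _toy_table({"a": [(1, 0.5), (2, 1.0)]})
        _, probs = posterior_probs(data, spec, params)
        np.testing.assert_allclose(probs[0], [0.3, 0.5, 0.2], atol=1e-12)

    def test_bayes_rule_known_ratio(self):
        # a single observation engineered so l_1 - l_2 = ln 2 with pi = (1/2, 1/2)
        sigma = 1.0
        delta = np.sqrt(2 * np.log(2.0))
        spec = TrajectoryModelSpec(2, (0, 0), -np.inf, np.inf)
        params = ParameterSet(beta=[(0.0,), (delta,)], sigma=sigma, pi=[0.5, 0.5])
        data = _toy_table({"a": [(1, 0.0)]})
        _, probs = posterior_probs(data, spec, params)
        np.testing.assert_allclose(probs[0], [2 / 3, 1 / 3], atol=1e-12)

    def test_overwhelming_evidence_is_exact_without_overflow(self):
        # likelihood ratio e^500 must give (1, 0) exactly, not NaN
        spec = TrajectoryModelSpec(2, (0, 0), -np.inf, np.inf)
        delta = np.sqrt(2 * 500.0)
        params = ParameterSet(beta=[(0.0,), (delta,)], sigma=1.0, pi=[0.5, 0.5])
        data = _toy_table({"a": [(1, 0.0)]})
        _, probs = posterior_probs(data, spec, params)
        assert np.isfinite(probs).all()
        assert probs[0, 0] == pytest.approx(1.0, abs=1e-15)
        assert probs[0, 1] < 1e-100

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 5))
        spec = TrajectoryModelSpec(k, (0,) * k, -np.inf, np.inf)
        pi = rng.dirichlet(np.ones(k) * 2)
        params = ParameterSet(beta=[(float(rng.normal(scale=5)),) for _ in range(k)],
                              sigma=float(rng.uniform(0.2, 3)), pi=pi)
        data = _toy_table({f"s{i}": [(1, float(rng.normal()))] for i in range(4)})
        _, probs = posterior_probs(data, spec, params)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs >= 0) and np.all(probs <= 1)


class TestInformationCriteria:
    def test_reference_footer_identities(self):
        """The published footer values satisfy the penalized-form identities
        with p = 12 free parameters (9 coefficients + sigma + 2 proportions)."""
        bic_obs, bic_subj, aic = information_criteria(-3444.35, 12, 1805, 35)
        assert round(bic_obs, 2) == -3489.34
        assert round(bic_subj, 2) == -3465.68
        assert round(aic, 2) == -3456.35

    def test_degenerate_zero_parameters(self):
        assert information_criteria(0.0, 0, 10, 5) == (0.0, 0.0, 0.0)

    def test_spec_parameter_count(self):
        assert TrajectoryModelSpec(3, (2, 2, 2), 0.0, np.inf).n_free_parameters == 12
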