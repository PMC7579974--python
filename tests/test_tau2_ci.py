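"""Interval estimators for tau2 and the weighted-chi-square CDF behind BJ/J."""

import numpy as np
import pytest
from scipy.stats import chi2

from lrrmeta import (
    MetaDataset,
    estimate_tau2,
    generalized_q,
    generalized_q_interval,
    profile_likelihood_interval,
    q_profile_interval,
    reml_tau2,
    weighted_chisq_cdf,
)
from lrrmeta.tau2 import q_at, restricted_loglik
from lrrmeta.tau2_ci import _bj_eigenvalues

from conftest import random_dataset


class TestWeightedChisqCdf:
    def test_chi_square_closed_forms(self):
        """With m equal unit coefficients the distribution is chi2(m)."""
        assert weighted_chisq_cdf([1.0], chi2.ppf(0.95, 1)) == pytest.approx(0.95, abs=1e-9)
        assert weighted_chisq_cdf([1.0, 1.0], chi2.ppf(0.95, 2)) == pytest.approx(0.95, abs=1e-9)
        # near-equal coefficients exercise the series path against chi2
        mu = np.linspace(1.0, 1.0 + 1e-9, 4)
        for x in (0.5, 3.0, 11.0):
            assert weighted_chisq_cdf(mu, x) == pytest.approx(
                chi2.cdf(x, 4), abs=1e-7
            )

    def test_against_monte_carlo_oracle(self):
        """10^6-draw Monte-Carlo oracle for Z1^2 + 2 Z2^2 + 3 Z3^2."""
        mu = np.array([1.0, 2.0, 3.0])
        rng = np.random.default_rng(42)
        q = rng.standard_normal((10**6, 3)) ** 2 @ mu
        for x in (2.0, 6.0, 15.0):
            mc = float(np.mean(q <= x))
            se = np.sqrt(mc * (1 - mc) / 10**6)
            assert abs(weighted_chisq_cdf(mu, x) - mc) < 3 * se

    def test_monotone_in_x_and_bounds(self):
        mu = [0.4, 1.3, 2.2, 0.9]
        xs = np.linspace(0.0, 30.0, 40)
        vals = [weighted_chisq_cdf(mu, x) for x in xs]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.0
        assert vals[-1] <= 1.0

    def test_rejects_negative_coefficients(self):
        with pytest.raises(ValueError):
            weighted_chisq_cdf([1.0, -0.1], 2.0)
        with pytest.raises(ValueError):
            weighted_chisq_cdf([0.0, 0.0], 2.0)

    @pytest.mark.parametrize("tau2", [0.0, 0.2])
    @pytest.mark.parametrize("rule", ["IV-null", "inverse-SD"])
    def test_eigenvalues_carry_the_first_moment(self, tau2, rule):
        """The eigenvalue sum must equal E[Q_a] under the random-effects
        model (the moment the DL/J estimators match)."""
        data = random_dataset(np.random.default_rng(5), k=7)
        a = 1.0 / data.var if rule == "IV-null" else 1.0 / np.sqrt(data.var)
        eig = _bj_eigenvalues(data, a, tau2)
        s = data.var + tau2
        expected = np.sum(a * s) - np.sum(a**2 * s) / np.sum(a)
        assert eig.sum() == pytest.approx(expected, rel=1e-10)


class TestQProfile:
    def test_equal_variance_closed_form(self, toy_equal_var):
        """Equal variances collapse F to sum((y-ybar)^2)/(v^2+tau2):
        the bounds are 0.5/chi2_quantile - 0.1, truncated at zero below."""
        ci = q_profile_interval(toy_equal_var)
        assert ci.lower == 0.0 and ci.lower_truncated
        expected_upper = 0.5 / chi2.ppf(0.025, 2) - 0.1
        assert ci.upper == pytest.approx(expected_upper, abs=1e-6)

    def test_tiny_variance_homogeneous_gives_null_interval(self):
        data = MetaDataset.from_arrays([0.2, 0.2, 0.2, 0.2], [1e-4] * 4)
        ci = q_profile_interval(data)
        assert (ci.lower, ci.upper) == (0.0, 0.0)
        assert ci.lower_truncated and ci.upper_truncated

    @pytest.mark.parametrize("seed", range(8))
    def test_endpoints_solve_defining_equations(self, seed):
        data = random_dataset(np.random.default_rng(300 + seed))
        ci = q_profile_interval(data)
        k = data.k
        if not ci.lower_truncated:
            assert q_at(data, ci.lower) == pytest.approx(chi2.ppf(0.975, k - 1), abs=1e-6)
        if np.isfinite(ci.upper) and not ci.upper_truncated:
            assert q_at(data, ci.upper) == pytest.approx(chi2.ppf(0.025, k - 1), abs=1e-6)


class TestGeneralizedQIntervals:
    def test_reduce_to_q_profile_for_equal_variances(self, toy_equal_var):
        """With equal variances all weight rules are proportional, the Q
        statistics coincide up to scale, and BJ = J = QP."""
        qp = q_profile_interval(toy_equal_var)
        bj = generalized_q_interval(toy_equal_var, "IV-null")
        jj = generalized_q_interval(toy_equal_var, "inverse-SD")
        for ci in (bj, jj):
            assert ci.lower == pytest.approx(qp.lower, abs=1e-6)
            assert ci.upper == pytest.approx(qp.upper, abs=2e-5)

    @pytest.mark.parametrize("rule", ["IV-null", "inverse-SD"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_endpoints_solve_defining_equations(self, rule, seed):
        """At each bound, the weighted-chi-square CDF of the observed Q_a
        must equal the corresponding tail probability."""
        data = random_dataset(np.random.default_rng(400 + seed))
        ci = generalized_q_interval(data, rule)
        a = 1.0 / data.var if rule == "IV-null" else 1.0 / np.sqrt(data.var)
        q_obs = generalized_q(data, a)
        if not ci.lower_truncated:
            p = weighted_chisq_cdf(_bj_eigenvalues(data, a, ci.lower), q_obs)
            assert p == pytest.approx(0.975, abs=1e-6)
        if np.isfinite(ci.upper) and not ci.upper_truncated:
            p = weighted_chisq_cdf(_bj_eigenvalues(data, a, ci.upper), q_obs)
            assert p == pytest.approx(0.025, abs=1e-6)


class TestProfileLikelihood:
    def test_homogeneous_lower_bound_zero(self, homogeneous):
        ci = profile_likelihood_interval(homogeneous)
        assert ci.lower == 0.0 and ci.lower_truncated

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_endpoints_match_likelihood_ratio_threshold(self, seed):
        """2[l(tau2_hat) - l(bound)] = chi2(1) 95% quantile at both bounds,
        verified against dense evaluation of the profile likelihood."""
        data = random_dataset(np.random.default_rng(500 + seed), k=5)
        ci = profile_likelihood_interval(data)
        fit = reml_tau2(data)
        l_max = restricted_loglik(data, fit.tau2)
        crit = chi2.ppf(0.95, 1)
        for bound, truncated in ((ci.lower, ci.lower_truncated), (ci.upper, ci.upper_truncated)):
            if not truncated and np.isfinite(bound):
                assert 2 * (l_max - restricted_loglik(data, bound)) == pytest.approx(
                    crit, abs=1e-6
                )
        # interval contents: every grid point inside must pass the LR test
        if np.isfinite(ci.upper):
            inside = np.linspace(ci.lower, ci.upper, 50)
            assert all(2 * (l_max - restricted_loglik(data, t)) <= crit + 1e-6 for t in inside)


@pytest.mark.parametrize("seed", range(10))
def test_intervals_contain_companion_point_estimates(seed):
    """QP contains MP, BJ contains DL, J contains J, PL contains REML
    whenever the bounds are not truncated."""
    data = random_dataset(np.random.default_rng(600 + seed))
    pairs = [
        (q_profile_interval(data), estimate_tau2(data, "MP").tau2),
        (generalized_q_interval(data, "IV-null"), estimate_tau2(data, "DL").tau2),
        (generalized_q_interval(data, "inverse-SD"), estimate_tau2(data, "J").tau2),
        (profile_likelihood_interval(data), estimate_tau2(data, "REML").tau2),
    ]
    for ci, point in pairs:
        lo = ci.lower if not ci.lower_truncated else 0.0
        assert lo - 1e-8 <= point
        if not ci.upper_truncated:
            assert point <= ci.upper + 1e-8
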