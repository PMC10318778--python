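"""Wald/IVW estimators, rescaling, the OR transformation and z-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr.gwas_io import AssociationRecord
from targetmr.mr import (
    ExposureConvention,
    MREstimate,
    difference_z_test,
    ivw,
    ivw_correlated,
    linear_to_logistic,
    rescale,
    wald_ratio,
)


def rec(beta, se=0.02, vid="rs1"):
    from scipy.stats import norm

    return AssociationRecord(vid, "1", 100, "A", "G", 0.3, beta, se,
                             2 * norm.sf(abs(beta / se)), 10_000)


def est(beta, se, scale="SD"):
    return MREstimate.from_beta_se(beta, se, method="wald", n_snps=1, scale=scale)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "out_beta,exp_beta,want_beta,want_se",
        [(0.10, 0.50, 0.20, 0.04), (0.10, -0.50, -0.20, 0.04), (0.0, 0.5, 0.0, 0.04)],
    )
    def test_ratio_and_delta_method_se(self, out_beta, exp_beta, want_beta, want_se):
        e = wald_ratio(rec(exp_beta), rec(out_beta))
        assert e.beta == pytest.approx(want_beta)
        assert e.se == pytest.approx(want_se)
        assert e.method == "wald" and e.n_snps == 1

    def test_null_outcome_gives_p_one(self):
        assert wald_ratio(rec(0.5), rec(0.0)).pvalue == pytest.approx(1.0)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(rec(0.0), rec(0.1))

    def test_ci_consistent_with_se(self):
        e = wald_ratio(rec(0.5), rec(0.1))
        z = 1.959963984540054
        assert e.ci_low == pytest.approx(e.beta - z * e.se)
        assert e.ci_high == pytest.approx(e.beta + z * e.se)


class TestIVW:
    def test_single_ratio_is_identity(self):
        r = est(0.2, 0.04)
        pooled = ivw([r])
        assert pooled.beta == pytest.approx(0.2)
        assert pooled.se == pytest.approx(0.04)
        assert pooled.method == "ivw_fixed"

    def test_two_ratio_weighted_mean(self):
        # w = 625 and 277.78; hand-computed weighted mean and SE.
        pooled = ivw([est(0.2, 0.04), est(0.3, 0.06)])
        assert pooled.beta == pytest.approx(0.23077, abs=1e-5)
        assert pooled.se == pytest.approx(0.03328, abs=1e-5)
        assert pooled.method == "ivw_fixed"

    def test_four_identical_ratios_hit_dispersion_floor(self):
        pooled = ivw([est(0.2, 0.04)] * 4)
        assert pooled.q_stat == pytest.approx(0.0, abs=1e-12)
        assert pooled.se == pytest.approx(0.02)  # floored at the fixed SE
        assert pooled.method == "ivw_random"

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(50):
            k = int(rng.integers(4, 9))
            betas = rng.normal(0.2, 0.3, k)
            ses = rng.uniform(0.01, 0.2, k)
            ratios = [est(b, s) for b, s in zip(betas, ses)]
            fixed = ivw(ratios, random_effects=False)
            rand = ivw(ratios, random_effects=True)
            assert rand.se >= fixed.se - 1e-15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ivw([])

    def test_switch_is_overridable(self):
        ratios = [est(0.2, 0.04), est(0.4, 0.05)]
        assert ivw(ratios).method == "ivw_fixed"
        assert ivw(ratios, random_effects=True).method == "ivw_random"


class TestIVWCorrelated:
    def test_identity_correlation_equals_fixed_ivw(self, rng):
        """GLS with rho = I reproduces fixed-effects IVW of the Wald ratios
        to at least 10 significant digits."""
        for _ in range(200):
            k = int(rng.integers(2, 8))
            x = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
            y = rng.normal(0.0, 0.1, k)
            s = rng.uniform(0.005, 0.05, k)
            gls = ivw_correlated(x, y, s, np.eye(k))
            ratios = [
                MREstimate.from_beta_se(yi / xi, si / abs(xi), "wald", 1)
                for xi, yi, si in zip(x, y, s)
            ]
            fixed = ivw(ratios, random_effects=False)
            assert gls.beta == pytest.approx(fixed.beta, rel=1e-10)
            assert gls.se == pytest.approx(fixed.se, rel=1e-10)

    def test_example_matches_uncorrelated_ivw(self):
        gls = ivw_correlated([0.5, 0.5], [0.10, 0.15], [0.02, 0.03], np.eye(2))
        assert gls.beta == pytest.approx(0.23077, abs=1e-5)

    def test_duplicated_snp_adds_no_information(self):
        single = wald_ratio(rec(0.5, 0.01), rec(0.10, 0.02))
        dup = ivw_correlated([0.5, 0.5], [0.10, 0.10], [0.02, 0.02], np.ones((2, 2)))
        assert dup.beta == pytest.approx(single.beta, rel=1e-6)
        assert dup.se >= single.se * (1 - 1e-6)

    def test_single_snp_reduces_to_wald(self):
        gls = ivw_correlated([0.5], [0.10], [0.02], np.eye(1))
        w = wald_ratio(rec(0.5, 0.01), rec(0.10, 0.02))
        assert gls.beta == pytest.approx(w.beta)
        assert gls.se == pytest.approx(w.se)


class TestRescale:
    def test_log_protection_ratio_to_life_years(self):
        e = rescale(est(0.05, 0.01, scale="log protection ratio"), 10, "life-years")
        assert (e.beta, e.se) == (pytest.approx(0.5), pytest.approx(0.1))
        assert e.scale == "life-years"

    def test_negation_swaps_ci(self):
        base = est(0.2, 0.05)
        neg = rescale(base, -1, base.scale)
        assert neg.beta == pytest.approx(-0.2)
        assert neg.ci_low == pytest.approx(-base.ci_high)
        assert neg.ci_high == pytest.approx(-base.ci_low)
        assert neg.pvalue == base.pvalue

    def test_identity(self):
        base = est(0.2, 0.05)
        assert rescale(base, 1, base.scale) == base

    def test_zero_factor_rejected(self):
        with pytest.raises(ValueError):
            rescale(est(0.2, 0.05), 0, "x")

    def test_exposure_convention_flips_sign(self):
        base = est(0.2, 0.05)
        flipped = ExposureConvention("per_sd_decrease").apply(base)
        assert flipped.beta == pytest.approx(-0.2)
        assert ExposureConvention("per_sd_increase").apply(base) == base


class TestLinearToLogistic:
    def test_formula_example(self):
        eff = linear_to_logistic(0.009, 0.0018, 0.1)
        assert eff.log_or == pytest.approx(0.1)
        assert eff.se == pytest.approx(0.02)
        assert eff.odds_ratio == pytest.approx(1.10517, abs=1e-5)

    def test_null_maps_to_or_one(self):
        assert linear_to_logistic(0.0, 0.01, 0.3).odds_ratio == pytest.approx(1.0)

    def test_balanced_case_fraction_divisor(self):
        assert linear_to_logistic(0.05, 0.01, 0.5).log_or == pytest.approx(0.2)

    @pytest.mark.parametrize("mu", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_case_fraction_rejected(self, mu):
        with pytest.raises(ValueError):
            linear_to_logistic(0.01, 0.01, mu)

    @pytest.mark.parametrize("mu", [0.05, 0.1, 0.5])
    def test_round_trip_recovers_planted_log_or(self, mu):
        """A linear-scale beta constructed analytically as alpha*mu*(1-mu)
        transforms back to the planted log OR exactly."""
        alpha = 0.3
        eff = linear_to_logistic(alpha * mu * (1 - mu), 0.01 * mu * (1 - mu), mu)
        assert eff.log_or == pytest.approx(alpha, rel=1e-12)
        assert eff.se == pytest.approx(0.01, rel=1e-12)

    def test_against_logistic_regression_fit(self, rng):
        """Independent oracle: on one simulated individual-level binary
        dataset, OLS beta / (mu(1-mu)) approximates the logistic-fit beta."""
        import statsmodels.api as sm

        n, maf, alpha0, alpha1 = 60_000, 0.3, -2.2, 0.12
        g = rng.binomial(2, maf, n).astype(float)
        p = 1 / (1 + np.exp(-(alpha0 + alpha1 * g)))
        y = (rng.random(n) < p).astype(float)
        X = sm.add_constant(g)
        logit = sm.Logit(y, X).fit(disp=0)
        ols = sm.OLS(y, X).fit()
        mu = y.mean()
        approx = linear_to_logistic(ols.params[1], ols.bse[1], mu)
        assert approx.log_or == pytest.approx(logit.params[1], rel=0.12)


class TestDifferenceZTest:
    def test_example(self):
        z, p = difference_z_test(est(0.2, 0.05), est(0.1, 0.05))
        assert z == pytest.approx(1.41421, abs=1e-5)
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_identical_estimates(self):
        z, p = difference_z_test(est(0.2, 0.05), est(0.2, 0.05))
        assert (z, p) == (0.0, pytest.approx(1.0))

    def test_extreme_difference(self):
        z, p = difference_z_test(est(0.3, 0.01), est(0.0, 0.01))
        assert z == pytest.approx(21.2, abs=0.05)
        assert p < 1e-15

    def test_mismatched_scales_rejected(self):
        with pytest.raises(ValueError):
            difference_z_test(est(0.2, 0.05, "SD"), est(0.1, 0.05, "log-odds"))

    @given(
        st.floats(-0.5, 0.5), st.floats(0.01, 0.2),
        st.floats(-0.5, 0.5), st.floats(0.01, 0.2),
        st.floats(0.1, 20.0),
    )
    @settings(max_examples=50)
    def test_z_invariant_under_common_rescale(self, b1, s1, b2, s2, factor):
        a, b = est(b1, s1), est(b2, s2)
        z0, _ = difference_z_test(a, b)
        z1, _ = difference_z_test(rescale(a, factor, "x"), rescale(b, factor, "x"))
        assert z1 == pytest.approx(z0, rel=1e-9, abs=1e-9)


class TestCoverage:
    def test_null_theta_estimates_centered_at_zero(self):
        from targetmr.gwas_io import harmonize
        from targetmr.synthetic import TwoSampleConfig, simulate_two_sample

        means = []
        for seed in range(200):
            exp, out = simulate_two_sample(TwoSampleConfig(theta=0.0, k=5, seed=seed))
            pair = harmonize(exp, out)
            ratios = [wald_ratio(pair.exposure[v], pair.outcome[v]) for v in pair.variant_ids]
            means.append(ivw(ratios).beta)
        means = np.asarray(means)
        assert abs(means.mean()) < 3 * means.std(ddof=1) / math.sqrt(len(means))
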