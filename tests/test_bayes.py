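"""Bayesian conditional logistic regression: posterior math and sampler checks."""

import math

import numpy as np
import pytest
from scipy import stats

from matchedcc import (
    FLAT_PRIOR,
    MHT_ORIGINAL_PRIOR,
    PriorSpec,
    build_design,
    conditional_loglik,
    fit_clogit,
    log_posterior,
    mix_over_imputations,
    prior_sensitivity,
    sample_posterior,
    simulate_matched_design,
)
from matchedcc.bayes import default_priors


class TestLogPosterior:
    def test_flat_priors_reduce_to_loglik(self, design_500):
        beta = np.array([0.3])
        lp = log_posterior(beta, design_500, [FLAT_PRIOR])
        ll = conditional_loglik(beta, design_500, order=0)
        assert lp == pytest.approx(ll)

    def test_no_data_equals_log_prior(self):
        prior = PriorSpec("normal", mu=0.17, sigma=0.13)
        lp = log_posterior(np.array([0.17]), None, [prior])
        assert lp == pytest.approx(-math.log(0.13 * math.sqrt(2 * math.pi)))

    def test_hand_sum_single_pair_stratum(self, toy_pairs):
        d = build_design(toy_pairs.iloc[:2])
        beta = np.array([0.3])
        prior = PriorSpec("normal", mu=0.0, sigma=1.0)
        expected = (0.3 - math.log(math.exp(0.3) + 1.0)) + (
            -0.5 * 0.09 - math.log(math.sqrt(2 * math.pi))
        )
        assert log_posterior(beta, d, [prior]) == pytest.approx(expected, abs=1e-10)

    def test_prior_count_mismatch_rejected(self, design_500):
        with pytest.raises(ValueError, match="one prior per coefficient"):
            log_posterior(np.array([0.1]), design_500, [FLAT_PRIOR, FLAT_PRIOR])


class TestSampler:
    def test_prior_only_recovers_analytic_normal(self):
        draws = sample_posterior(
            None, [MHT_ORIGINAL_PRIOR], seed=11, n_iter=3000, warmup=1000
        )
        flat = draws.exposure.ravel()
        p_gt = (flat > 0).mean()
        assert p_gt == pytest.approx(stats.norm.cdf(0.17 / 0.13), abs=0.02)
        _, ks_p = stats.kstest(flat[::5], stats.norm(0.17, 0.13).cdf)
        assert ks_p > 0.01

    def test_flat_prior_median_matches_mle(self, design_500):
        mle = fit_clogit(design_500).beta[0]
        draws = sample_posterior(design_500, [FLAT_PRIOR], seed=3)
        assert np.median(draws.exposure) == pytest.approx(mle, abs=0.05)
        assert draws.rhat < 1.01
        assert draws.ess > 400

    def test_fixed_seed_reproducible(self, design_500):
        d1 = sample_posterior(design_500, [FLAT_PRIOR], seed=5, n_iter=600, warmup=300)
        d2 = sample_posterior(design_500, [FLAT_PRIOR], seed=5, n_iter=600, warmup=300)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_flat_prior_without_data_rejected(self):
        with pytest.raises(ValueError, match="improper"):
            sample_posterior(None, [FLAT_PRIOR], seed=0)

    def test_doubling_data_shrinks_interval(self):
        widths = []
        for n in (200, 400):
            ds = simulate_matched_design(n, 0.4, seed=21)
            d = build_design(ds)
            draws = sample_posterior(d, [FLAT_PRIOR], seed=4)
            lo, hi = np.percentile(draws.exposure, [2.5, 97.5])
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestMixing:
    def test_identical_datasets_match_single(self, design_500):
        priors = [FLAT_PRIOR]
        per = [
            sample_posterior(design_500, priors, seed=6, n_iter=800, warmup=400)
            for _ in range(3)
        ]
        mixed = mix_over_imputations(per)
        single = per[0].exposure.ravel()
        assert mixed.median_or == pytest.approx(float(np.exp(np.median(single))), rel=0.02)
        assert mixed.p_or_gt_1 + (1 - mixed.p_or_gt_1) == 1.0

    def test_between_imputation_spread_widens_mixture(self, design_500):
        d1 = sample_posterior(design_500, [FLAT_PRIOR], seed=7, n_iter=800, warmup=400)
        d2 = sample_posterior(design_500, [FLAT_PRIOR], seed=8, n_iter=800, warmup=400)
        # shift the second posterior to mimic between-imputation variability
        d2.draws = d2.draws + 0.5
        mixed = mix_over_imputations([d1, d2])
        within = np.mean([d1.exposure.var(), d2.exposure.var()])
        assert mixed.exposure_draws.var() >= within

    def test_unequal_counts_resampled_with_warning(self, design_500):
        d1 = sample_posterior(design_500, [FLAT_PRIOR], seed=7, n_iter=800, warmup=400)
        d2 = sample_posterior(design_500, [FLAT_PRIOR], seed=8, n_iter=600, warmup=300)
        with pytest.warns(RuntimeWarning, match="unequal"):
            mixed = mix_over_imputations([d1, d2])
        assert mixed.n_draws == 2 * d2.exposure.size


class TestPriorSensitivity:
    @pytest.fixture(scope="class")
    def small_design(self):
        return build_design(simulate_matched_design(150, 0.5, n_controls=3, seed=13))

    def test_wider_sigma_does_not_narrow_interval(self, small_design):
        grid = [
            PriorSpec("normal", 0.17, 0.13, "original"),
            PriorSpec("normal", 0.17, 0.26, "alt"),
            PriorSpec("normal", 0.17, 0.52, "alt2"),
        ]
        table = prior_sensitivity(small_design, grid, seed=9, n_iter=1200, warmup=600)
        widths = table["pi_high"] - table["pi_low"]
        assert widths.is_monotonic_increasing

    def test_mean_shift_moves_median_monotonically(self, small_design):
        grid = [
            PriorSpec("normal", -0.26, 0.2, "original"),
            PriorSpec("normal", -0.13, 0.2, "alt1"),
            PriorSpec("normal", 0.0, 0.2, "alt2"),
        ]
        table = prior_sensitivity(small_design, grid, seed=10, n_iter=1200, warmup=600)
        assert table["median_or"].is_monotonic_increasing
        assert table.attrs["median_monotone"]

    def test_single_prior_rejected(self, small_design):
        with pytest.raises(ValueError, match="at least two"):
            prior_sensitivity(small_design, [FLAT_PRIOR], seed=0)


def test_default_priors_layout():
    priors = default_priors(MHT_ORIGINAL_PRIOR, 4)
    assert priors[0] is MHT_ORIGINAL_PRIOR
    assert all(p.sigma == 2.5 for p in priors[1:])
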