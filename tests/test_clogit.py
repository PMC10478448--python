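"""Conditional logistic regression: likelihood oracles, fitting, pooling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from matchedcc import (
    build_design,
    complete_case_fit,
    conditional_loglik,
    fit_clogit,
    pool_rubin,
    simulate_matched_design,
)
from matchedcc.clogit import NoInformationError


def _design_from_rows(rows):
    df = pd.DataFrame(rows, columns=["stratum_id", "is_case", "x1"])
    return build_design(df)


class TestLoglik:
    def test_null_beta_gives_minus_log_stratum_sizes(self, design_500):
        ll = conditional_loglik(np.zeros(1), design_500, order=0)
        assert ll == pytest.approx(-500 * math.log(2))

    def test_hand_computed_two_pair_strata(self):
        # strata {case x=1, control x=0} and {case x=0.2, control x=0.7}, beta=0.5
        d = _design_from_rows(
            [(0, 1, 1.0), (0, 0, 0.0), (1, 1, 0.2), (1, 0, 0.7)]
        )
        beta = np.array([0.5])
        expected = (0.5 - math.log(math.exp(0.5) + 1.0)) + (
            0.1 - math.log(math.exp(0.1) + math.exp(0.35))
        )
        assert conditional_loglik(beta, d, order=0) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_constant_shift_within_stratum(self, design_500):
        beta = np.array([0.37])
        base = conditional_loglik(beta, design_500, order=0)
        shifted = design_500
        X2 = shifted.X.copy()
        X2[shifted.starts[0]: shifted.starts[1] if len(shifted.starts) > 1 else None] += 5.0
        from matchedcc.clogit import CLogitDesign

        d2 = CLogitDesign(X2, shifted.y, shifted.starts, shifted.stratum_ids, shifted.names)
        assert conditional_loglik(beta, d2, order=0) == pytest.approx(base, abs=1e-8)

    def test_gradient_at_zero_is_case_minus_stratum_mean(self, design_500):
        _, grad = conditional_loglik(np.zeros(1), design_500, order=1)
        X, y, starts, sizes = (
            design_500.X, design_500.y, design_500.starts, design_500.sizes,
        )
        means = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
        expected = X[y == 1].sum(axis=0) - means.sum(axis=0)
        np.testing.assert_allclose(grad, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_gradient_matches_finite_differences(self, seed):
        ds = simulate_matched_design(
            40, 0.3, n_controls=3, covariate_sd=1.0, covariate_logor=-0.5, seed=seed
        )
        d = build_design(ds)
        rng = np.random.default_rng(seed)
        beta = rng.normal(0, 0.5, 2)
        _, grad, H = conditional_loglik(beta, d)
        eps = 1e-6
        for j in range(2):
            e = np.zeros(2)
            e[j] = eps
            fd = (
                conditional_loglik(beta + e, d, order=0)
                - conditional_loglik(beta - e, d, order=0)
            ) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-5)

    def test_nonfinite_covariates_rejected(self):
        from matchedcc.clogit import CLogitDesign

        with pytest.raises(ValueError, match="non-finite"):
            CLogitDesign(
                np.array([[1.0], [np.inf]]), np.array([1.0, 0.0]),
                np.array([0]), np.array([0]), ["x"],
            )


class TestFit:
    def test_discordant_pair_ratio_oracle(self, toy_pairs):
        # 1:1 binary exposure: MLE odds ratio equals n10 / n01 = 10 / 5
        fit = fit_clogit(build_design(toy_pairs))
        assert fit.or_ == pytest.approx(2.0, abs=1e-4)
        assert fit.converged

    def test_balanced_discordance_gives_null(self):
        rows, sid = [], 0
        for _ in range(8):
            rows += [(sid, 1, 1.0), (sid, 0, 0.0)]
            sid += 1
        for _ in range(8):
            rows += [(sid, 1, 0.0), (sid, 0, 1.0)]
            sid += 1
        fit = fit_clogit(_design_from_rows(rows))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_grid_polish_equivalence_on_small_strata(self):
        # exhaustive-search oracle on strata of size <= 4, two binary covariates
        ds = simulate_matched_design(
            60, 0.4, n_controls=2, covariate_sd=1.0, covariate_logor=0.6, seed=5
        )
        ds["covariate"] = (ds["covariate"] > 0).astype(float)
        d = build_design(ds)
        fit = fit_clogit(d)
        grid = np.linspace(-2, 2, 81)
        best, best_ll = None, -np.inf
        for b1, b2 in itertools.product(grid, grid):
            ll = conditional_loglik(np.array([b1, b2]), d, order=0)
            if ll > best_ll:
                best, best_ll = (b1, b2), ll
        # polish the winning grid point with a local fine grid
        fine = np.linspace(-0.06, 0.06, 25)
        for d1, d2 in itertools.product(fine, fine):
            ll = conditional_loglik(np.array([best[0] + d1, best[1] + d2]), d, order=0)
            if ll > best_ll:
                best_ll = ll
                polished = (best[0] + d1, best[1] + d2)
        polished = locals().get("polished", best)
        np.testing.assert_allclose(fit.beta, polished, atol=1e-2)
        assert fit.loglik >= best_ll - 1e-6

    @pytest.mark.parametrize("n_controls", [1, 3])
    def test_parameter_recovery_over_seeds(self, n_controls):
        truth = math.log(1.5)
        ests = []
        for seed in range(20):
            ds = simulate_matched_design(500, truth, n_controls=n_controls, seed=seed)
            ests.append(fit_clogit(build_design(ds)).beta[0])
        assert np.mean(ests) == pytest.approx(truth, abs=0.1)

    def test_matching_variable_reported_non_identified(self, matched_500):
        df = matched_500.copy()
        df["matched_age"] = df["stratum_id"] % 40 + 20  # constant within stratum
        fit = fit_clogit(build_design(df, covariates=["exposure", "matched_age"]))
        assert "matched_age" in fit.dropped
        assert np.isnan(fit.beta[1]) and np.isfinite(fit.beta[0])

    def test_no_information_raises(self):
        d = _design_from_rows([(0, 1, 1.0), (0, 0, 1.0), (1, 1, 0.0), (1, 0, 0.0)])
        with pytest.raises(NoInformationError):
            fit_clogit(d)

    def test_separation_flagged_not_silent(self):
        rows, sid = [], 0
        for _ in range(12):
            rows += [(sid, 1, 1.0), (sid, 0, 0.0)]
            sid += 1
        with pytest.warns(RuntimeWarning, match="separation|monotone"):
            fit = fit_clogit(_design_from_rows(rows))
        assert fit.separation and not fit.converged

    def test_statsmodels_cross_check(self, matched_500):
        statsmodels = pytest.importorskip("statsmodels.api")
        fit = fit_clogit(build_design(matched_500))
        ref = statsmodels.ConditionalLogit(
            matched_500["is_case"],
            matched_500[["exposure"]],
            groups=matched_500["stratum_id"],
        ).fit(disp=0)
        assert fit.beta[0] == pytest.approx(ref.params.iloc[0], abs=1e-5)
        assert fit.se[0] == pytest.approx(ref.bse.iloc[0], abs=1e-5)


class TestPooling:
    def test_single_fit_passthrough(self, design_500):
        fit = fit_clogit(design_500)
        pooled = pool_rubin([fit])
        assert pooled.beta[0] == pytest.approx(fit.beta[0])
        np.testing.assert_allclose(pooled.T, fit.se**2)

    def test_hand_computed_two_imputation_pool(self, design_500):
        fit = fit_clogit(design_500)
        a, b = fit, fit
        import copy

        a = copy.deepcopy(fit)
        b = copy.deepcopy(fit)
        a.beta = np.array([0.5]); a.se = np.array([0.2])
        b.beta = np.array([0.7]); b.se = np.array([0.2])
        pooled = pool_rubin([a, b])
        assert pooled.beta[0] == pytest.approx(0.6)
        assert pooled.W[0] == pytest.approx(0.04)
        assert pooled.B[0] == pytest.approx(0.02)
        assert pooled.T[0] == pytest.approx(0.07)
        assert pooled.se[0] == pytest.approx(math.sqrt(0.07), abs=1e-4)

    def test_total_variance_at_least_within(self, matched_500):
        fits = []
        for seed in range(5):
            ds = simulate_matched_design(200, 0.4, seed=seed)
            fits.append(fit_clogit(build_design(ds)))
        pooled = pool_rubin(fits)
        assert np.all(pooled.T >= pooled.W)

    def test_mixed_parameterizations_rejected(self, matched_500):
        f1 = fit_clogit(build_design(matched_500))
        ds = simulate_matched_design(50, 0.2, covariate_sd=1.0, seed=0)
        f2 = fit_clogit(build_design(ds))
        with pytest.raises(ValueError, match="parameteriz"):
            pool_rubin([f1, f2])


class TestCompleteCase:
    def test_no_missing_identical_to_full_fit(self, matched_500):
        fit_full = fit_clogit(build_design(matched_500))
        fit_cc, log = complete_case_fit(matched_500)
        assert fit_cc.beta[0] == pytest.approx(fit_full.beta[0])
        assert log["n_rows_dropped"] == 0

    def test_stratum_dropped_when_case_missing(self, matched_500):
        df = matched_500.copy()
        victim = df.index[(df["stratum_id"] == 0) & (df["is_case"] == 1)][0]
        df.loc[victim, "exposure"] = np.nan
        _, log = complete_case_fit(df)
        assert 0 in log["strata_dropped"]
        assert log["n_strata_used"] == 499

    def test_mcar_deletion_consistent_with_full(self):
        ds = simulate_matched_design(800, math.log(1.5), seed=9)
        full = fit_clogit(build_design(ds))
        rng = np.random.default_rng(1)
        df = ds.copy()
        df.loc[rng.uniform(size=len(df)) < 0.1, "exposure"] = np.nan
        cc, _ = complete_case_fit(df)
        assert abs(cc.beta[0] - full.beta[0]) < 1.96 * math.hypot(cc.se[0], full.se[0])
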