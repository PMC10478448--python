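"""Cohort generator: validation, determinism, marginals, exclusion, missingness."""

import numpy as np
import pandas as pd
import pytest

from matchedcc import (
    SimConfig,
    apply_baseline_exclusion,
    crude_logor,
    impose_missingness,
    simulate_cohort,
    simulate_matched_design,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_women=0), "n_women"),
            (dict(age_range=(50, 40)), "age_range"),
            (dict(frailty_sd=-1.0), "frailty_sd"),
            (dict(exposure="xyz"), "exposure"),
            (dict(nonresponse_rates={"wave1": 1.4}), "nonresponse_rates"),
            (dict(exposure_prevalence_by_age=((16, 1.5),)), "exposure_prevalence_by_age"),
        ],
    )
    def test_invalid_fields_rejected_by_name(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SimConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(n_women=123, seed=9, true_logOR_exposure=0.3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg


class TestSimulation:
    def test_seed_reproducibility_byte_identical(self):
        cfg = SimConfig(n_women=2000, seed=11)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_cohort(SimConfig(n_women=2000, seed=1))
        b = simulate_cohort(SimConfig(n_women=2000, seed=2))
        assert not a.equals(b)

    def test_invariants_hold(self, small_cohort):
        df = small_cohort
        hc = df[df["ever_hc"] == 1]
        assert (hc["hc_start_age"] <= hc["age_2008"] + 10).all()
        assert (df.loc[df["asthma_onset_age"].notna(), "asthma_2016"] == 1).all()
        new_onset = (df["asthma_ever_2008"] == 0) & (df["asthma_2016"] == 1)
        assert (df.loc[df["asthma_ever_2008"] == 1, "asthma_2016"] == 1).all()
        assert new_onset.sum() > 0
        lo, hi = 16, 75
        assert df["age_2008"].between(lo, hi).all()

    def test_null_effect_crude_or_near_one(self):
        # null exposure effect, no frailty, flat exposure profile: crude OR ~ 1
        zs = []
        for seed in range(20):
            cfg = SimConfig(
                n_women=8000, true_logOR_exposure=0.0, frailty_sd=0.0,
                exposure_prevalence_by_age=((16, 0.6), (75, 0.6)),
                confounder_effects={}, baseline_asthma_model=None,
                followup_asthma_model={"intercept": -3.2, "age": 0.0},
                seed=seed,
            )
            coh = simulate_cohort(cfg)
            logor, se = crude_logor(coh, "ever_hc", "asthma_2016")
            zs.append(logor / se)
        assert abs(np.mean(zs)) < 3 / np.sqrt(20)

    def test_parameter_recovery_no_selection_no_confounding(self):
        # true OR 1.5, crude logistic estimate recovers log(1.5) within 0.1
        ests = []
        for seed in range(5):
            cfg = SimConfig(
                n_women=50_000, true_logOR_exposure=np.log(1.5), frailty_sd=0.0,
                exposure_prevalence_by_age=((16, 0.5), (75, 0.5)),
                confounder_effects={}, baseline_asthma_model=None,
                followup_asthma_model={"intercept": -3.5, "age": 0.0},
                seed=seed,
            )
            coh = simulate_cohort(cfg)
            logor, _ = crude_logor(coh, "ever_hc", "asthma_2016")
            ests.append(logor)
        assert np.mean(ests) == pytest.approx(np.log(1.5), abs=0.1)

    def test_wave_structure_responder_counts(self):
        # 15,003 women, 66% wave-1 response -> ~9,897 responders; wave 2 ~72%
        cfg = SimConfig(n_women=15_003, seed=3)
        coh = simulate_cohort(cfg)
        n1 = int(coh["responded_wave1"].sum())
        assert n1 == pytest.approx(9897, rel=0.02)
        assert coh["responded_wave2"].mean() == pytest.approx(0.72, abs=0.02)


class TestExclusion:
    def test_no_prevalent_asthma_identity(self):
        cfg = SimConfig(n_women=500, baseline_asthma_model=None, seed=0)
        coh = simulate_cohort(cfg)
        out, n = apply_baseline_exclusion(coh)
        assert n == 0
        pd.testing.assert_frame_equal(out, coh)

    def test_exclusion_count_matches_binomial_expectation(self, small_cohort):
        out, n = apply_baseline_exclusion(small_cohort)
        assert n == int(small_cohort["asthma_ever_2008"].sum())
        assert len(out) + n == len(small_cohort)
        assert (out["asthma_ever_2008"] == 0).all()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="asthma_ever_2008"):
            apply_baseline_exclusion(pd.DataFrame({"id": [1]}))


class TestMissingness:
    def test_zero_rates_identity(self, small_cohort):
        out = impose_missingness(small_cohort, {"bmi": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_mcar_rate_realized(self):
        df = pd.DataFrame({"x": np.arange(5000, dtype=float), "z": 1.0})
        out = impose_missingness(df, {"x": 0.30}, seed=2)
        assert out["x"].isna().mean() == pytest.approx(0.30, abs=0.02)

    def test_group_differential_missingness(self):
        # exposure item non-response ~36.8% among cases, ~62.5% among controls
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"is_case": rng.binomial(1, 0.2, 20_000), "exp": 1.0})
        out = impose_missingness(
            df, {"exp": {"group_rates": {"is_case": {1: 0.368, 0: 0.625}}}}, seed=3
        )
        assert out.loc[df.is_case == 1, "exp"].isna().mean() == pytest.approx(0.368, abs=0.02)
        assert out.loc[df.is_case == 0, "exp"].isna().mean() == pytest.approx(0.625, abs=0.02)

    def test_mar_depends_only_on_observed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"age": rng.uniform(20, 70, 8000), "y": 1.0})
        out = impose_missingness(
            df, {"y": {"rate": 0.3, "predictors": {"age": 1.0}}}, seed=4
        )
        assert out["y"].isna().mean() == pytest.approx(0.3, abs=0.02)
        old = out.loc[df["age"] > 55, "y"].isna().mean()
        young = out.loc[df["age"] < 35, "y"].isna().mean()
        assert old > young  # positive coefficient raises missingness with age

    def test_spec_referencing_missing_target_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        spec = {"a": 0.5, "b": {"rate": 0.3, "predictors": {"a": 1.0}}}
        with pytest.raises(ValueError, match="itself"):
            impose_missingness(df, spec, seed=0)

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError, match="unknown column"):
            impose_missingness(pd.DataFrame({"a": [1.0]}), {"zz": 0.5})


class TestMatchedDesignGenerator:
    def test_one_case_per_stratum(self):
        ds = simulate_matched_design(100, 0.5, n_controls=4, seed=0)
        counts = ds.groupby("stratum_id")["is_case"].sum()
        assert (counts == 1).all()
        assert (ds.groupby("stratum_id").size() == 5).all()

    def test_null_effect_symmetric_case_assignment(self):
        ds = simulate_matched_design(4000, 0.0, seed=1)
        # under the null the case is uniform within stratum: exposure balanced
        p_case = ds.loc[ds.is_case == 1, "exposure"].mean()
        p_ctrl = ds.loc[ds.is_case == 0, "exposure"].mean()
        assert p_case == pytest.approx(p_ctrl, abs=0.03)
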