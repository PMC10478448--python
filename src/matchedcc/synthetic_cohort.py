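"""Synthetic nested-cohort generator with a depletion-of-susceptibles mechanism.

The generator emulates a population-based female cohort: a baseline
questionnaire wave (ages 16-75), an 8-year follow-up wave defining new-onset
asthma, and a later women's-health questionnaire measuring lifetime hormonal
exposures (hormonal contraceptives, typically started in the late teens, and
menopausal hormone therapy, typically started in the early fifties).

Asthma is generated in two stages sharing a per-woman normal frailty (a
random intercept on the log-odds scale):

* a pre-baseline stage - cumulative asthma risk from early life to the
  baseline wave, increasing with attained age;
* a follow-up stage - 8-year incidence after baseline.

Because a lifetime exposure acts in both stages, excluding women with
prevalent asthma at baseline preferentially removes high-frailty women from
whichever exposure group has the higher pre-baseline risk. The imbalance in
retained susceptibility grows with baseline age (older women have had more
pre-baseline risk time), which is exactly the selection mechanism the
age-cutoff subgroup diagnostic is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "apply_baseline_exclusion",
    "impose_missingness",
    "simulate_matched_design",
    "new_onset_case_ids",
    "crude_logor",
]

# ever-use prevalence of hormonal contraceptives by baseline age (piecewise linear):
# younger birth cohorts used them more
DEFAULT_HC_PREVALENCE = ((16, 0.75), (30, 0.85), (45, 0.80), (60, 0.65), (75, 0.45))


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort.

    The two asthma models are logistic coefficient maps with keys
    ``intercept`` and ``age`` (per-year slope on age above the range minimum);
    exposure and confounder effects are added on top, and the shared frailty
    is a N(0, frailty_sd^2) random intercept common to both stages.
    """

    n_women: int = 15_003
    age_range: tuple[int, int] = (16, 75)
    exposure: str = "hc"  # "hc" | "mht": which exposure carries the causal effect
    true_logOR_exposure: float = 0.0
    exposure_prevalence_by_age: tuple[tuple[float, float], ...] = DEFAULT_HC_PREVALENCE
    confounder_effects: dict[str, float] = field(
        default_factory=lambda: {"smoking_current": 0.4, "bmi_obese": 0.5, "gyn_condition": 0.3}
    )
    confounder_exposure_effects: dict[str, float] = field(default_factory=dict)
    frailty_sd: float = 2.0
    baseline_asthma_model: dict[str, float] | None = field(
        default_factory=lambda: {"intercept": -4.6, "age": 0.045}
    )
    followup_asthma_model: dict[str, float] = field(
        default_factory=lambda: {"intercept": -6.2, "age": 0.015}
    )
    mht_prevalence: float = 0.17
    hc_start_window: tuple[int, int] = (14, 22)
    mht_start_window: tuple[int, int] = (48, 56)
    nonresponse_rates: dict[str, float] = field(
        default_factory=lambda: {
            "wave1": 0.34, "wave2": 0.28, "wave3_case": 0.37, "wave3_control": 0.53,
        }
    )
    missingness: dict | None = None  # MAR spec applied by impose_missingness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError(f"n_women must be positive, got {self.n_women}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must have min < max, got {self.age_range}")
        if self.frailty_sd < 0:
            raise ValueError(f"frailty_sd must be >= 0, got {self.frailty_sd}")
        if self.exposure not in ("hc", "mht"):
            raise ValueError(f"exposure must be 'hc' or 'mht', got {self.exposure!r}")
        for wave, rate in self.nonresponse_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"nonresponse_rates[{wave!r}] must be in [0,1], got {rate}")
        for age, prev in self.exposure_prevalence_by_age:
            if not 0 <= prev <= 1:
                raise ValueError(
                    f"exposure_prevalence_by_age at age {age} must be in [0,1], got {prev}"
                )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        d["exposure_prevalence_by_age"] = [list(t) for t in d["exposure_prevalence_by_age"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["age_range"] = tuple(d["age_range"])
        d["exposure_prevalence_by_age"] = tuple(tuple(t) for t in d["exposure_prevalence_by_age"])
        for key in ("hc_start_window", "mht_start_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _prevalence_at(age: np.ndarray, table) -> np.ndarray:
    pts = np.asarray(table, dtype=float)
    return np.interp(age, pts[:, 0], pts[:, 1])


def _confounder_lp(df: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    """Linear predictor contribution of configured covariate effects."""
    lp = np.zeros(len(df))
    derived = {
        "smoking_current": (df["smoking"] == "current").to_numpy(float),
        "smoking_former": (df["smoking"] == "former").to_numpy(float),
        "bmi_obese": (df["bmi"] >= 30).to_numpy(float),
        "bmi_overweight": ((df["bmi"] >= 25) & (df["bmi"] < 30)).to_numpy(float),
        "education_tertiary": (df["education"] == "tertiary").to_numpy(float),
    }
    for name, beta in effects.items():
        if name in derived:
            lp += beta * derived[name]
        elif name in df.columns:
            lp += beta * df[name].to_numpy(float)
        else:
            raise ValueError(f"confounder_effects references unknown covariate {name!r}")
    return lp


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw one cohort table; byte-identical for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_women
    lo, hi = config.age_range

    age = rng.integers(lo, hi + 1, size=n)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age_2008": age,
            "residence": rng.binomial(1, 0.57, n),  # 1 = in city
            "smoking": rng.choice(["never", "former", "current"], n, p=[0.56, 0.37, 0.07]),
            "education": rng.choice(
                ["less_than_high_school", "high_school", "tertiary"], n, p=[0.15, 0.28, 0.57]
            ),
            "bmi": np.clip(rng.normal(25.5, 4.2, n), 16, 50),
            "age_menarche": np.clip(np.round(rng.normal(13.0, 1.4, n)), 9, 18),
            "gyn_condition": rng.binomial(1, 0.15, n),
            "env_tobacco": rng.binomial(1, 0.25, n),
            "phys_exercise": rng.choice([0, 1, 2, 3], n, p=[0.15, 0.35, 0.35, 0.15]),
        }
    )
    df["bmi_band"] = pd.cut(
        df["bmi"], [0, 25, 30, np.inf], right=False, labels=["<25", "25-29.9", ">=30"]
    )
    menop = age >= 45
    df["age_menopause"] = np.where(
        menop, np.clip(np.round(rng.normal(51, 3.5, n)), 40, 60), np.nan
    )

    # hormonal contraceptives: age-profile prevalence, start age in the teen window
    p_hc = _prevalence_at(age, config.exposure_prevalence_by_age)
    if config.confounder_exposure_effects:
        logit = np.log(p_hc / (1 - p_hc)) + _confounder_lp(df, config.confounder_exposure_effects)
        p_hc = expit(logit)
    df["ever_hc"] = rng.binomial(1, p_hc, n)
    s_lo, s_hi = config.hc_start_window
    df["hc_start_age"] = np.where(
        df["ever_hc"] == 1, rng.integers(s_lo, s_hi + 1, n), np.nan
    )
    # mht: menopausal women only, constant prevalence, start around menopause
    m_lo, m_hi = config.mht_start_window
    df["ever_mht"] = np.where(menop, rng.binomial(1, config.mht_prevalence, n), 0)
    df["mht_start_age"] = np.where(
        df["ever_mht"] == 1,
        np.minimum(rng.integers(m_lo, m_hi + 1, n), age + 10),
        np.nan,
    )

    frailty = rng.normal(0.0, config.frailty_sd, n) if config.frailty_sd > 0 else np.zeros(n)
    df["frailty"] = frailty

    exp_col, start_col = (
        ("ever_hc", "hc_start_age") if config.exposure == "hc" else ("ever_mht", "mht_start_age")
    )
    start = df[start_col].fillna(np.inf).to_numpy()
    exposed = df[exp_col].to_numpy(bool)
    exposed_pre_baseline = exposed & (start <= age)
    exposed_by_2016 = exposed & (start <= age + 8)
    conf_lp = _confounder_lp(df, config.confounder_effects)

    # stage 1: cumulative pre-baseline asthma
    if config.baseline_asthma_model is not None:
        bm = config.baseline_asthma_model
        lp0 = (
            bm.get("intercept", -4.6)
            + bm.get("age", 0.045) * (age - lo)
            + config.true_logOR_exposure * exposed_pre_baseline
            + conf_lp
            + frailty
        )
        df["asthma_ever_2008"] = rng.binomial(1, expit(lp0), n)
    else:
        df["asthma_ever_2008"] = 0

    # stage 2: 8-year follow-up incidence, same frailty
    fm = config.followup_asthma_model
    lp1 = (
        fm.get("intercept", -6.2)
        + fm.get("age", 0.015) * (age - lo)
        + config.true_logOR_exposure * exposed_by_2016
        + conf_lp
        + frailty
    )
    onset = rng.binomial(1, expit(lp1), n).astype(bool) & (df["asthma_ever_2008"] == 0)
    df["asthma_2016"] = ((df["asthma_ever_2008"] == 1) | onset).astype(int)
    df["asthma_onset_age"] = np.where(onset, age + rng.integers(1, 9, n), np.nan)

    nr = config.nonresponse_rates
    df["responded_wave1"] = rng.binomial(1, 1 - nr.get("wave1", 0.34), n)
    df["responded_wave2"] = rng.binomial(1, 1 - nr.get("wave2", 0.28), n)
    p3 = np.where(onset, 1 - nr.get("wave3_case", 0.37), 1 - nr.get("wave3_control", 0.53))
    df["responded_wave3"] = rng.binomial(1, p3, n)
    return df


def apply_baseline_exclusion(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop women with prevalent asthma at baseline; report the exclusion count."""
    if "asthma_ever_2008" not in cohort.columns:
        raise ValueError("cohort lacks asthma_ever_2008; cannot apply baseline exclusion")
    keep = cohort["asthma_ever_2008"] == 0
    n_excluded = int((~keep).sum())
    return cohort.loc[keep].reset_index(drop=True), n_excluded


def new_onset_case_ids(cohort: pd.DataFrame, require_response: bool = True) -> np.ndarray:
    """Women asthma-free at baseline who report asthma at follow-up."""
    mask = (cohort["asthma_ever_2008"] == 0) & (cohort["asthma_2016"] == 1)
    if require_response:
        mask &= (cohort["responded_wave1"] == 1) & (cohort["responded_wave2"] == 1)
    return cohort.loc[mask, "id"].to_numpy()


def crude_logor(
    cohort: pd.DataFrame, exposure_col: str, outcome_col: str
) -> tuple[float, float]:
    """Unadjusted 2x2 log odds ratio and its standard error."""
    x = cohort[exposure_col].to_numpy(float)
    y = cohort[outcome_col].to_numpy(float)
    a = np.sum((x == 1) & (y == 1))
    b = np.sum((x == 1) & (y == 0))
    c = np.sum((x == 0) & (y == 1))
    d = np.sum((x == 0) & (y == 0))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log(a * d / (b * c))), float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))


# ---------------------------------------------------------------------------
# missingness


def _is_number(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def impose_missingness(cohort: pd.DataFrame, spec: dict, seed: int = 0) -> pd.DataFrame:
    """Blank cells according to a missing-at-random specification.

    ``spec`` maps a column name to one of

    * a float: MCAR at that rate;
    * ``{"rate": r, "predictors": {col: coef}}``: logistic MAR whose
      intercept is calibrated so the realized marginal rate is ~r, with
      log-odds depending on standardized observed predictors;
    * ``{"group_rates": {col: {value: rate}}}``: per-group MCAR, e.g.
      differential item non-response by case status.

    Predictors must be fully observed columns that are not themselves
    scheduled for blanking (the mechanism must depend on observed data only).
    """
    targets = set(spec)
    for col, rule in spec.items():
        if col not in cohort.columns:
            raise ValueError(f"missingness spec references unknown column {col!r}")
        preds = []
        if isinstance(rule, dict) and "predictors" in rule:
            preds = list(rule["predictors"])
        if isinstance(rule, dict) and "group_rates" in rule:
            preds = list(rule["group_rates"])
        for p in preds:
            if p not in cohort.columns:
                raise ValueError(f"missingness predictor {p!r} not in cohort")
            if p in targets:
                raise ValueError(
                    f"missingness for {col!r} depends on {p!r}, which is itself set "
                    "to be missing; the mechanism must condition on observed values"
                )

    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    for col, rule in spec.items():
        if _is_number(rule):
            if not 0 <= rule <= 1:
                raise ValueError(f"missingness rate for {col!r} must be in [0,1]")
            p = np.full(n, float(rule))
        elif isinstance(rule, dict) and "group_rates" in rule:
            (gcol, rates), = rule["group_rates"].items()
            p = np.zeros(n)
            for val, r in rates.items():
                p[cohort[gcol] == val] = r
        elif isinstance(rule, dict) and "rate" in rule:
            rate = rule["rate"]
            lp = np.zeros(n)
            for pcol, coef in rule.get("predictors", {}).items():
                z = pd.to_numeric(cohort[pcol], errors="coerce").to_numpy(float)
                sd = np.nanstd(z)
                z = (z - np.nanmean(z)) / (sd if sd > 0 else 1.0)
                lp += coef * np.nan_to_num(z)
            if rate <= 0:
                continue
            if rate >= 1:
                p = np.ones(n)
            else:
                c = brentq(lambda c_: expit(c_ + lp).mean() - rate, -30, 30)
                p = expit(c + lp)
        else:
            raise ValueError(f"unrecognized missingness rule for {col!r}: {rule!r}")
        mask = rng.uniform(size=n) < p
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# direct matched-design generator (conditional-model oracle)


def simulate_matched_design(
    n_strata: int,
    true_logor: float,
    *,
    n_controls: int = 1,
    p_exposure: float = 0.5,
    covariate_sd: float = 0.0,
    covariate_logor: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate matched strata directly under the conditional logistic model.

    Each stratum has 1 + n_controls members with independent Bernoulli
    exposures (and optionally a continuous covariate); the case is the member
    drawn with probability proportional to exp(x . beta). This is the exact
    model the conditional likelihood assumes, so it serves as a clean
    parameter-recovery oracle for the fitting code.
    """
    rng = np.random.default_rng(seed)
    k = 1 + n_controls
    x = rng.binomial(1, p_exposure, size=(n_strata, k)).astype(float)
    lp = true_logor * x
    cov = None
    if covariate_sd > 0:
        cov = rng.normal(0, covariate_sd, size=(n_strata, k))
        lp = lp + covariate_logor * cov
    w = np.exp(lp)
    probs = w / w.sum(axis=1, keepdims=True)
    case_pos = (probs.cumsum(axis=1) > rng.uniform(size=(n_strata, 1))).argmax(axis=1)
    rows = {
        "stratum_id": np.repeat(np.arange(n_strata), k),
        "is_case": (np.tile(np.arange(k), n_strata) == np.repeat(case_pos, k)).astype(int),
        "exposure": x.ravel(),
    }
    if cov is not None:
        rows["covariate"] = cov.ravel()
    return pd.DataFrame(rows)
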