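"""Descriptive tables and end-to-end pipeline orchestration.

``describe`` builds a background-characteristics table (counts and
percentages by case status, Student's t-test for continuous variables,
Fisher's exact test for categorical ones, missingness shown as its own
category). ``run_pipeline`` chains the whole analysis from one config:

    simulate -> baseline exclusion -> match -> impose missingness ->
    chained-equation imputation -> frequentist conditional logistic
    regression (Rubin-pooled, plus complete-case sensitivity) -> Bayesian
    fits across the prior grid -> E-values -> age-cutoff subgroup trend.

All randomness flows from one root seed expanded deterministically per
stage, and the report carries a provenance block (seed, config hash,
library versions) so a rerun is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .bayes import prior_sensitivity
from .clogit import build_design, complete_case_fit, fit_clogit, pool_rubin
from .evalue import evalue
from .matching import MatchSpec, analysis_table, match_controls
from .mi_fcs import ImputationModelSpec, impute
from .priors import PriorSpec, make_alternatives
from .selection import subgroup_trend
from .synthetic_cohort import (
    SimConfig,
    apply_baseline_exclusion,
    impose_missingness,
    new_onset_case_ids,
    simulate_cohort,
)

__all__ = ["pct", "describe", "PipelineConfig", "StudyReport", "run_pipeline"]


def pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, the way descriptive tables print it."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def describe(
    df: pd.DataFrame,
    group_col: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Background-characteristics table by group.

    Continuous variables are summarized as mean (SD) per group with a
    two-sample t-test; categorical variables as n (%) per level (including an
    explicit Missing row) with Fisher's exact test on the observed 2xk table.
    """
    if group_col not in df.columns:
        raise ValueError(f"grouping column {group_col!r} absent")
    groups = sorted(df[group_col].dropna().unique().tolist())
    if len(groups) < 2 or any((df[group_col] == g).sum() == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    continuous = continuous or []
    categorical = categorical or []
    rows = []
    for var in continuous:
        samples = [df.loc[df[group_col] == g, var].dropna() for g in groups]
        _, p = stats.ttest_ind(*samples[:2], equal_var=True)
        row = {"variable": var, "level": "mean (SD)", "p_value": round(float(p), 3)}
        for g, s in zip(groups, samples):
            row[f"{g}"] = f"{s.mean():.1f} ({s.std():.1f})"
        rows.append(row)
    for var in categorical:
        levels = list(pd.unique(df[var].dropna()))
        counts = {g: df.loc[df[group_col] == g, var] for g in groups}
        table = np.array(
            [[(counts[g] == lv).sum() for lv in levels] for g in groups]
        )
        if table.sum() and table.shape[1] >= 2 and all(table.sum(axis=1) > 0):
            _, p = stats.fisher_exact(table)
        else:
            p = np.nan
        denom = {g: int((df[group_col] == g).sum()) for g in groups}
        for i, lv in enumerate(levels + ["Missing"]):
            row = {"variable": var, "level": str(lv),
                   "p_value": round(float(p), 3) if i == 0 and np.isfinite(p) else np.nan}
            for g in groups:
                n = (
                    int(counts[g].isna().sum())
                    if isinstance(lv, str) and lv == "Missing"
                    else int((counts[g] == lv).sum())
                )
                row[f"{g}"] = f"{n} ({pct(n, denom[g])})"
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Single configuration for the full study pipeline."""

    sim: SimConfig = field(default_factory=SimConfig)
    match: MatchSpec = field(default_factory=MatchSpec)
    exposure_col: str = "ever_hc"
    adjustment: tuple[str, ...] = (
        "age_2008", "residence", "education", "age_menarche", "gyn_condition", "smoking",
    )
    missingness: dict = field(
        default_factory=lambda: {
            "ever_hc": {"group_rates": {"is_case": {1: 0.368, 0: 0.625}}},
            "education": 0.01,
            "age_menarche": 0.05,
        }
    )
    m: int = 10
    n_iterations: int = 10
    prior: PriorSpec = field(default_factory=lambda: PriorSpec("normal", -0.26, 0.20))
    n_chains: int = 4
    n_iter: int = 1500
    warmup: int = 750
    cutoffs: tuple[int, ...] = (25, 35, 45, 55, 65)
    complete_case: bool = True
    run_bayes: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "sim" in kw:
            sim = dict(kw["sim"])
            if "age_range" in sim:
                sim["age_range"] = tuple(sim["age_range"])
            if "exposure_prevalence_by_age" in sim:
                sim["exposure_prevalence_by_age"] = tuple(
                    tuple(t) for t in sim["exposure_prevalence_by_age"]
                )
            kw["sim"] = SimConfig(**sim)
        if "match" in kw:
            mt = dict(kw["match"])
            if "exact_vars" in mt:
                mt["exact_vars"] = tuple(mt["exact_vars"])
            kw["match"] = MatchSpec(**mt)
        if "prior" in kw:
            kw["prior"] = PriorSpec(**kw["prior"])
        for key in ("adjustment", "cutoffs"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(json.loads(json.dumps(asdict(self), default=str)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    descriptive: pd.DataFrame
    forest: pd.DataFrame          # overall + subgroup frequentist rows
    bayes_table: pd.DataFrame | None
    evalues: dict
    counts: dict
    provenance: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "tables").mkdir(parents=True, exist_ok=True)
        self.descriptive.to_csv(outdir / "tables" / "descriptive.csv", index=False)
        self.forest.to_csv(outdir / "tables" / "forest.csv", index=False)
        if self.bayes_table is not None:
            self.bayes_table.to_csv(outdir / "tables" / "bayes.csv", index=False)
        payload = {
            "evalues": self.evalues,
            "counts": self.counts,
            "provenance": self.provenance,
        }
        (outdir / "results.json").write_text(json.dumps(payload, indent=1, default=str))
        lines = ["# Study report", "", "## Frequentist forest table", ""]
        lines.append(self.forest.to_string(index=False))
        if self.bayes_table is not None:
            lines += ["", "## Bayesian summaries", "", self.bayes_table.to_string(index=False)]
        lines += ["", "## E-values", "", json.dumps(self.evalues, indent=1)]
        (outdir / "report.md").write_text("\n".join(lines))


def _encode(table: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code categorical covariates; exposure column stays first.

    Reference levels: never smoker, less-than-high-school (the natural
    ordering of the descriptive table).
    """
    ordered_levels = {
        "smoking": ["never", "former", "current"],
        "education": ["less_than_high_school", "high_school", "tertiary"],
    }
    out = table[["stratum_id", "is_case"]].copy()
    names: list[str] = []
    for cov in covariates:
        col = table[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = ordered_levels.get(cov) or sorted(col.dropna().unique().tolist())
            for lv in levels[1:]:
                name = f"{cov}_{lv}"
                out[name] = np.where(col.isna(), np.nan, (col == lv).astype(float))
                names.append(name)
        else:
            out[cov] = col.astype(float)
            names.append(cov)
    return out, names


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> StudyReport:
    """Run every stage from one config; deterministic given ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["sim", "missing", "impute", "bayes"], ss.spawn(4)
        )
    }

    sim_cfg = config.sim
    sim_cfg = SimConfig(**{**asdict(sim_cfg), "seed": stage_seed["sim"]}) if sim_cfg.seed == 0 else sim_cfg
    cohort = simulate_cohort(sim_cfg)
    cohort, n_excluded = apply_baseline_exclusion(cohort)
    cases = new_onset_case_ids(cohort)
    matched = match_controls(cohort, cases, config.match)

    covs = [config.exposure_col] + [c for c in config.adjustment if c != config.exposure_col]
    tab = analysis_table(cohort, matched, covs)
    tab = impose_missingness(tab, config.missingness, seed=stage_seed["missing"])

    stack = impute(
        tab.drop(columns=["woman_id"]),
        ImputationModelSpec(
            m=config.m, n_iterations=config.n_iterations,
            exclude=("stratum_id",), seed=stage_seed["impute"],
        ),
    )
    encoded = [_encode(ds, covs) for ds in stack.datasets]
    designs = [build_design(e, covariates=names) for e, names in encoded]
    fits = [fit_clogit(d) for d in designs]
    pooled = pool_rubin(fits)
    ci = pooled.conf_int()[0]

    forest_rows = [
        dict(subset="all", cutoff=np.nan, n_strata=len(matched.strata),
             or_=pooled.or_, ci_low=float(ci[0]), ci_high=float(ci[1]))
    ]
    trend = subgroup_trend(
        [e for e, _ in encoded],
        covariates=encoded[0][1],
        cutoffs=config.cutoffs,
    )
    for _, row in trend.above().iterrows():
        forest_rows.append(
            dict(subset=f">={int(row['cutoff'])}", cutoff=int(row["cutoff"]),
                 n_strata=int(row["n_strata"]), or_=row["or_"],
                 ci_low=row["ci_low"], ci_high=row["ci_high"])
        )
    forest = pd.DataFrame(forest_rows)

    if config.complete_case:
        try:
            cc_table, _cc_names = _encode(tab.drop(columns=["woman_id"]), covs)
            cc_fit, cc_log = complete_case_fit(cc_table)
            cci = cc_fit.conf_int()[0]
            forest = pd.concat(
                [forest, pd.DataFrame([
                    dict(subset="complete_case", cutoff=np.nan,
                         n_strata=cc_log["n_strata_used"], or_=cc_fit.or_,
                         ci_low=float(cci[0]), ci_high=float(cci[1]))
                ])],
                ignore_index=True,
            )
        except ValueError:
            pass

    ev = evalue(pooled.or_, float(ci[0]), float(ci[1]))
    evalues = {"overall": ev.as_dict()}

    bayes_table = None
    if config.run_bayes:
        grid = (
            make_alternatives(config.prior)
            if config.prior.kind == "normal"
            else [config.prior]
        )
        if len(grid) < 2:
            from .priors import FLAT_PRIOR

            grid = grid + [FLAT_PRIOR]
        bayes_table = prior_sensitivity(
            designs, grid,
            n_chains=config.n_chains, n_iter=config.n_iter,
            warmup=config.warmup, seed=stage_seed["bayes"],
        )

    case_mask = tab["is_case"] == 1
    descriptive = describe(
        tab.assign(group=np.where(case_mask, "case", "control")),
        "group",
        continuous=[c for c in covs if tab[c].dtype != object and tab[c].nunique() > 4],
        categorical=[c for c in covs if tab[c].dtype == object or tab[c].nunique() <= 4],
    )

    counts = {
        "n_cohort": int(sim_cfg.n_women),
        "n_excluded_baseline": n_excluded,
        "n_cases": int(len(cases)),
        "n_cases_matched": len(matched.strata),
        "n_controls": matched.n_controls,
        "n_unmatched_cases": len(matched.unmatched_case_ids),
    }
    provenance = {
        "seed": config.seed,
        "stage_seeds": stage_seed,
        "config_hash": config.config_hash(),
        "matchedcc_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "m": config.m,
    }
    report = StudyReport(
        descriptive=descriptive,
        forest=forest,
        bayes_table=bayes_table,
        evalues=evalues,
        counts=counts,
        provenance=provenance,
    )
    if outdir is not None:
        report.save(outdir)
    return report
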