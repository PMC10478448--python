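"""Exact individual matching of controls to cases.

Each new-onset case is matched to at most ``max_controls`` controls sharing
identical values on the matching variables (default: exact age in years at
baseline, place of residence, smoking status). Controls are used without
replacement: once matched they are unavailable to later cases. Cases are
processed in ascending age with a seeded shuffle breaking ties, and when a
case has more eligible candidates than the ratio allows, a seeded uniform
subset is drawn. Cases with no eligible candidate are returned separately
rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MatchSpec", "MatchedStratum", "MatchResult", "match_controls", "analysis_table"]


@dataclass(frozen=True)
class MatchSpec:
    exact_vars: tuple[str, ...] = ("age_2008", "residence", "smoking")
    max_controls: int = 10
    age_caliper: int = 0  # optional +/- years widening on age_2008 when exact pool is empty
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_controls < 1:
            raise ValueError(f"max_controls must be >= 1, got {self.max_controls}")
        if not self.exact_vars:
            raise ValueError("exact_vars must be non-empty")
        if self.age_caliper < 0:
            raise ValueError("age_caliper must be >= 0")


@dataclass
class MatchedStratum:
    stratum_id: int
    case_id: int
    control_ids: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return 1 + len(self.control_ids)


@dataclass
class MatchResult:
    strata: list[MatchedStratum]
    unmatched_case_ids: list[int]
    spec: MatchSpec

    @property
    def n_controls(self) -> int:
        return sum(len(s.control_ids) for s in self.strata)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per woman with stratum id and role."""
        rows = []
        for s in self.strata:
            rows.append((s.stratum_id, "case", s.case_id))
            rows.extend((s.stratum_id, "control", cid) for cid in s.control_ids)
        return pd.DataFrame(rows, columns=["stratum_id", "role", "woman_id"])


def match_controls(
    cohort: pd.DataFrame, cases: np.ndarray | list[int], spec: MatchSpec | None = None
) -> MatchResult:
    """Build matched strata by exact matching without replacement.

    Eligible controls are cohort members who are not cases and never had
    asthma through follow-up (``asthma_ever_2008`` and ``asthma_2016`` both
    zero). The output is invariant to the row order of the cohort up to the
    seeded subsampling draws: candidates are keyed and sorted by woman id
    before any random subset is taken.
    """
    spec = spec or MatchSpec()
    missing_vars = [v for v in spec.exact_vars if v not in cohort.columns]
    if missing_vars:
        raise ValueError(f"matching variables absent from cohort: {missing_vars}")
    case_ids = list(dict.fromkeys(int(c) for c in np.asarray(cases).ravel()))
    known = set(cohort["id"].tolist())
    for cid in case_ids:
        if cid not in known:
            raise ValueError(f"case id {cid} not present in cohort")

    is_control = (
        (~cohort["id"].isin(case_ids))
        & (cohort.get("asthma_ever_2008", 0) == 0)
        & (cohort.get("asthma_2016", 0) == 0)
    )
    controls = cohort.loc[is_control]

    rng = np.random.default_rng(spec.seed)

    # key -> seeded random permutation of available control ids; sequential
    # without-replacement draws are realized by slicing disjoint chunks of the
    # permutation, which has the same joint law and is fast at cohort scale
    ctrl_keys = list(map(tuple, controls[list(spec.exact_vars)].itertuples(index=False, name=None)))
    pool: dict[tuple, list[int]] = {}
    for k, cid in zip(ctrl_keys, controls["id"].astype(int)):
        pool.setdefault(k, []).append(int(cid))
    cursor: dict[tuple, int] = {}
    for k in sorted(pool, key=repr):
        ids = sorted(pool[k])
        pool[k] = [ids[j] for j in rng.permutation(len(ids))]
        cursor[k] = 0

    case_rows = cohort.set_index("id").loc[case_ids]
    case_keys = list(
        map(tuple, case_rows[list(spec.exact_vars)].itertuples(index=False, name=None))
    )
    ages = (
        case_rows["age_2008"].to_numpy()
        if "age_2008" in case_rows.columns
        else np.zeros(len(case_ids))
    )
    # ascending case age, seeded tie-break within equal ages
    tie = rng.permutation(len(case_ids))
    order = np.lexsort((tie, ages))

    age_pos = spec.exact_vars.index("age_2008") if "age_2008" in spec.exact_vars else None

    def draw(key: tuple, want: int) -> list[int]:
        lst = pool.get(key)
        if lst is None:
            return []
        pos = cursor[key]
        chunk = lst[pos: pos + want]
        cursor[key] = pos + len(chunk)
        return chunk

    strata: list[MatchedStratum] = []
    unmatched: list[int] = []
    sid = 0
    for i in order:
        cid = case_ids[i]
        key = case_keys[i]
        chosen = draw(key, spec.max_controls)
        if not chosen and spec.age_caliper and age_pos is not None:
            for delta in range(1, spec.age_caliper + 1):
                for sign in (-1, 1):
                    alt = list(key)
                    alt[age_pos] = key[age_pos] + sign * delta
                    chosen.extend(draw(tuple(alt), spec.max_controls - len(chosen)))
                if chosen:
                    break
        if not chosen:
            unmatched.append(cid)
            continue
        strata.append(MatchedStratum(stratum_id=sid, case_id=cid, control_ids=sorted(chosen)))
        sid += 1
    return MatchResult(strata=strata, unmatched_case_ids=unmatched, spec=spec)


def analysis_table(
    cohort: pd.DataFrame, result: MatchResult, columns: list[str]
) -> pd.DataFrame:
    """Long-format analysis table: stratum id, case indicator, covariates.

    One row per matched woman, joining the requested cohort columns onto the
    stratum roster produced by :func:`match_controls`.
    """
    roster = result.to_frame()
    merged = roster.merge(
        cohort[["id"] + columns], left_on="woman_id", right_on="id", how="left"
    )
    merged["is_case"] = (merged["role"] == "case").astype(int)
    return merged[["stratum_id", "is_case", "woman_id"] + columns]
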