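"""E-values: minimum confounder strength needed to explain away an association.

For a risk ratio RR >= 1 the E-value is RR + sqrt(RR (RR - 1)); a protective
RR < 1 is inverted first, so the measure is symmetric in RR <-> 1/RR. For the
confidence interval the bound closer to the null is used, and an interval
covering 1 yields an E-value of 1 (no unmeasured confounding needed).

Odds ratios can stand in for risk ratios when the outcome is rare; a warning
is issued when the supplied cumulative incidence exceeds 15%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["EValueResult", "evalue_point", "evalue_ci", "evalue"]

RARE_OUTCOME_THRESHOLD = 0.15


def evalue_point(rr: float) -> float:
    """E-value for a point estimate on the risk-ratio scale.

    E = RR* + sqrt(RR* (RR* - 1)) with RR* = max(RR, 1/RR).
    """
    if not rr > 0:
        raise ValueError(f"risk ratio must be positive, got {rr}")
    r = 1.0 / rr if rr < 1.0 else float(rr)
    return r + math.sqrt(r * (r - 1.0))


def evalue_ci(rr: float, ci_low: float, ci_high: float) -> float:
    """E-value for the confidence-interval bound closer to the null.

    Returns 1 when the interval includes the null (nothing to explain away).
    """
    if ci_low > ci_high:
        raise ValueError(f"inverted confidence interval ({ci_low}, {ci_high})")
    if not (ci_low <= rr <= ci_high):
        raise ValueError("point estimate must lie inside the confidence interval")
    if ci_low <= 1.0 <= ci_high:
        return 1.0
    bound = ci_low if rr > 1.0 else ci_high
    return evalue_point(bound)


@dataclass
class EValueResult:
    rr: float
    ci_low: float | None
    ci_high: float | None
    e_point: float
    e_ci: float | None
    rare_outcome: bool

    def as_dict(self) -> dict:
        return {
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "e_point": round(self.e_point, 2),
            "e_ci": None if self.e_ci is None else round(self.e_ci, 2),
            "rare_outcome": self.rare_outcome,
        }


def evalue(
    rr: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
    outcome_incidence: float | None = None,
) -> EValueResult:
    """Point and (optional) CI E-value with the rare-outcome bookkeeping.

    ``outcome_incidence`` is the cumulative outcome incidence used to judge
    whether an odds ratio approximates a risk ratio.
    """
    rare = True
    if outcome_incidence is not None and outcome_incidence > RARE_OUTCOME_THRESHOLD:
        rare = False
        warnings.warn(
            f"outcome incidence {outcome_incidence:.1%} exceeds "
            f"{RARE_OUTCOME_THRESHOLD:.0%}; the OR may overstate the RR and the "
            "E-value inherits that approximation",
            UserWarning,
            stacklevel=2,
        )
    e_ci = None
    if ci_low is not None and ci_high is not None:
        e_ci = evalue_ci(rr, ci_low, ci_high)
    return EValueResult(rr, ci_low, ci_high, evalue_point(rr), e_ci, rare)
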