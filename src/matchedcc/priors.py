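"""Elicitation of normal priors on the exposure log odds ratio.

Prior evidence is a set of published ORs with 95% CIs; each is converted to a
log-OR and standard error (SE = (log hi - log lo) / 3.92) and pooled by
inverse-variance (fixed-effect) weighting into a single normal prior.
Alternative priors express elicitation uncertainty by widening the standard
deviation and drifting the mean toward the null; a flat (improper uniform)
prior is always available to let the data speak alone.

The elicited priors shipped as defaults are N(-0.26, 0.20^2) for ever use
of hormonal contraceptives and N(0.17, 0.13^2) for ever use of menopausal
hormone therapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorSpec",
    "PriorEvidence",
    "pool_evidence",
    "make_alternatives",
    "HC_ORIGINAL_PRIOR",
    "MHT_ORIGINAL_PRIOR",
    "FLAT_PRIOR",
]


@dataclass(frozen=True)
class PriorSpec:
    """Normal or flat prior on a log odds ratio."""

    kind: str  # "normal" | "flat"
    mu: float = 0.0
    sigma: float = 1.0
    label: str = "original"

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "flat"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "normal" and not self.sigma > 0:
            raise ValueError("normal prior requires sigma > 0")

    def logpdf(self, beta: float) -> float:
        if self.kind == "flat":
            return 0.0
        z = (beta - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma * math.sqrt(2 * math.pi))

    def dlogpdf(self, beta: float) -> float:
        if self.kind == "flat":
            return 0.0
        return -(beta - self.mu) / self.sigma**2

    def d2logpdf(self) -> float:
        if self.kind == "flat":
            return 0.0
        return -1.0 / self.sigma**2


# priors shipped as configuration for the two hormonal exposures
HC_ORIGINAL_PRIOR = PriorSpec("normal", mu=-0.26, sigma=0.20, label="original")
MHT_ORIGINAL_PRIOR = PriorSpec("normal", mu=0.17, sigma=0.13, label="original")
FLAT_PRIOR = PriorSpec("flat", label="flat")


@dataclass(frozen=True)
class PriorEvidence:
    """One prior study: OR with 95% CI, optionally an explicit weight."""

    label: str
    or_: float
    ci_low: float
    ci_high: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low > 0 and self.ci_high > 0):
            raise ValueError(f"{self.label}: CI bounds must be positive")
        if not self.ci_low < self.ci_high:
            raise ValueError(f"{self.label}: CI bounds must be ordered and non-degenerate")
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError(f"{self.label}: OR outside its CI")

    @property
    def log_or(self) -> float:
        return math.log(self.or_)

    @property
    def se(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / 3.92


def pool_evidence(evidence: list[PriorEvidence], label: str = "original") -> PriorSpec:
    """Inverse-variance weighted pooling of study log-ORs into a normal prior.

    With a single study the prior is that study's logOR and SE; with k studies
    of equal SE s the pooled mean is the simple average and the pooled sigma
    is s / sqrt(k). Explicit weights override the 1/SE^2 default.
    """
    if not evidence:
        raise ValueError("need at least one study to pool")
    logs = np.array([e.log_or for e in evidence])
    ses = np.array([e.se for e in evidence])
    w = np.array([e.weight if e.weight is not None else 1.0 / s**2 for e, s in zip(evidence, ses)])
    mu = float(np.sum(w * logs) / np.sum(w))
    sigma = float(math.sqrt(1.0 / np.sum(1.0 / ses**2)))
    return PriorSpec("normal", mu=mu, sigma=sigma, label=label)


def make_alternatives(
    original: PriorSpec,
    sigma_factors: tuple[float, ...] = (1.5, 2.0, 3.0),
    drift_to_null: bool = True,
    include_flat: bool = True,
) -> list[PriorSpec]:
    """Deterministic grid of alternative priors around an elicited original.

    Each alternative widens sigma by a factor f and (by default) shrinks the
    mean toward 0 by the same factor, expressing progressively weaker
    commitment to the elicited direction; a flat prior is appended so the
    grid brackets the data-only analysis. The original is returned first.
    """
    if original.kind != "normal":
        raise ValueError("alternatives are derived from a normal original prior")
    out = [original]
    for i, f in enumerate(sigma_factors, start=1):
        mu = original.mu / f if drift_to_null else original.mu
        out.append(PriorSpec("normal", mu=mu, sigma=original.sigma * f, label=f"alt{i}"))
    if include_flat:
        out.append(FLAT_PRIOR)
    return out
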