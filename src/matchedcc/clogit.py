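"""Conditional logistic regression for individually matched case-control strata.

Each stratum holds exactly one case and one or more matched controls. The
conditional likelihood eliminates the stratum-specific intercepts: a stratum
with covariate rows x_1..x_k and case row x_c contributes

    exp(x_c . beta) / sum_i exp(x_i . beta),

so covariates constant within every stratum (the matching variables) carry no
information and are reported as non-identified rather than estimated.

Estimation is Newton-Raphson with step-halving from beta = 0; inference is
Wald on the log-odds-ratio scale. Rubin's rules combine fits across multiply
imputed datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLogitDesign",
    "FitResult",
    "PooledFit",
    "build_design",
    "conditional_loglik",
    "fit_clogit",
    "complete_case_fit",
    "pool_rubin",
]


class NoInformationError(ValueError):
    """Raised when no stratum carries within-stratum covariate variation."""


@dataclass
class CLogitDesign:
    """Grouped design matrix for one-case-per-stratum conditional logistic models.

    Rows are sorted by stratum; ``starts`` indexes the first row of each
    stratum. ``y`` marks the single case row per stratum.
    """

    X: np.ndarray            # (n, p) float
    y: np.ndarray            # (n,) 0/1, exactly one 1 per stratum
    starts: np.ndarray       # (S,) first-row index of each stratum
    stratum_ids: np.ndarray  # (S,) original stratum labels
    names: list[str]         # column names, exposure first by convention

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains non-finite covariate values")
        counts = np.add.reduceat(self.y, self.starts)
        if not np.allclose(counts, 1.0):
            bad = self.stratum_ids[np.where(~np.isclose(counts, 1.0))[0]]
            raise ValueError(
                f"each stratum must contain exactly one case; offending strata: {bad[:5].tolist()}"
            )

    @property
    def n_strata(self) -> int:
        return len(self.starts)

    @property
    def sizes(self) -> np.ndarray:
        n = self.X.shape[0]
        return np.diff(np.append(self.starts, n))

    def informative_columns(self, tol: float = 1e-12) -> np.ndarray:
        """Boolean mask of columns that vary within at least one stratum."""
        Xc = _center_within(self.X, self.starts, self.sizes)
        return np.abs(Xc).max(axis=0) > tol

    def subset_strata(self, keep: np.ndarray) -> "CLogitDesign":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.where(keep)[0]
        sizes = self.sizes
        row_blocks = [np.arange(self.starts[s], self.starts[s] + sizes[s]) for s in keep]
        if row_blocks:
            rows = np.concatenate(row_blocks)
        else:
            rows = np.array([], dtype=int)
        new_sizes = sizes[keep]
        starts = np.concatenate([[0], np.cumsum(new_sizes)[:-1]]).astype(int) if len(keep) else np.array([], dtype=int)
        return CLogitDesign(self.X[rows], self.y[rows], starts, self.stratum_ids[keep], list(self.names))


def _center_within(X: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    means = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
    return X - np.repeat(means, sizes, axis=0)


def build_design(
    data: pd.DataFrame,
    stratum_col: str = "stratum_id",
    case_col: str = "is_case",
    covariates: list[str] | None = None,
) -> CLogitDesign:
    """Build a :class:`CLogitDesign` from a long-format analysis table.

    ``covariates`` defaults to every column other than the stratum and case
    indicator; the first listed covariate is treated as the exposure of
    interest by downstream summaries.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (stratum_col, case_col)]
    df = data.sort_values(stratum_col, kind="stable").reset_index(drop=True)
    codes, uniques = pd.factorize(df[stratum_col], sort=True)
    starts = np.searchsorted(codes, np.arange(len(uniques)))
    X = df[covariates].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; impute or drop first")
    y = df[case_col].to_numpy(dtype=float)
    return CLogitDesign(X, y, starts.astype(int), np.asarray(uniques), list(covariates))


def conditional_loglik(
    beta: np.ndarray, design: CLogitDesign, *, order: int = 2
) -> tuple[float, np.ndarray, np.ndarray] | tuple[float, np.ndarray] | float:
    """Conditional log-likelihood, optionally with gradient and Hessian.

    loglik = sum_strata [ x_case . beta - log sum_i exp(x_i . beta) ].
    At beta = 0 each stratum of size k contributes -log k and the gradient is
    the sum of (x_case - stratum mean).
    """
    beta = np.asarray(beta, dtype=float)
    X, y, starts = design.X, design.y, design.starts
    sizes = design.sizes
    eta = X @ beta
    # per-stratum log-sum-exp, numerically shifted
    m = np.maximum.reduceat(eta, starts)
    expe = np.exp(eta - np.repeat(m, sizes))
    denom = np.add.reduceat(expe, starts)
    lse = m + np.log(denom)
    ll = float(np.sum(eta[y == 1.0]) - np.sum(lse))
    if order == 0:
        return ll
    w = expe / np.repeat(denom, sizes)            # within-stratum softmax weights
    xbar = np.add.reduceat(w[:, None] * X, starts, axis=0)   # (S, p)
    grad = X[y == 1.0].sum(axis=0) - xbar.sum(axis=0)
    if order == 1:
        return ll, grad
    H = -((X * w[:, None]).T @ X - xbar.T @ xbar)
    return ll, grad, H


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit for a matched design."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    names: list[str]
    loglik: float
    converged: bool
    separation: bool
    n_strata: int
    n_strata_informative: int
    dropped: list[str] = field(default_factory=list)  # non-identified covariates

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta[0]))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.exp(np.column_stack([self.beta - z * self.se, self.beta + z * self.se]))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "logOR": self.beta,
                "se": self.se,
                "OR": np.exp(self.beta),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=self.names,
        )


def fit_clogit(
    design: CLogitDesign,
    *,
    max_iter: int = 50,
    tol: float = 1e-8,
    beta_bound: float = 15.0,
) -> FitResult:
    """Newton-Raphson fit with step-halving.

    Covariates with no within-stratum variation (e.g. the exact-matched age)
    are dropped from estimation and reported in ``dropped``; strata with no
    covariate variation at all contribute nothing and are counted but kept.
    Monotone likelihood (separation) is flagged when coefficients run away.
    """
    info = design.informative_columns()
    dropped = [n for n, keep in zip(design.names, info) if not keep]
    if not info.any():
        raise NoInformationError(
            "no covariate varies within any stratum; conditional likelihood is flat"
        )
    sub = CLogitDesign(
        design.X[:, info], design.y, design.starts, design.stratum_ids,
        [n for n, k in zip(design.names, info) if k],
    )
    Xc = _center_within(sub.X, sub.starts, sub.sizes)
    per_stratum_var = np.add.reduceat(Xc**2, sub.starts, axis=0).sum(axis=1)
    n_informative = int((per_stratum_var > 1e-12).sum())

    p = sub.X.shape[1]
    beta = np.zeros(p)
    ll, grad, H = conditional_loglik(beta, sub)
    converged = False
    separation = False
    # score tolerance floored at the float64 accumulation noise of the row sums
    gtol = max(tol, 1e-11 * sub.X.shape[0])
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        # small ridge keeps the step defined when H is near-singular
        step = np.linalg.solve(H - 1e-10 * np.eye(p), -grad)
        scale = 1.0
        # acceptance is relative: near the optimum the true improvement can be
        # below the representable resolution of the log-likelihood
        ll_slack = 1e-10 * max(1.0, abs(ll))
        for _ in range(30):
            cand = beta + scale * step
            ll_new = conditional_loglik(cand, sub, order=0)
            if ll_new >= ll - ll_slack:
                break
            scale /= 2
        beta = beta + scale * step
        ll, grad, H = conditional_loglik(beta, sub)
        if np.max(np.abs(beta)) > beta_bound:
            separation = True
            warnings.warn(
                "monotone likelihood detected (separation); estimates unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
            break
    else:
        converged = np.max(np.abs(grad)) < gtol
    if np.max(np.abs(grad)) < gtol and not separation:
        converged = True
    cov = np.linalg.inv(-H + 1e-12 * np.eye(p))
    se = np.sqrt(np.diag(cov))

    # re-expand to the full covariate list with NaN for non-identified terms
    beta_full = np.full(len(design.names), np.nan)
    se_full = np.full(len(design.names), np.nan)
    cov_full = np.full((len(design.names), len(design.names)), np.nan)
    idx = np.where(info)[0]
    beta_full[idx] = beta
    se_full[idx] = se
    cov_full[np.ix_(idx, idx)] = cov
    return FitResult(
        beta=beta_full,
        se=se_full,
        cov=cov_full,
        names=list(design.names),
        loglik=ll,
        converged=converged and not separation,
        separation=separation,
        n_strata=design.n_strata,
        n_strata_informative=n_informative,
        dropped=dropped,
    )


def complete_case_fit(
    data: pd.DataFrame,
    stratum_col: str = "stratum_id",
    case_col: str = "is_case",
    covariates: list[str] | None = None,
) -> tuple[FitResult, dict]:
    """Listwise-deletion sensitivity fit.

    Rows with any missing covariate are removed; strata that lose their case,
    or all their controls, are dropped entirely and counted in the returned
    log dict.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (stratum_col, case_col)]
    complete = data.dropna(subset=covariates)
    keep_strata = []
    for sid, grp in complete.groupby(stratum_col):
        if grp[case_col].sum() == 1 and len(grp) >= 2:
            keep_strata.append(sid)
    kept = complete[complete[stratum_col].isin(keep_strata)]
    log = {
        "n_rows_dropped": int(len(data) - len(complete)),
        "n_strata_input": int(data[stratum_col].nunique()),
        "n_strata_used": len(keep_strata),
        "strata_dropped": sorted(set(data[stratum_col]) - set(keep_strata)),
    }
    design = build_design(kept, stratum_col, case_col, covariates)
    return fit_clogit(design), log


@dataclass
class PooledFit:
    """Rubin's-rules combination of per-imputation fits.

    total variance T = W + (1 + 1/m) B with W the mean within-imputation
    variance and B the between-imputation variance of the point estimates;
    degrees of freedom follow Barnard-Rubin.
    """

    beta: np.ndarray
    se: np.ndarray
    W: np.ndarray
    B: np.ndarray
    T: np.ndarray
    df: np.ndarray
    m: int
    names: list[str]

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta[0]))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = stats.t.ppf(0.5 + level / 2, np.maximum(self.df, 1.0))
        return np.exp(np.column_stack([self.beta - q * self.se, self.beta + q * self.se]))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "logOR": self.beta,
                "se": self.se,
                "OR": np.exp(self.beta),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "df": self.df,
            },
            index=self.names,
        )


def pool_rubin(fits: list[FitResult], df_com: float | None = None) -> PooledFit:
    """Combine m per-imputation fits by Rubin's rules.

    With m = 1 the pooled result equals the single fit (B = 0, T = W). The
    Barnard-Rubin small-sample degrees of freedom use ``df_com`` (complete
    data df; defaults to informative strata minus parameters of the first
    fit, or infinity if that is not positive).
    """
    if not fits:
        raise ValueError("need at least one fit to pool")
    names = fits[0].names
    for f in fits:
        if f.names != names:
            raise ValueError("fits have mixed parameterizations; cannot pool")
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to pool")
    m = len(usable)
    betas = np.array([f.beta for f in usable])
    var_w = np.array([f.se**2 for f in usable])
    qbar = betas.mean(axis=0)
    W = var_w.mean(axis=0)
    B = betas.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1 + 1 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * B / W
        lam = (1 + 1 / m) * B / T
        nu_old = np.where(B > 0, (m - 1) / np.maximum(lam, 1e-300) ** 2, np.inf)
    if df_com is None:
        df_com = usable[0].n_strata_informative - len(names)
        if df_com <= 0:
            df_com = np.inf
    if np.isfinite(df_com):
        nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
        df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    else:
        df = nu_old
    return PooledFit(
        beta=qbar, se=np.sqrt(T), W=W, B=B, T=T, df=df, m=m, names=list(names)
    )
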