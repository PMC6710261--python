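"""Clade-level statistics for PTS indices.

One-sample t-tests against an index of 1 (the null that the groove
landmark sits exactly on the base circle), one-way ANOVA with pairwise
group comparisons, ordinary least squares, and phylogenetic generalized
least squares for allometric regressions. All analyses operate on species
means, matching the original workflow.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from taluscam import trees as _trees

__all__ = [
    "one_sample_t",
    "anova_pairwise",
    "AnovaResult",
    "ols",
    "OLSResult",
    "pgls",
    "PGLSResult",
]


def one_sample_t(
    values: Sequence[float], mu: float = 1.0
) -> Tuple[float, int, float]:
    """One-sample two-sided t-test of the mean against ``mu`` (default 1,
    the no-cam null). Returns (t, df, p)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero sample variance: t undefined")
    res = sps.ttest_1samp(x, popmean=mu)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA over all groups plus pairwise comparisons.

    ``pairwise`` has one row per group pair with the two-group F, the raw
    p, and the multiplicity-adjusted p (Bonferroni by default)."""

    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: pd.DataFrame


def anova_pairwise(
    groups: Dict[str, Sequence[float]],
    adjustment: str = "bonferroni",
) -> AnovaResult:
    """One-way ANOVA F over all groups and pairwise two-group comparisons.

    Each pairwise comparison is itself a two-group one-way ANOVA
    (equivalent to a pooled-variance t-test squared); p-values are
    Bonferroni-adjusted across pairs unless ``adjustment="none"``.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment: {adjustment}")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    res = sps.f_oneway(*arrays.values())
    k = len(arrays)
    n_total = sum(len(v) for v in arrays.values())
    pairs = list(itertools.combinations(arrays, 2))
    rows = []
    for a, b in pairs:
        pr = sps.f_oneway(arrays[a], arrays[b])
        padj = min(float(pr.pvalue) * len(pairs), 1.0) \
            if adjustment == "bonferroni" else float(pr.pvalue)
        rows.append(
            {"group_a": a, "group_b": b, "F": float(pr.statistic),
             "p_raw": float(pr.pvalue), "p_adjusted": padj}
        )
    return AnovaResult(
        F=float(res.statistic),
        df_between=k - 1,
        df_within=n_total - k,
        p=float(res.pvalue),
        pairwise=pd.DataFrame(rows),
    )


@dataclasses.dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r2: float
    p: float
    slope_se: float


def ols(x: Sequence[float], y: Sequence[float]) -> OLSResult:
    """Ordinary least squares of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero x-variance")
    res = sps.linregress(x, y)
    return OLSResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        slope_se=float(res.stderr),
    )


@dataclasses.dataclass(frozen=True)
class PGLSResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_slope: float
    lambda_: Optional[float]
    log_likelihood: float


def _gls(
    X: np.ndarray, y: np.ndarray, C: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float, float]:
    n = len(y)
    chol = cho_factor(C + 1e-12 * np.eye(n), lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    CiX = cho_solve(chol, X)
    XtCiX = X.T @ CiX
    beta = np.linalg.solve(XtCiX, CiX.T @ y)
    r = y - X @ beta
    q = float(r @ cho_solve(chol, r))
    df = n - X.shape[1]
    s2 = q / df if df > 0 else float("nan")
    cov_beta = (s2 if df > 0 else 0.0) * np.linalg.inv(XtCiX)
    # ML loglik (sigma2 profiled with /n) for lambda comparison
    s2_ml = max(q / n, 1e-300)
    ll = -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
    return beta, cov_beta, s2, ll


def pgls(
    tree: dendropy.Tree,
    x: pd.Series,
    y: pd.Series,
    correlation: str = "bm",
) -> PGLSResult:
    """Phylogenetic GLS regression of y on x.

    ``x`` and ``y`` are Series indexed by taxon. correlation="bm" uses the
    Brownian shared-path-length covariance; "lambda_ml" scales its
    off-diagonals by an ML-estimated Pagel lambda. On a star tree the
    covariance is diagonal and the fit reduces to OLS.
    """
    if correlation not in ("bm", "lambda_ml"):
        raise ValueError(f"unknown correlation: {correlation}")
    taxa = sorted(set(x.index) & set(y.index))
    tree_tips = set(_trees.tip_labels(tree))
    if set(taxa) - tree_tips or not taxa:
        raise KeyError(
            f"taxa not in tree: {sorted(set(taxa) - tree_tips)}"
        )
    if len(taxa) < 2:
        raise ValueError("need >= 2 matched taxa")
    xv = x.loc[taxa].to_numpy(dtype=float)
    yv = y.loc[taxa].to_numpy(dtype=float)
    _, C = _trees.vcv_matrix(tree, taxa)
    X = np.column_stack([np.ones(len(taxa)), xv])

    def C_lambda(lam: float) -> np.ndarray:
        Cl = lam * C
        np.fill_diagonal(Cl, np.diag(C))
        return Cl

    lam: Optional[float] = None
    if correlation == "lambda_ml":
        def nll(lam_: float) -> float:
            return -_gls(X, yv, C_lambda(lam_))[3]

        res = minimize_scalar(
            nll, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(res.x)
        C = C_lambda(lam)
    beta, cov_beta, _, ll = _gls(X, yv, C)
    df = len(taxa) - 2
    se = np.sqrt(np.diag(cov_beta))
    tstat = beta[1] / se[1] if se[1] > 0 else np.inf
    p = 2.0 * sps.t.sf(abs(tstat), df) if df > 0 else float("nan")
    return PGLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=float(se[1]),
        intercept_se=float(se[0]),
        p_slope=float(p),
        lambda_=lam,
        log_likelihood=float(ll),
    )
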