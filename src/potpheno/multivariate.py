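"""Eigen-based genotype grouping: PCA with quadrant assignment, factor
analysis by principal-component extraction, and trait-physiology
correlation.

PCA operates on the correlation matrix of the (standardized) input, so
total variance equals the number of variables.  The sign of each
component is fixed deterministically — the largest-magnitude loading of
each column is made positive — so quadrant labels are reproducible
across platforms.  Quadrants follow the usual biplot reading of the
(PC1, PC2) score signs: (+,+) -> 1, (-,+) -> 2, (-,-) -> 3, (+,-) -> 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PcaResult", "FactorResult", "CorrelationResult",
           "pca", "factor_analysis", "varimax", "correlate", "plot_scores"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    scores: pd.DataFrame        # observations x components
    loadings: pd.DataFrame      # variables x components
    quadrant: pd.Series         # per observation, in {1, 2, 3, 4}


@dataclass
class FactorResult:
    loadings: pd.DataFrame      # variables x factors
    communality: pd.Series
    variance: pd.Series         # per-factor variance (sum of squared loadings)
    percent_variance: pd.Series
    total_percent: float
    rotation: str = "none"


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


def _as_matrix(matrix) -> pd.DataFrame:
    m = pd.DataFrame(matrix)
    if m.isna().any().any():
        raise ValueError("input matrix has missing cells")
    return m.astype(float)


def _quadrant(pc1: float, pc2: float) -> int:
    if pc1 >= 0 and pc2 >= 0:
        return 1
    if pc1 < 0 and pc2 >= 0:
        return 2
    if pc1 < 0 and pc2 < 0:
        return 3
    return 4


def pca(matrix, standardize: bool = True, n_components: int | None = None) -> PcaResult:
    """Correlation-matrix PCA of an observations x variables table.

    Scores are the projections of the standardized data on the
    eigenvectors; loadings are eigenvector * sqrt(eigenvalue).
    """
    m = _as_matrix(matrix)
    n_obs, n_var = m.shape
    if n_var < 2 or n_obs < 3:
        raise ValueError("PCA needs >= 2 variables and >= 3 observations")
    sd = m.std(axis=0, ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    if standardize:
        x = (m - m.mean(axis=0)) / sd
        cov = np.corrcoef(m.to_numpy(), rowvar=False)
    else:
        x = m - m.mean(axis=0)
        cov = np.cov(m.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    k = n_components or n_var
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(x.to_numpy() @ eigvec[:, :k], index=m.index, columns=comp_names)
    loadings = pd.DataFrame(eigvec[:, :k] * np.sqrt(eigval[:k]),
                            index=m.columns, columns=comp_names)
    total = eigval.sum()
    pct = 100.0 * eigval / total
    quad = scores.apply(lambda row: _quadrant(row.iloc[0], row.iloc[1]), axis=1)
    return PcaResult(
        eigenvalues=eigval,
        percent_variance=pct,
        cumulative_percent=np.cumsum(pct),
        scores=scores,
        loadings=loadings,
        quadrant=quad.astype(int),
    )


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Raw varimax rotation of a loading matrix (Kaiser, unnormalized)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return L @ R


def factor_analysis(matrix, n_factors: int = 3, rotation: str = "none") -> FactorResult:
    """Factor analysis by principal-component extraction.

    Loadings are the first ``n_factors`` eigenvectors of the
    correlation matrix scaled by sqrt(eigenvalue); communality is the
    row sum of squared loadings; percent variance is each factor's
    variance divided by the number of variables.  Varimax rotation is
    optional and preserves communalities.
    """
    if rotation not in ("none", "varimax"):
        raise ValueError("rotation must be 'none' or 'varimax'")
    m = _as_matrix(matrix)
    n_var = m.shape[1]
    if n_factors >= n_var:
        raise ValueError("n_factors must be smaller than the number of variables")
    res = pca(m, standardize=True)
    L = res.loadings.iloc[:, :n_factors].to_numpy()
    if rotation == "varimax":
        L = varimax(L)
        # deterministic sign after rotation too
        for j in range(L.shape[1]):
            k = np.argmax(np.abs(L[:, j]))
            if L[k, j] < 0:
                L[:, j] *= -1
    names = [f"Factor{i + 1}" for i in range(n_factors)]
    loadings = pd.DataFrame(L, index=m.columns, columns=names)
    communality = (loadings**2).sum(axis=1)
    variance = (loadings**2).sum(axis=0)
    pct = variance / n_var
    return FactorResult(
        loadings=loadings,
        communality=communality,
        variance=variance,
        percent_variance=pct,
        total_percent=float(pct.sum()),
        rotation=rotation,
    )


def correlate(table, min_n: int = 3) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    ``table`` is observations x variables (e.g. genotype-level BLUEs
    and physiology side by side).  No multiple-testing correction is
    applied; with the small genotype panels this serves, the r values
    themselves matter more than the stars.
    """
    m = _as_matrix(table)
    n = m.shape[0]
    if n < min_n:
        raise ValueError(f"need >= {min_n} paired observations, have {n}")
    sd = m.std(axis=0, ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"undefined correlation for zero-variance column(s): {zero}")
    cols = m.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            rv, pv = stats.pearsonr(m[a], m[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return CorrelationResult(r=r, p=p, n=n)


def plot_scores(result: PcaResult, ax=None):
    """Basic PC1 x PC2 score plot with quadrant axes and labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    s = result.scores
    ax.axhline(0, color="0.7", lw=0.8)
    ax.axvline(0, color="0.7", lw=0.8)
    ax.scatter(s.iloc[:, 0], s.iloc[:, 1], s=30)
    for name, row in s.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel(f"PC1 ({result.percent_variance[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.percent_variance[1]:.1f}%)")
    return ax
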