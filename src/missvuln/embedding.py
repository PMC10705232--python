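"""Spectral embedding of cell-type similarity graphs.

Cell types are compared either by their gene-expression profiles or by their
regional density maps.  From the Pearson cross-correlation matrix R the
correlation distance D = 1 − R is formed, converted to similarities
s_ij = 1/d_ij (s_ii = 0), min-max normalized over the off-diagonal entries,
and embedded through the eigenvectors of the unnormalized graph Laplacian
L = Δ − S.  The first eigenvector is trivial (eigenvalue 0 on a connected
graph); loadings on v2 and v3 locate each cell type in the low-dimensional
similarity space, and mean tau correlation is regressed on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EPS_DISTANCE = 1e-9  # floor applied before inverting distances


@dataclass
class SimilarityMatrix:
    S: pd.DataFrame
    mode: str  # "gene" | "spatial"
    epsilon_clipped: int = 0
    degenerate_range: bool = False


@dataclass
class Embedding:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: pd.DataFrame  # entities × eigenvector index (1-based columns)
    degenerate: bool = False

    @property
    def v2(self) -> pd.Series:
        return self.eigenvectors[2]

    @property
    def v3(self) -> pd.Series:
        return self.eigenvectors[3]


@dataclass
class LoadingRegression:
    slope: float
    intercept: float
    r2: float
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def correlation_distance(X: pd.DataFrame) -> pd.DataFrame:
    """D = 1 − R over entity rows; zero-variance entities are excluded."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables per entity")
    variances = np.asarray(X, dtype=float).var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = list(X.index[~keep])
        logger.warning("zero-variance entities excluded from the distance "
                       "matrix: %s", dropped)
        X = X.loc[keep]
    R = np.atleast_2d(np.corrcoef(np.asarray(X, dtype=float)))
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 2.0)
    return pd.DataFrame(D, index=X.index, columns=X.index)


def similarity_from_distance(Dm: pd.DataFrame) -> SimilarityMatrix:
    """Inverse-distance similarity, min-max normalized over off-diagonals.

    s_ij = 1/d_ij for i ≠ j with distances floored at 1e-9 (logged), s_ii = 0.
    The min-max normalization runs over the off-diagonal entries only — the
    zero diagonal is pinned, not rescaled.  If all off-diagonal similarities
    are equal (degenerate range) they are all set to 1, logged.
    """
    D = np.asarray(Dm, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    clipped = int((D[off] < EPS_DISTANCE).sum())
    if clipped:
        logger.info("%d near-zero distances floored at %g before inversion",
                    clipped, EPS_DISTANCE)
    Dc = np.maximum(D, EPS_DISTANCE)
    S = np.zeros_like(D)
    S[off] = 1.0 / Dc[off]
    lo, hi = S[off].min(), S[off].max()
    degenerate = hi == lo
    if degenerate:
        logger.warning("degenerate similarity range; all off-diagonals set to 1")
        S[off] = 1.0
    else:
        S[off] = (S[off] - lo) / (hi - lo)
    out = pd.DataFrame(S, index=Dm.index, columns=Dm.columns)
    return SimilarityMatrix(S=out, mode="", epsilon_clipped=clipped,
                            degenerate_range=degenerate)


def graph_laplacian(S: pd.DataFrame | SimilarityMatrix) -> pd.DataFrame:
    """Unnormalized Laplacian L = Δ − S with Δ the degree (row-sum) matrix."""
    Sm = S.S if isinstance(S, SimilarityMatrix) else S
    A = np.asarray(Sm, dtype=float)
    L = np.diag(A.sum(axis=1)) - A
    return pd.DataFrame(L, index=Sm.index, columns=Sm.columns)


def spectral_embed(L: pd.DataFrame) -> Embedding:
    """Eigendecomposition of the Laplacian with a fixed sign convention.

    Eigenpairs are sorted by ascending eigenvalue.  Each eigenvector's sign
    is fixed so that its largest-magnitude loading is positive.  A warning is
    issued when the smallest eigenvalue is not ≈ 0 (the connected-graph
    Laplacian assumption is then violated); repeated eigenvalues are flagged
    as degenerate.
    """
    A = np.asarray(L, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("Laplacian must be symmetric")
    w, V = np.linalg.eigh(A)
    if abs(w[0]) > 1e-6:
        logger.warning("smallest eigenvalue %.3g is not ~0; graph assumption "
                       "violated", w[0])
    for j in range(V.shape[1]):
        i_max = int(np.argmax(np.abs(V[:, j])))
        if V[i_max, j] < 0:
            V[:, j] = -V[:, j]
    degenerate = bool(np.any(np.diff(w) < 1e-10))
    if degenerate:
        logger.info("repeated Laplacian eigenvalues; embedding axes are not "
                    "uniquely defined")
    vecs = pd.DataFrame(V, index=L.index, columns=range(1, V.shape[1] + 1))
    return Embedding(eigenvalues=w, eigenvectors=vecs, degenerate=degenerate)


def embedding_tau_regression(
    loadings: pd.Series, mean_R: pd.Series
) -> LoadingRegression:
    """Simple OLS of mean tau correlation on one eigenvector's loadings.

    Returns slope, R², two-sided p and a 95% t-based confidence interval on
    the slope.  Constant loadings make the slope undefined (flagged).
    """
    common = [e for e in loadings.index if e in mean_R.index]
    if len(common) < 3:
        raise ValueError("need at least 3 cell types")
    x = loadings.loc[common].to_numpy(dtype=float)
    y = mean_R.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        logger.warning("constant loadings; regression slope undefined")
        return LoadingRegression(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, degenerate=True)
    res = sps.linregress(x, y)
    n = x.size
    tcrit = sps.t.ppf(0.975, n - 2)
    return LoadingRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
    )
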