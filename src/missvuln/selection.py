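"""MRx3 informative-gene selection.

Minimum-Redundancy-Maximum-Relevance-Minimum-Residual (MRx3) selects the gene
subset used for spatial deconvolution in three stages:

1. *Noise trimming*: estimate, per gene, the incremental reconstruction error
   that including the gene adds to the least-squares prediction of the spatial
   expression matrix, and drop the worst decile.  The scores admit an exact
   rank-one (leave-one-row-out) closed form; a from-scratch refit per gene is
   the defining oracle and must agree to 1e-8.
2. *Greedy mRMR*: starting from the empty set S, repeatedly add the candidate
   gene maximizing V_i = F_i / Redund(i|S), where F_i is the sample variance
   of the gene's (column-normalized) expression across cell types and
   Redund(i|S) is the mean absolute Pearson correlation between gene i and the
   genes already in S, across cell types.  The first pick maximizes F_i alone.
3. *Subset-size choice*: sweep candidate sizes, deconvolve on each size-prefix
   and pick the elbow (maximum discrete second difference) of the
   residual-vs-size curve.

All tie-breaks use stable gene-identifier order, so selection is deterministic
given the input ordering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ShapeError

logger = logging.getLogger(__name__)

#: Guard against division by zero in V_i = F_i / Redund(i|S).
EPS_REDUNDANCY = 1e-12

NORMALIZATION_SCHEMES = ("max", "sum", "l2")


@dataclass
class GeneSubset:
    """Ordered MRx3 selection with per-step criterion values."""

    genes: list[str]
    v_values: list[float]
    noise_scores: pd.Series | None = None
    trimmed_genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene subset contains duplicates")


@dataclass
class SubsetSizeSweep:
    """Residual-vs-size sweep with the chosen subset size."""

    sizes: list[int]
    residuals: list[float]
    chosen: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "residual": self.residuals,
                "chosen": [s == self.chosen for s in self.sizes],
            }
        )


def _scale_vectors(X: np.ndarray, scheme: str, axis: int, what: str) -> np.ndarray:
    if scheme == "max":
        denom = X.max(axis=axis, keepdims=True)
    elif scheme == "sum":
        denom = X.sum(axis=axis, keepdims=True)
    elif scheme == "l2":
        denom = np.sqrt((X**2).sum(axis=axis, keepdims=True))
    else:
        raise ConfigurationError(
            f"unknown normalization scheme {scheme!r}; choose from {NORMALIZATION_SCHEMES}"
        )
    zero = denom == 0
    if zero.any():
        logger.warning("%d all-zero %s passed through unscaled", int(zero.sum()), what)
        denom = np.where(zero, 1.0, denom)
    return X / denom


def normalize_inputs(
    E_raw: pd.DataFrame,
    C_raw: pd.DataFrame,
    e_scheme: str = "max",
    c_scheme: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Scale E per gene row and C per cell-type column.

    Defaults: per-gene max for the spatial matrix, per-type sum for the
    signature matrix.  All-zero rows/columns pass through as zeros with a
    logged warning.  The schemes used are returned as provenance metadata.
    """
    E = pd.DataFrame(
        _scale_vectors(np.asarray(E_raw, dtype=float), e_scheme, 1, "gene rows of E"),
        index=E_raw.index,
        columns=E_raw.columns,
    )
    C = pd.DataFrame(
        _scale_vectors(np.asarray(C_raw, dtype=float), c_scheme, 0, "cell-type columns of C"),
        index=C_raw.index,
        columns=C_raw.columns,
    )
    return E, C, {"e_scheme": e_scheme, "c_scheme": c_scheme}


def estimate_incremental_noise(E: pd.DataFrame, C: pd.DataFrame) -> pd.Series:
    """Per-gene incremental reconstruction error (rank-one leave-one-out).

    With the unconstrained least-squares density fit D̂(G) over all genes,
    the score of gene g is::

        score_g = ( ||E - C·D̂(G)||²  -  ||E₋g - C₋g·D̂(G \\ g)||² ) / N_v

    i.e. the growth in squared reconstruction error attributable to including
    gene g, normalized per voxel.  Because dropping a gene is a rank-one
    downdate of the normal equations, the score has the exact closed form
    ``||r_g||² / ((1 - h_g) · N_v)`` with residual row r_g and leverage
    h_g = c_gᵀ(CᵀC)⁻¹c_g; this must match a from-scratch refit to 1e-8.
    A perfectly explained gene (r_g = 0) scores exactly 0.
    """
    if E.shape[0] != C.shape[0]:
        raise ShapeError(f"E has {E.shape[0]} genes, C has {C.shape[0]}")
    Em = np.asarray(E, dtype=float)
    Cm = np.asarray(C, dtype=float)
    n_genes, n_vox = Em.shape
    A = Cm.T @ Cm
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[0]:
        logger.warning("normal equations rank-deficient (rank %d < %d); "
                       "using pseudo-inverse", rank, A.shape[0])
        Ainv = np.linalg.pinv(A)
    else:
        Ainv = np.linalg.inv(A)
    D_hat = Ainv @ (Cm.T @ Em)
    R = Em - Cm @ D_hat
    rss_rows = (R**2).sum(axis=1)
    leverage = np.einsum("ij,jk,ik->i", Cm, Ainv, Cm)
    scores = np.empty(n_genes)
    for g in range(n_genes):
        denom = 1.0 - leverage[g]
        if denom > 1e-10:
            scores[g] = rss_rows[g] / denom / n_vox
        else:
            # gene is pivotal for identifiability; refit without it directly
            logger.info("leverage ≈ 1 for gene %s; brute-force refit", E.index[g])
            keep = np.arange(n_genes) != g
            D_wo, *_ = np.linalg.lstsq(Cm[keep], Em[keep], rcond=None)
            rss_wo = ((Em[keep] - Cm[keep] @ D_wo) ** 2).sum()
            scores[g] = (rss_rows.sum() - rss_wo) / n_vox
    return pd.Series(scores, index=E.index, name="incremental_noise")


def trim_noisy_genes(
    scores: pd.Series,
    E: pd.DataFrame,
    C: pd.DataFrame,
    frac: float = 0.10,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Remove the ceil(frac·|G|) highest-scoring genes.

    Ties are broken by stable gene-identifier order: of equal scores, the
    gene appearing earlier in the index is removed first.  Returns the
    retained gene list and the reduced E*, C*.
    """
    if not (0 <= frac < 1):
        raise ConfigurationError(f"trim fraction must be in [0, 1), got {frac}")
    n_remove = math.ceil(frac * len(scores))
    if n_remove == 0:
        return list(scores.index), E, C
    order = np.lexsort((np.arange(len(scores)), -scores.to_numpy()))
    removed = set(scores.index[order[:n_remove]])
    kept = [g for g in scores.index if g not in removed]
    return kept, E.loc[kept], C.loc[kept]


def f_statistic(c_row: np.ndarray) -> float:
    """Across-cell-type variance criterion for a single gene.

    Σ_j (c(j) − mean(c))² / (N_t − 1): the sample variance of the gene's
    column-normalized expression across cell types.
    """
    c = np.asarray(c_row, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValueError("need a 1-D expression row over at least 2 cell types")
    return float(np.var(c, ddof=1))


def _centered_unit_rows(C: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit norm; zero-variance rows become zero
    (so they correlate 0 with everything, per the documented convention)."""
    X = C - C.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(norms > 0, X / np.where(norms == 0, 1.0, norms), 0.0)
    return X


def redundancy(i: str, S: list[str], C: pd.DataFrame) -> float:
    """Mean |Pearson R| between gene i and the members of S across cell types."""
    if i in S:
        raise ValueError(f"gene {i!r} is already in S")
    if not S:
        raise ValueError("redundancy is undefined for an empty S; "
                         "the first mRMR pick maximizes F alone")
    U = _centered_unit_rows(np.asarray(C, dtype=float))
    idx = {g: k for k, g in enumerate(C.index)}
    r = np.abs(U[[idx[j] for j in S]] @ U[idx[i]])
    return float(r.mean())


def mrmr_select_next(
    candidates: list[str], S: list[str], C: pd.DataFrame
) -> tuple[str, float]:
    """One greedy mRMR step: argmax of V_i = F_i / Redund(i|S) over candidates.

    With S empty the criterion reduces to F_i.  Zero redundancy is guarded by
    ``EPS_REDUNDANCY``.  Ties resolve to the candidate earliest in C's index.
    """
    if not candidates:
        raise ValueError("no candidate genes")
    Cm = np.asarray(C, dtype=float)
    idx = {g: k for k, g in enumerate(C.index)}
    cand_rows = [idx[g] for g in candidates]
    F = np.var(Cm[cand_rows], axis=1, ddof=1)
    if S:
        U = _centered_unit_rows(Cm)
        red = np.abs(U[cand_rows] @ U[[idx[j] for j in S]].T).mean(axis=1)
        guarded = np.maximum(red, EPS_REDUNDANCY)
        if (red < EPS_REDUNDANCY).any():
            logger.info("zero redundancy encountered; applying eps guard")
        V = F / guarded
    else:
        V = F
    # stable tie-break: among equal V, the candidate earliest in C's index wins
    order = sorted(range(len(candidates)), key=lambda k: cand_rows[k])
    vmax = max(V[k] for k in order)
    best = next(k for k in order if V[k] == vmax)
    return candidates[best], float(V[best])


def mrx3(
    E: pd.DataFrame,
    C: pd.DataFrame,
    n: int,
    trim_frac: float = 0.10,
) -> GeneSubset:
    """Full MRx3 selection: noise trimming then n greedy mRMR steps.

    The output is ordered by selection step, and the prefix property holds:
    the first n−1 entries equal the n−1-gene selection on the same inputs.
    """
    scores = estimate_incremental_noise(E, C)
    kept, _E_star, C_star = trim_noisy_genes(scores, E, C, trim_frac)
    trimmed = [g for g in E.index if g not in set(kept)]
    if n > len(kept):
        raise ConfigurationError(
            f"requested {n} genes but only {len(kept)} remain after trimming"
        )
    S: list[str] = []
    v_values: list[float] = []
    candidates = list(kept)
    for _ in range(n):
        g, v = mrmr_select_next(candidates, S, C_star)
        S.append(g)
        v_values.append(v)
        candidates.remove(g)
    return GeneSubset(genes=S, v_values=v_values, noise_scores=scores,
                      trimmed_genes=trimmed)


def choose_subset_size(
    E: pd.DataFrame,
    C: pd.DataFrame,
    sizes: list[int],
    trim_frac: float = 0.10,
) -> tuple[SubsetSizeSweep, GeneSubset]:
    """Sweep subset sizes and choose the elbow of the residual-vs-size curve.

    For each candidate size the deconvolution runs on that size-prefix of one
    full MRx3 selection (valid because of the prefix property) and the mean
    voxel relative residual is recorded.  The chosen size sits at the maximum
    discrete second difference r[i-1] − 2r[i] + r[i+1] over interior points.
    Degenerate cases: fewer than 3 sizes → minimum-residual size with a
    warning; a flat curve → smallest size with a warning.
    """
    from .deconvolution import deconvolve

    if not sizes:
        raise ConfigurationError("sizes must be non-empty")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ConfigurationError("sizes must be strictly increasing")
    subset = mrx3(E, C, max(sizes), trim_frac=trim_frac)
    residuals = []
    for s in sizes:
        genes = subset.genes[:s]
        _, report = deconvolve(E.loc[genes], C.loc[genes])
        residuals.append(float(np.nanmean(report.voxel_residual)))
    chosen = pick_elbow(sizes, residuals)
    return SubsetSizeSweep(sizes=list(sizes), residuals=residuals, chosen=chosen), subset


def pick_elbow(sizes: list[int], residuals: list[float]) -> int:
    """Discrete-second-difference elbow rule (see :func:`choose_subset_size`)."""
    if len(sizes) < 3:
        logger.warning("fewer than 3 sizes: elbow undefined, returning the "
                       "minimum-residual size")
        return sizes[int(np.argmin(residuals))]
    r = np.asarray(residuals, dtype=float)
    d2 = r[:-2] - 2 * r[1:-1] + r[2:]
    if np.allclose(r, r[0]):
        logger.warning("flat residual curve; returning the smallest size")
        return sizes[0]
    return sizes[int(np.argmax(d2)) + 1]
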