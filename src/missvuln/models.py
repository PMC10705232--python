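"""Multivariate models of regional tau from cell-type or gene predictors.

Two variable-selection routes, mirroring the univariate prefiltering and BIC
machinery of the analysis:

* *BIC*: order candidates by correlation with tau, keep the top fraction,
  then evaluate nested OLS models of dimensionality 2 … n_kept + 1 (counting
  the intercept) adding features in correlation order; the model with the
  lowest BIC wins (ties go to the smaller model).
* *Top-k*: fit directly on the k most correlated features.  By construction
  the top-5 model equals the dimensionality-6 entry of the BIC trace.

Correlation ordering uses |R| by default (negatively correlated, "resilient"
features legitimately enter the models); signed ordering is available.
BIC = n·ln(RSS/n) + (k+1)·ln(n) with k predictors excluding the intercept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyModelError, ShapeError
from .vulnstats import bonferroni

logger = logging.getLogger(__name__)

RSS_FLOOR = 1e-300

#: significance stars per the reporting convention of the results tables
STAR_THRESHOLDS = ((1e-4, "***"), (1e-3, "**"), (1e-2, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def round_half_away(x: float) -> int:
    """round() with halves away from zero (3.5 → 4), not banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class LinearModelFit:
    features: list[str]
    coef: pd.Series  # includes "intercept"
    r2: float
    rss: float
    n: int
    k: int
    bic: float
    f_pvalue: float
    f_pvalue_corrected: float | None = None
    exact_fit: bool = False


@dataclass
class SelectionTrace:
    """BIC at each evaluated dimensionality, with the chosen one."""

    dimensionalities: list[int]
    bics: list[float]
    fits: list[LinearModelFit]
    chosen_dim: int


def prefilter_by_correlation(
    r_values: pd.Series,
    keep_frac: float,
    mode: str = "abs",
) -> list[str]:
    """Order features by correlation and keep the top fraction.

    ``mode='abs'`` (default) orders by descending |R|; ``mode='signed'`` by
    descending R.  Missing correlations are excluded first.  Keeps
    round(keep_frac·N) features (half away from zero), minimum 1.
    """
    if not (0 < keep_frac <= 1):
        raise ValueError(f"keep_frac must be in (0, 1], got {keep_frac}")
    r = r_values.dropna()
    if r.empty:
        raise EmptyModelError("all feature correlations are missing")
    key = r.abs() if mode == "abs" else r
    order = np.lexsort((np.arange(len(r)), -key.to_numpy(dtype=float)))
    n_keep = max(1, round_half_away(keep_frac * len(r)))
    return list(r.index[order[:n_keep]])


def _design(values: pd.DataFrame, features: list[str]) -> np.ndarray:
    X = values.loc[features].to_numpy(dtype=float).T  # regions × features
    return np.column_stack([np.ones(X.shape[0]), X])


def bic_score(y: np.ndarray, X: np.ndarray, features: list[str]) -> LinearModelFit:
    """OLS fit and BIC for a design matrix whose first column is the intercept.

    Rank-deficient designs drop the offending trailing features (warned)
    before fitting.  An exact fit floors RSS at 1e-300 and is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ShapeError("response and design row counts differ")
    rank = np.linalg.matrix_rank(X)
    feats = list(features)
    while rank < X.shape[1] and X.shape[1] > 1:
        logger.warning("rank-deficient design; dropping feature %r", feats[-1])
        X = X[:, :-1]
        feats = feats[:-1]
        rank = np.linalg.matrix_rank(X)
    k = X.shape[1] - 1
    if n <= k + 1:
        raise EmptyModelError(f"n={n} too small for {k} predictors plus intercept")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    # numerically exact fit relative to the response scale
    exact = rss <= 1e-12 * max(tss, 1.0)
    rss_b = max(rss, RSS_FLOOR)
    bic = n * math.log(rss_b / n) + (k + 1) * math.log(n)
    if k >= 1 and rss > 0 and n - k - 1 > 0 and tss > rss:
        F = ((tss - rss) / k) / (rss / (n - k - 1))
        f_p = float(sps.f.sf(F, k, n - k - 1))
    elif exact:
        f_p = 0.0
    else:
        f_p = 1.0
    coef = pd.Series(beta, index=["intercept"] + feats)
    return LinearModelFit(features=feats, coef=coef, r2=max(0.0, min(1.0, r2)),
                          rss=rss, n=n, k=k, bic=bic, f_pvalue=f_p,
                          exact_fit=exact)


def select_bic_model(
    features: list[str],
    values: pd.DataFrame,
    y: pd.Series | np.ndarray,
) -> tuple[LinearModelFit, SelectionTrace]:
    """Minimum-BIC model over the nested correlation-ordered family.

    ``features`` must already be in the desired (correlation) order; the
    evaluated models have dimensionality 2 … len(features) + 1 including the
    intercept.  BIC ties resolve to the smaller model.
    """
    if not features:
        raise EmptyModelError("no candidate features")
    yv = np.asarray(y, dtype=float)
    dims, bics, fits = [], [], []
    for m in range(1, len(features) + 1):
        feats = features[:m]
        if yv.size <= m + 1:
            logger.warning("stopping nesting at %d predictors (n=%d)", m - 1, yv.size)
            break
        fit = bic_score(yv, _design(values, feats), feats)
        dims.append(m + 1)
        bics.append(fit.bic)
        fits.append(fit)
    if not fits:
        raise EmptyModelError(
            f"too few observations (n={yv.size}) for any model with >= 1 predictor"
        )
    best = int(np.argmin(bics))  # argmin keeps the first (smallest) of ties
    trace = SelectionTrace(dimensionalities=dims, bics=bics, fits=fits,
                           chosen_dim=dims[best])
    return fits[best], trace


def top_k_model(
    features: list[str],
    values: pd.DataFrame,
    y: pd.Series | np.ndarray,
    k: int = 5,
) -> LinearModelFit:
    """Fit on the k most correlated features (same ordering as the prefilter)."""
    if len(features) < k:
        logger.warning("only %d candidates for top-%d model; using all",
                       len(features), k)
        k = len(features)
    n = np.asarray(y).size
    if n <= k + 2:
        logger.warning("only %d observations; top-%d model reduced to %d "
                       "predictors", n, k, n - 2)
        k = n - 2
    if k < 1:
        raise EmptyModelError(f"n={n} too small for any top-k model")
    feats = features[:k]
    return bic_score(np.asarray(y, dtype=float), _design(values, feats), feats)


@dataclass
class FamilyComparison:
    dataset: str
    rows: pd.DataFrame  # per family: r2, n, bic, p, p_corrected, stars, best
    winner: str | None  # None on an exact BIC tie


def compare_feature_families(
    fits: dict[str, LinearModelFit],
    dataset: str = "",
    n_datasets_for_correction: int = 1,
) -> FamilyComparison:
    """Declare the lower-BIC feature family the winner for one dataset.

    ``fits`` maps family labels (e.g. "celltypes", "genes") to fitted models
    on the same response/region set.  Emits a results-table-shaped frame with
    R², number of predictors, BIC and Bonferroni-corrected overall-model
    significance stars.  An exact BIC tie is reported explicitly.
    """
    labels = list(fits)
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ShapeError(f"fits use different region counts: {ns}")
    bics = {lab: fits[lab].bic for lab in labels}
    best_bic = min(bics.values())
    winners = [lab for lab in labels if bics[lab] == best_bic]
    winner = winners[0] if len(winners) == 1 else None
    rows = []
    for lab in labels:
        f = fits[lab]
        p_corr = bonferroni(f.f_pvalue, n_datasets_for_correction)
        f.f_pvalue_corrected = p_corr
        rows.append({
            "family": lab, "r2": f.r2, "n": f.k, "bic": f.bic,
            "p": f.f_pvalue, "p_corrected": p_corr,
            "stars": significance_stars(p_corr),
            "best": winner is not None and lab == winner,
        })
    if winner is None:
        logger.info("%s: exact BIC tie between %s", dataset, winners)
    return FamilyComparison(dataset=dataset, rows=pd.DataFrame(rows), winner=winner)
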