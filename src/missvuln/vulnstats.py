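"""Univariate vulnerability statistics.

Correlation tables between regional entity values (cell-type densities or
gene expression) and regional tau pathology across experiments; class-level
one-sample and pairwise tests on the pooled correlations; Bonferroni
correction; the selection-frequency goodness-of-fit test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ShapeError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationTable:
    """Entities × datasets Pearson R, matching p-values and per-entity mean R.

    The mean is taken over non-missing datasets only; a dataset is missing for
    an entity when fewer than 3 common regions were available or the entity
    had zero variance.
    """

    R: pd.DataFrame
    p: pd.DataFrame
    mean_R: pd.Series


@dataclass
class ClassTestResult:
    one_sample: pd.DataFrame  # class → t, df, p, p_corrected, degenerate
    pairwise: pd.DataFrame  # class pair → t, df, p, p_corrected
    family_size: int


def pearson(x, y) -> tuple[float, float]:
    """Pearson R with a two-sided t-based p-value.

    Zero-variance input yields an undefined correlation, reported as
    (nan, nan) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ShapeError("need 1-D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(
    regional: dict[str, pd.DataFrame],
    tau: dict[str, pd.Series],
) -> CorrelationTable:
    """One Pearson R per (entity, dataset) plus per-entity means.

    ``regional[name]`` is the entities × regions matrix already projected
    into dataset ``name``'s region space with seeds removed; ``tau[name]`` is
    the aligned tau vector.  The same machinery serves cell types and genes.
    """
    if set(regional) != set(tau):
        raise ShapeError("regional and tau dataset names differ")
    names = list(regional)
    entities = regional[names[0]].index
    R = pd.DataFrame(np.nan, index=entities, columns=names)
    P = pd.DataFrame(np.nan, index=entities, columns=names)
    for name in names:
        mat, t = regional[name], tau[name]
        common = [r for r in t.index if r in mat.columns]
        if len(common) < 3:
            logger.warning("%s: only %d common regions; dataset marked missing",
                           name, len(common))
            continue
        X = mat[common].to_numpy(dtype=float)
        yv = t.loc[common].to_numpy(dtype=float)
        for i, ent in enumerate(mat.index):
            if np.ptp(X[i]) == 0 or np.ptp(yv) == 0:
                continue
            r, p = sps.pearsonr(X[i], yv)
            R.loc[ent, name] = r
            P.loc[ent, name] = p
    return CorrelationTable(R=R, p=P, mean_R=R.mean(axis=1, skipna=True))


def bonferroni(p: float, n_tests: int) -> float:
    """Multiply the nominal p by the family size, capped at 1."""
    if not (0 <= p <= 1):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def _one_sample(values: np.ndarray) -> tuple[float, int, float, bool]:
    df = values.size - 1
    sd = values.std(ddof=1)
    if sd == 0:
        if values.mean() == 0:
            return 0.0, df, 1.0, False
        t = float("inf") if values.mean() > 0 else float("-inf")
        return t, df, 0.0, True  # degenerate: constant nonzero values
    res = sps.ttest_1samp(values, 0.0)
    return float(res.statistic), df, float(res.pvalue), False


def class_tests(
    tab: CorrelationTable,
    classes: dict[str, str],
    family_size: int | None = None,
) -> ClassTestResult:
    """Class-level tests on pooled correlation values.

    Per class: a one-sample t of the class's pooled R values (all member
    entities × all datasets) against 0.  Between classes: Welch two-sample
    tests for every pair.  All p-values are Bonferroni-corrected over the
    family (by default the total number of tests performed).  Classes with
    fewer than 2 pooled values are excluded with a warning.
    """
    pooled: dict[str, np.ndarray] = {}
    for cls in dict.fromkeys(classes.values()):
        members = [e for e in tab.R.index if classes.get(e) == cls]
        vals = tab.R.loc[members].to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            logger.warning("class %r has < 2 values; excluded", cls)
            continue
        pooled[cls] = vals

    one_rows = []
    for cls, vals in pooled.items():
        t, df, p, degen = _one_sample(vals)
        one_rows.append({"class": cls, "t": t, "df": df, "p": p,
                         "degenerate": degen})
    pair_rows = []
    for a, b in itertools.combinations(pooled, 2):
        res = sps.ttest_ind(pooled[a], pooled[b], equal_var=False)
        pair_rows.append({
            "class_a": a, "class_b": b,
            "t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue),
        })
    n_family = family_size if family_size is not None else len(one_rows) + len(pair_rows)
    one = pd.DataFrame(one_rows).set_index("class") if one_rows else pd.DataFrame()
    if len(one):
        one["p_corrected"] = [bonferroni(p, n_family) for p in one["p"]]
    pair = pd.DataFrame(pair_rows)
    if len(pair):
        pair["p_corrected"] = [bonferroni(p, n_family) for p in pair["p"]]
    return ClassTestResult(one_sample=one, pairwise=pair, family_size=n_family)


def chi2_gof(
    observed,
    expected,
    df: int | None = None,
) -> tuple[float, int, float]:
    """Chi-squared goodness of fit: Σ(O−E)²/E with an upper-tail p.

    ``df`` defaults to (number of categories with E > 0) − 1 but can be
    overridden.  Zero-expected categories are dropped with a warning (the
    default df adjusts accordingly).  Totals must agree within rounding.
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape:
        raise ShapeError("observed and expected differ in length")
    if abs(O.sum() - E.sum()) > 0.5 + 1e-9:
        raise ValueError(
            f"totals differ beyond rounding: {O.sum()} observed vs {E.sum()} expected"
        )
    keep = E > 0
    if not keep.all():
        logger.warning("%d zero-expected categories dropped", int((~keep).sum()))
        O, E = O[keep], E[keep]
    stat = float((((O - E) ** 2) / E).sum())
    dof = int(df) if df is not None else O.size - 1
    return stat, dof, float(sps.chi2.sf(stat, dof))


def selection_frequency(
    models: list[list[str]],
    entities: list[str],
) -> pd.Series:
    """Count, per entity, how many models included it."""
    counts = pd.Series(0, index=pd.Index(entities), dtype=int)
    for feats in models:
        for f in feats:
            if f in counts.index:
                counts[f] += 1
    return counts


def class_representation_test(
    counts: pd.Series,
    classes: dict[str, str],
    mode: str = "proportional",
    df: int | None = None,
) -> tuple[pd.Series, float, int, float]:
    """Are the classes equally represented among selected features?

    Aggregates per-entity selection counts into class totals and tests them
    against a null of equal representation.  Under ``mode='proportional'``
    (default) the expected counts are proportional to the number of entities
    per class — the fair null when class sizes differ; ``mode='equal'`` uses
    a flat expectation.
    """
    class_names = list(dict.fromkeys(classes.values()))
    totals = pd.Series(0.0, index=class_names)
    sizes = pd.Series(0.0, index=class_names)
    for ent, cls in classes.items():
        sizes[cls] += 1
        if ent in counts.index:
            totals[cls] += counts[ent]
    total = totals.sum()
    if mode == "proportional":
        expected = total * sizes / sizes.sum()
    elif mode == "equal":
        expected = pd.Series(total / len(class_names), index=class_names)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    stat, dof, p = chi2_gof(totals.to_numpy(), expected.to_numpy(), df=df)
    return totals, stat, dof, p
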