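"""Construction of vulnerability/resilience gene sets.

Four sets are built for functional comparison and external GO analysis:

* SV-G / SR-G — *direct* sets: the top decile of genes by |mean tau
  correlation| across experiments, split by sign (positive → SV-G,
  negative → SR-G).
* SV-C / SR-C — *cell-type-mediated* sets: per vulnerable (resp. resilient)
  cell type, a per-type quota of its most differentially expressed genes
  (largest z-score of column-normalized signature expression across cell
  types), unioned with duplicates removed.  The quota is sized against the
  matching direct set so the two are comparable: quota = ceil(|SV-G| /
  n_vulnerable_types) by default.

Vulnerable types are those with positive mean tau correlation that entered
at least one multivariate model; resilient types are the symmetric case.
Every set carries provenance sufficient to regenerate it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .models import round_half_away
from .selection import normalize_inputs

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    label: str  # SV-G | SR-G | SV-C | SR-C
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.label}: duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def direct_gene_sets(
    mean_gene_R: pd.Series,
    frac: float = 0.10,
    mode: str = "abs_split",
) -> tuple[GeneSet, GeneSet]:
    """Top-decile correlated / anti-correlated genes (SV-G, SR-G).

    ``mode='abs_split'`` (default): rank by |mean R|, take the top
    round(frac·N) genes and partition by sign.  ``mode='signed'``: take the
    top frac by signed R for SV-G and the bottom frac for SR-G.
    """
    if not (0 < frac < 1):
        raise ConfigurationError(f"frac must be in (0, 1), got {frac}")
    r = mean_gene_R.dropna()
    n_top = round_half_away(frac * len(r))
    if n_top < 1:
        raise ConfigurationError("frac·N_genes < 1: no genes would be selected")
    if mode == "abs_split":
        order = np.lexsort((np.arange(len(r)), -r.abs().to_numpy(dtype=float)))
        top = r.iloc[order[:n_top]]
        sv = [g for g in top.index if top[g] > 0]
        sr = [g for g in top.index if top[g] < 0]
        if len(sv) + len(sr) < n_top:
            logger.warning("genes with exactly zero mean R excluded from both sets")
    elif mode == "signed":
        order = np.lexsort((np.arange(len(r)), -r.to_numpy(dtype=float)))
        sv = list(r.index[order[:n_top]])
        sr = list(r.index[order[::-1][:n_top]])
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if not sr:
        logger.warning("no anti-correlated genes; SR-G is empty")
    if not sv:
        logger.warning("no positively correlated genes; SV-G is empty")
    prov = {"frac": frac, "mode": mode, "n_genes": len(r), "n_top": n_top}
    return (
        GeneSet("SV-G", sv, {**prov, "sign": "positive"}),
        GeneSet("SR-G", sr, {**prov, "sign": "negative"}),
    )


def de_zscores(
    C: pd.DataFrame, c_scheme: str = "sum"
) -> tuple[pd.DataFrame, pd.Series]:
    """Differential-expression z-scores of each gene across cell types.

    The signature matrix is first column-normalized (per cell type, same
    scheme options as input normalization), then each gene row is
    standardized with the sample standard deviation (N−1).  Zero-variance
    rows get all-zero z-scores and are flagged.
    """
    if C.shape[1] < 2:
        raise ConfigurationError("need at least 2 cell types for z-scores")
    dummy_E = pd.DataFrame(np.ones((C.shape[0], 1)), index=C.index)
    _, Cn, _ = normalize_inputs(dummy_E, C, c_scheme=c_scheme)
    X = np.asarray(Cn, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flagged = pd.Series((sd == 0).ravel(), index=C.index, name="zero_variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    if flagged.any():
        logger.warning("%d zero-variance gene rows flagged (z set to 0)",
                       int(flagged.sum()))
    return pd.DataFrame(Z, index=C.index, columns=C.columns), flagged


def quota(sv_g_size: int, n_vuln_types: int, mode: str = "ceil") -> int:
    """Per-type gene quota sizing SV-C against SV-G: ceil(|SV-G| / n_types).

    Ceiling is the default convention; half-away-from-zero rounding is
    available as ``mode='round'``.
    """
    if sv_g_size < 1 or n_vuln_types < 1:
        raise ConfigurationError("both sizes must be >= 1")
    if mode == "ceil":
        return math.ceil(sv_g_size / n_vuln_types)
    if mode == "round":
        return round_half_away(sv_g_size / n_vuln_types)
    raise ConfigurationError(f"unknown quota mode {mode!r}")


def _top_genes_per_type(z: pd.DataFrame, celltype: str, q: int) -> list[str]:
    col = z[celltype]
    order = np.lexsort((np.arange(len(col)), -col.to_numpy(dtype=float)))
    return list(col.index[order[:q]])


def celltype_gene_sets(
    z: pd.DataFrame,
    vulnerable: list[str],
    resilient: list[str],
    sv_g_size: int,
    sr_g_size: int,
    quota_mode: str = "ceil",
) -> tuple[GeneSet, GeneSet]:
    """Union-of-quotas construction of SV-C and SR-C.

    Per vulnerable type, its quota of highest-z genes (ties by gene order);
    the union across types, first contribution order, duplicates removed.
    Symmetric for resilient types sized against SR-G.  Contributing-type
    provenance is retained per gene.
    """
    def build(types: list[str], ref_size: int, label: str) -> GeneSet:
        if not types:
            logger.warning("%s: no contributing cell types; empty set", label)
            return GeneSet(label, [], {"quota": 0, "types": []})
        q = quota(ref_size, len(types), mode=quota_mode)
        if q > z.shape[0]:
            logger.warning("%s: quota %d exceeds gene count %d; capped",
                           label, q, z.shape[0])
            q = z.shape[0]
        contributors: dict[str, list[str]] = {}
        ordered: list[str] = []
        for t in types:
            for g in _top_genes_per_type(z, t, q):
                if g not in contributors:
                    contributors[g] = []
                    ordered.append(g)
                contributors[g].append(t)
        return GeneSet(label, ordered, {
            "quota": q, "quota_mode": quota_mode, "reference_size": ref_size,
            "types": list(types), "contributors": contributors,
        })

    if not vulnerable and not resilient:
        raise ConfigurationError("no vulnerable or resilient cell types given")
    return build(vulnerable, sv_g_size, "SV-C"), build(resilient, sr_g_size, "SR-C")


def select_vulnerable_types(
    mean_R: pd.Series, selection_counts: pd.Series
) -> tuple[list[str], list[str]]:
    """Vulnerable/resilient type lists from univariate and multivariate evidence.

    Vulnerable: mean tau correlation > 0 *and* selected in at least one
    multivariate model.  Resilient: the symmetric rule with mean R < 0.
    """
    common = [t for t in mean_R.index if t in selection_counts.index]
    vulnerable = [t for t in common
                  if mean_R[t] > 0 and selection_counts[t] >= 1]
    resilient = [t for t in common
                 if mean_R[t] < 0 and selection_counts[t] >= 1]
    if not vulnerable:
        logger.warning("no vulnerable cell types identified")
    if not resilient:
        logger.warning("no resilient cell types identified")
    return vulnerable, resilient


def overlap_counts(A: GeneSet, B: GeneSet) -> tuple[int, int, int]:
    """(|A∩B|, |A\\B|, |B\\A|) — the numbers behind a two-set Venn diagram."""
    a, b = set(A.genes), set(B.genes)
    return len(a & b), len(a - b), len(b - a)


def export_gene_list(gene_set: GeneSet, path: str | Path) -> Path:
    """Write one gene symbol per line with a provenance comment header.

    The plain-text format is directly usable as input to external enrichment
    services.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# gene set: {gene_set.label}\n")
        fh.write(f"# n_genes: {len(gene_set)}\n")
        for key in ("frac", "mode", "quota", "quota_mode", "reference_size", "types"):
            if key in gene_set.provenance:
                fh.write(f"# {key}: {gene_set.provenance[key]}\n")
        for g in gene_set.genes:
            fh.write(f"{g}\n")
    if not gene_set.genes:
        logger.warning("%s: empty gene set exported (header only)", gene_set.label)
    return path


def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes
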