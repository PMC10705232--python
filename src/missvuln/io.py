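"""File formats and input preprocessing.

TSV with a ``#``-prefixed provenance header is the canonical matrix format;
JSON carries metadata (parcellations, seeds, class labels, configs).  Floats
are written with 17 significant digits so matrices round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import AlignmentError, ConfigurationError

logger = logging.getLogger(__name__)


def write_matrix(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a labelled matrix as TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = dict(meta or {})
    header.setdefault("software", f"missvuln {__version__}")
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", float_format="%.17g")
    return path


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV matrix written by :func:`write_matrix` (header returned)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df, meta


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def collapse_probes(
    expr: pd.DataFrame, probe_to_gene: dict[str, str]
) -> pd.DataFrame:
    """Unweighted averaging of probes mapping to the same gene.

    Single-probe genes pass through unchanged; an unmapped probe is an error
    listing the offending probes.  Output gene order follows first appearance
    of each gene among the probes.
    """
    unmapped = [p for p in expr.index if p not in probe_to_gene]
    if unmapped:
        raise ConfigurationError(f"unmapped probes: {unmapped}")
    genes = [probe_to_gene[p] for p in expr.index]
    grouped = expr.groupby(pd.Index(genes, name="gene"), sort=False).mean()
    return grouped


def intersect_genes(*matrices: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict all matrices to their common genes, sorted, identically ordered.

    The number of genes dropped per input is logged; an empty intersection is
    an error.
    """
    common = set(matrices[0].index)
    for m in matrices[1:]:
        common &= set(m.index)
    if not common:
        raise AlignmentError("empty gene intersection")
    order = sorted(common)
    for i, m in enumerate(matrices):
        dropped = len(m.index) - len(order)
        if dropped:
            logger.info("matrix %d: %d genes dropped by intersection", i, dropped)
    return [m.loc[order] for m in matrices]
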