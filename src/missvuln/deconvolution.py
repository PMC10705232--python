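"""Voxel-wise nonnegative least-squares deconvolution.

Given the gene-subset spatial expression matrix E_red (genes × voxels) and
signature matrix C_red (genes × cell types), the cell-type density of voxel k
is the nonnegative vector d_k minimizing ||e_k − C_red·d_k||₂.  Voxels are
solved independently (no spatial coupling) with the Lawson–Hanson active-set
solver, which returns the exact KKT-satisfying solution; whenever the
unconstrained least-squares solution is already elementwise nonnegative the
two coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import AlignmentError, ShapeError
from .regions import Parcellation, aggregate_voxels_to_regions

logger = logging.getLogger(__name__)


@dataclass
class ResidualReport:
    """Per-voxel relative residuals ||e_k − C d_k|| / ||e_k||.

    Voxels with zero total expression have an undefined relative residual;
    they are reported as NaN and flagged in ``zero_voxels`` rather than
    silently divided.  ``region_residual`` (mean over each region's defined
    voxels) is present when a parcellation was supplied.
    """

    voxel_residual: np.ndarray
    zero_voxels: np.ndarray
    region_residual: pd.Series | None = None


def nnls_voxel(e_k: np.ndarray, C_red: np.ndarray) -> np.ndarray:
    """Solve min ||e_k − C_red·d||₂ subject to d ≥ 0 for one voxel."""
    e = np.asarray(e_k, dtype=float)
    C = np.asarray(C_red, dtype=float)
    if C.ndim != 2 or C.shape[1] < 1:
        raise ShapeError("C_red must be 2-D with at least one cell type")
    if e.shape != (C.shape[0],):
        raise ShapeError(f"expression vector length {e.shape} does not match "
                         f"{C.shape[0]} genes")
    if not (np.isfinite(e).all() and np.isfinite(C).all()):
        raise ValueError("non-finite values in NNLS input")
    d, _ = nnls(C, e)
    return d


def deconvolve(
    E_red: pd.DataFrame,
    C_red: pd.DataFrame,
    parcellation: Parcellation | None = None,
) -> tuple[pd.DataFrame, ResidualReport]:
    """Apply :func:`nnls_voxel` independently to every voxel of E_red.

    Gene identifiers of the two matrices must agree in content and order;
    mismatches raise an :class:`AlignmentError` naming the offending genes.
    Returns the cell-types × voxels density map (voxel order preserved) and a
    residual report.
    """
    if list(E_red.index) != list(C_red.index):
        offending = sorted(
            set(E_red.index).symmetric_difference(C_red.index)
        ) or ["(same set, different order)"]
        raise AlignmentError(f"gene identifiers misaligned: {offending[:10]}")
    Em = np.asarray(E_red, dtype=float)
    Cm = np.asarray(C_red, dtype=float)
    n_vox = Em.shape[1]
    D = np.empty((Cm.shape[1], n_vox))
    resid = np.empty(n_vox)
    for k in range(n_vox):
        D[:, k] = nnls_voxel(Em[:, k], Cm)
        resid[k] = np.linalg.norm(Em[:, k] - Cm @ D[:, k])
    norms = np.linalg.norm(Em, axis=0)
    zero = norms == 0
    if zero.any():
        logger.info("%d zero-expression voxels flagged in the residual report",
                    int(zero.sum()))
    rel = np.where(zero, np.nan, resid / np.where(zero, 1.0, norms))
    region_resid = None
    if parcellation is not None:
        region_resid = aggregate_voxels_to_regions(
            pd.DataFrame(rel[None, :], index=["residual"]), parcellation
        ).loc["residual"]
    density = pd.DataFrame(D, index=C_red.columns, columns=E_red.columns)
    report = ResidualReport(voxel_residual=rel, zero_voxels=zero,
                            region_residual=region_resid)
    return density, report
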