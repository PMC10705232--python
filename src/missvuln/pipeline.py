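"""End-to-end orchestration: simulate → select → deconvolve → regionalize →
correlate → model → embed → genesets.

`run_pipeline` executes every stage in order on a synthetic bundle and
returns all intermediate products in a :class:`PipelineResult`; when an
output directory is given, each stage also writes its TSV/JSON artifacts with
provenance headers.  Identical configuration and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .deconvolution import ResidualReport, deconvolve
from .embedding import (
    Embedding,
    LoadingRegression,
    correlation_distance,
    embedding_tau_regression,
    graph_laplacian,
    similarity_from_distance,
    spectral_embed,
)
from .genesets import (
    GeneSet,
    celltype_gene_sets,
    de_zscores,
    direct_gene_sets,
    export_gene_list,
    overlap_counts,
    select_vulnerable_types,
)
from .io import write_json, write_matrix
from .models import (
    FamilyComparison,
    LinearModelFit,
    SelectionTrace,
    compare_feature_families,
    prefilter_by_correlation,
    select_bic_model,
    top_k_model,
)
from .regions import (
    RegionCorrespondence,
    aggregate_voxels_to_regions,
    match_regions,
    remove_seed_regions,
)
from .selection import GeneSubset, SubsetSizeSweep, choose_subset_size, normalize_inputs
from .synthetic import GroundTruth, generate_bundle
from .vulnstats import (
    ClassTestResult,
    CorrelationTable,
    class_representation_test,
    class_tests,
    correlation_table,
    selection_frequency,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetModels:
    bic_fit: LinearModelFit
    bic_trace: SelectionTrace
    top_k_fit: LinearModelFit
    gene_bic_fit: LinearModelFit
    gene_top_k_fit: LinearModelFit
    comparison: FamilyComparison


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundle: GroundTruth
    E_norm: pd.DataFrame
    C_norm: pd.DataFrame
    sweep: SubsetSizeSweep
    subset: GeneSubset
    density: pd.DataFrame
    residuals: ResidualReport
    density_regional: pd.DataFrame
    celltype_table: CorrelationTable
    gene_table: CorrelationTable
    class_result: ClassTestResult
    dataset_models: dict[str, DatasetModels]
    selection_counts: pd.Series
    class_counts: pd.Series
    class_chi2: tuple[float, int, float]
    embeddings: dict[str, Embedding]
    embedding_regressions: dict[str, LoadingRegression]
    gene_sets: dict[str, GeneSet]
    overlaps: dict[str, tuple[int, int, int]]
    vulnerable_types: list[str]
    resilient_types: list[str]
    aligned_density: dict[str, pd.DataFrame] = field(default_factory=dict)
    aligned_tau: dict[str, pd.Series] = field(default_factory=dict)


def risk_gene_panel(bundle: GroundTruth) -> list[str]:
    """Candidate gene panel for the gene-based models.

    The full-scale analysis contrasts cell-type models against a small panel
    of disease risk genes, which are not themselves markers of the vulnerable
    cell types.  The synthetic analogue therefore draws its panel from the
    baseline (non-marker) genes: the first 2 × n_celltypes of them, a panel
    of comparable relative size.  If too few baseline genes exist, the list
    is padded with class-marker genes.
    """
    from .synthetic import baseline_genes, class_marker_genes

    cfg = bundle.config
    panel = baseline_genes(cfg)[: 2 * cfg.n_celltypes]
    if len(panel) < 2 * cfg.n_celltypes:
        extra = [g for gs in class_marker_genes(cfg).values() for g in gs]
        panel += extra[: 2 * cfg.n_celltypes - len(panel)]
    return panel


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    out = Path(outdir) if outdir is not None else None

    def stage_dir(name: str) -> Path | None:
        if out is None:
            return None
        d = out / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    prov = {"config_hash": cfg.digest(), "seed": cfg.seed,
            "software": f"missvuln {__version__}"}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_json({**prov, "config": cfg.to_dict()}, out / "provenance.json")

    # -- 1. simulate ---------------------------------------------------------
    bundle = generate_bundle(cfg.synthetic)
    if (d := stage_dir("01_simulate")) is not None:
        from .synthetic import write_bundle

        write_bundle(bundle, d)

    # -- 2. informative-gene selection --------------------------------------
    E_norm, C_norm, norm_meta = normalize_inputs(
        bundle.E, bundle.C_true, e_scheme=cfg.e_scheme, c_scheme=cfg.c_scheme
    )
    sizes = cfg.default_subset_sizes()
    sweep, subset = choose_subset_size(E_norm, C_norm, sizes, trim_frac=cfg.trim_frac)
    selected = subset.genes[: sweep.chosen]
    if (d := stage_dir("02_select_genes")) is not None:
        (d / "selected_genes.txt").write_text("\n".join(selected) + "\n")
        write_matrix(sweep.to_frame().set_index("size"), d / "sweep.tsv",
                     {**prov, **norm_meta})
        write_matrix(subset.noise_scores.to_frame(), d / "noise_scores.tsv", prov)

    # -- 3. deconvolution ----------------------------------------------------
    density, residuals = deconvolve(
        E_norm.loc[selected], C_norm.loc[selected], bundle.parcellation
    )
    if (d := stage_dir("03_deconvolve")) is not None:
        write_matrix(density, d / "density.tsv", prov)
        write_matrix(
            pd.DataFrame({"relative_residual": residuals.voxel_residual}),
            d / "voxel_residuals.tsv", prov,
        )

    # -- 4. regionalization --------------------------------------------------
    density_regional = aggregate_voxels_to_regions(density, bundle.parcellation)
    expression_regional = aggregate_voxels_to_regions(E_norm, bundle.parcellation)
    aligned_density: dict[str, pd.DataFrame] = {}
    aligned_expr: dict[str, pd.DataFrame] = {}
    aligned_tau: dict[str, pd.Series] = {}
    for ds in bundle.tau_datasets:
        corr = ds.correspondence or RegionCorrespondence.identity(
            bundle.parcellation.region_names
        )
        dens_ds = match_regions(density_regional, bundle.parcellation, corr)
        expr_ds = match_regions(expression_regional, bundle.parcellation, corr)
        dens_f, tau_f = remove_seed_regions(dens_ds, ds)
        expr_f, _ = remove_seed_regions(expr_ds, ds)
        aligned_density[ds.name] = dens_f
        aligned_expr[ds.name] = expr_f
        aligned_tau[ds.name] = tau_f
    if (d := stage_dir("04_regionalize")) is not None:
        write_matrix(density_regional, d / "density_regional.tsv", prov)

    # -- 5. univariate correlations and class tests -------------------------
    celltype_table = correlation_table(aligned_density, aligned_tau)
    gene_table = correlation_table(aligned_expr, aligned_tau)
    class_result = class_tests(celltype_table, bundle.class_labels,
                               family_size=cfg.class_test_family)
    if (d := stage_dir("05_correlate")) is not None:
        write_matrix(celltype_table.R, d / "celltype_R.tsv", prov)
        write_matrix(gene_table.R, d / "gene_R.tsv", prov)
        write_matrix(class_result.one_sample, d / "class_one_sample.tsv",
                     {**prov, "family_size": class_result.family_size})
        write_matrix(class_result.pairwise, d / "class_pairwise.tsv", prov)

    # -- 6. multivariate models ---------------------------------------------
    panel = risk_gene_panel(bundle)
    dataset_models: dict[str, DatasetModels] = {}
    n_ds = len(bundle.tau_datasets)
    for ds in bundle.tau_datasets:
        y = aligned_tau[ds.name]
        ct_candidates = prefilter_by_correlation(
            celltype_table.R[ds.name], cfg.keep_frac_celltypes
        )
        ct_fit, ct_trace = select_bic_model(ct_candidates,
                                            aligned_density[ds.name], y)
        ct_top = top_k_model(ct_candidates, aligned_density[ds.name], y,
                             k=cfg.top_k)
        gene_r = gene_table.R[ds.name].loc[panel]
        g_candidates = prefilter_by_correlation(gene_r, cfg.keep_frac_genes)
        g_fit, _ = select_bic_model(g_candidates, aligned_expr[ds.name], y)
        g_top = top_k_model(g_candidates, aligned_expr[ds.name], y, k=cfg.top_k)
        comparison = compare_feature_families(
            {"celltypes": ct_fit, "genes": g_fit},
            dataset=ds.name, n_datasets_for_correction=n_ds,
        )
        dataset_models[ds.name] = DatasetModels(
            bic_fit=ct_fit, bic_trace=ct_trace, top_k_fit=ct_top,
            gene_bic_fit=g_fit, gene_top_k_fit=g_top, comparison=comparison,
        )
    selection_counts = selection_frequency(
        [m.bic_fit.features for m in dataset_models.values()],
        list(bundle.C_true.columns),
    )
    class_counts, chi2_stat, chi2_df, chi2_p = class_representation_test(
        selection_counts, bundle.class_labels
    )
    if (d := stage_dir("06_model")) is not None:
        table = pd.concat(
            [m.comparison.rows.assign(dataset=name)
             for name, m in dataset_models.items()],
            ignore_index=True,
        ).set_index("dataset")
        write_matrix(table, d / "model_comparison.tsv", prov)
        write_matrix(selection_counts.to_frame("count"),
                     d / "selection_counts.tsv",
                     {**prov, "chi2": chi2_stat, "df": chi2_df, "p": chi2_p})

    # -- 7. spectral embedding ----------------------------------------------
    C_red = C_norm.loc[selected]
    embeddings: dict[str, Embedding] = {}
    regressions: dict[str, LoadingRegression] = {}
    for mode, X in (("gene", C_red.T), ("spatial", density_regional)):
        Dm = correlation_distance(pd.DataFrame(X))
        S = similarity_from_distance(Dm)
        S.mode = mode
        emb = spectral_embed(graph_laplacian(S))
        embeddings[mode] = emb
        for v_name, v in (("v2", emb.v2), ("v3", emb.v3)):
            regressions[f"{mode}_{v_name}"] = embedding_tau_regression(
                v, celltype_table.mean_R
            )
    if (d := stage_dir("07_embed")) is not None:
        for mode, emb in embeddings.items():
            write_matrix(emb.eigenvectors[[2, 3]], d / f"loadings_{mode}.tsv", prov)
            write_matrix(pd.DataFrame({"eigenvalue": emb.eigenvalues}),
                         d / f"eigenvalues_{mode}.tsv", prov)
        write_json({k: vars(v) for k, v in regressions.items()},
                   d / "loading_regressions.json")

    # -- 8. gene sets --------------------------------------------------------
    sv_g, sr_g = direct_gene_sets(gene_table.mean_R, frac=cfg.geneset_frac,
                                  mode=cfg.geneset_mode)
    vulnerable, resilient = select_vulnerable_types(celltype_table.mean_R,
                                                    selection_counts)
    z, _flags = de_zscores(bundle.C_true, c_scheme=cfg.c_scheme)
    sv_c, sr_c = celltype_gene_sets(
        z, vulnerable, resilient,
        sv_g_size=max(len(sv_g), 1), sr_g_size=max(len(sr_g), 1),
        quota_mode=cfg.quota_mode,
    )
    gene_sets = {"SV-G": sv_g, "SR-G": sr_g, "SV-C": sv_c, "SR-C": sr_c}
    overlaps = {
        "SV": overlap_counts(sv_g, sv_c),
        "SR": overlap_counts(sr_g, sr_c),
    }
    if (d := stage_dir("08_genesets")) is not None:
        for gs in gene_sets.values():
            export_gene_list(gs, d / f"{gs.label}.txt")
        write_json(
            {k: {"intersection": v[0], "only_first": v[1], "only_second": v[2]}
             for k, v in overlaps.items()},
            d / "overlaps.json",
        )

    return PipelineResult(
        config=cfg,
        bundle=bundle,
        E_norm=E_norm,
        C_norm=C_norm,
        sweep=sweep,
        subset=subset,
        density=density,
        residuals=residuals,
        density_regional=density_regional,
        celltype_table=celltype_table,
        gene_table=gene_table,
        class_result=class_result,
        dataset_models=dataset_models,
        selection_counts=selection_counts,
        class_counts=class_counts,
        class_chi2=(chi2_stat, chi2_df, chi2_p),
        embeddings=embeddings,
        embedding_regressions=regressions,
        gene_sets=gene_sets,
        overlaps=overlaps,
        vulnerable_types=vulnerable,
        resilient_types=resilient,
        aligned_density=aligned_density,
        aligned_tau=aligned_tau,
    )
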