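"""Regionalization: voxel→region aggregation, region matching, seed removal.

Cell-type densities are inferred at voxel resolution but tau pathology is
quantified per atlas region, and each tauopathy experiment uses its own
(coarser) region space.  This module collapses voxel maps onto the atlas
parcellation, maps atlas regions into each experiment's region space with
volume-weighted merging of subregions, and removes injection-seeded regions
from both sides before any association analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CorrespondenceError, ShapeError

logger = logging.getLogger(__name__)

BACKGROUND_LABEL = 0


@dataclass
class Parcellation:
    """Voxel→region labelling with region names and volumes.

    ``labels`` holds one integer label per voxel; label 0 is background and
    is excluded from all regions.  ``region_names`` maps label ``i`` (1-based)
    to ``region_names[i - 1]``.  Volumes default to voxel counts but physical
    volumes may be supplied instead.
    """

    labels: np.ndarray
    region_names: list[str]
    volumes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n_named = len(self.region_names)
        present = set(np.unique(self.labels)) - {BACKGROUND_LABEL}
        if present and max(present) > n_named:
            raise ConfigurationError(
                f"label {max(present)} exceeds the {n_named} named regions"
            )
        if self.volumes is None:
            counts = np.bincount(self.labels, minlength=n_named + 1)
            self.volumes = pd.Series(
                counts[1 : n_named + 1].astype(float), index=self.region_names
            )
        bad = self.volumes[self.volumes <= 0]
        if len(bad):
            raise ConfigurationError(f"non-positive region volumes: {list(bad.index)}")

    @property
    def n_voxels(self) -> int:
        return self.labels.size

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def region_voxels(self, name: str) -> np.ndarray:
        label = self.region_names.index(name) + 1
        return np.flatnonzero(self.labels == label)


@dataclass
class TauDataset:
    """Regional tau quantification for one experimental condition.

    ``tau`` is indexed by the dataset's own region names and, by convention,
    already excludes any seeded region.  ``seed_regions`` lists the injection
    sites (empty for unseeded, endogenously developing models).
    ``correspondence`` optionally maps each dataset region to the atlas
    regions it covers; ``None`` means the identity mapping.
    """

    name: str
    tau: pd.Series
    seed_regions: list[str] = field(default_factory=list)
    correspondence: "RegionCorrespondence | None" = None

    def __post_init__(self) -> None:
        self.tau = pd.Series(self.tau, dtype=float)
        if self.tau.index.has_duplicates:
            raise ConfigurationError(f"{self.name}: duplicate region names in tau")


class RegionCorrespondence:
    """Mapping from dataset regions to lists of atlas regions.

    Many-to-one merges are expressed as a multi-element atlas list.  An atlas
    region may appear under at most one dataset region.  Dataset regions with
    an empty atlas list are recorded as unmatched and dropped downstream.
    """

    def __init__(self, mapping: dict[str, list[str]]):
        seen: dict[str, str] = {}
        for ds_region, atlas_list in mapping.items():
            for a in atlas_list:
                if a in seen:
                    raise CorrespondenceError(
                        f"atlas region {a!r} mapped to both {seen[a]!r} and {ds_region!r}"
                    )
                seen[a] = ds_region
        self.mapping = {k: list(v) for k, v in mapping.items()}

    @property
    def unmatched(self) -> list[str]:
        return [k for k, v in self.mapping.items() if not v]

    @classmethod
    def identity(cls, regions: list[str]) -> "RegionCorrespondence":
        return cls({r: [r] for r in regions})

    @classmethod
    def read_tsv(cls, path) -> "RegionCorrespondence":
        df = pd.read_csv(path, sep="\t", comment="#", header=0)
        mapping: dict[str, list[str]] = {}
        for ds_region, atlas_region in zip(df.iloc[:, 0], df.iloc[:, 1]):
            mapping.setdefault(str(ds_region), [])
            if not pd.isna(atlas_region) and str(atlas_region):
                mapping[str(ds_region)].append(str(atlas_region))
        return cls(mapping)

    def write_tsv(self, path) -> None:
        rows = [
            {"dataset_region": d, "atlas_region": a}
            for d, atlas_list in self.mapping.items()
            for a in atlas_list
        ]
        pd.DataFrame(rows, columns=["dataset_region", "atlas_region"]).to_csv(
            path, sep="\t", index=False
        )


def aggregate_voxels_to_regions(
    X_vox: pd.DataFrame, parc: Parcellation
) -> pd.DataFrame:
    """Unweighted mean of voxel values within each parcellation region.

    ``X_vox`` is entities × voxels. Background voxels (label 0) are excluded;
    regions containing no voxels are dropped with a warning.
    """
    if X_vox.shape[1] != parc.n_voxels:
        raise ShapeError(
            f"matrix has {X_vox.shape[1]} voxels, parcellation has {parc.n_voxels}"
        )
    values = np.asarray(X_vox, dtype=float)
    out = {}
    for label, name in enumerate(parc.region_names, start=1):
        mask = parc.labels == label
        if not mask.any():
            logger.warning("region %r has no voxels; dropped", name)
            continue
        out[name] = values[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=X_vox.index)


def match_regions(
    atlas: pd.DataFrame,
    parc: Parcellation,
    corr: RegionCorrespondence,
) -> pd.DataFrame:
    """Project an entities × atlas-regions matrix into a dataset's region space.

    One-to-one mappings copy values; many-to-one mappings take the
    volume-weighted mean over the contributing atlas regions; dataset regions
    with no atlas match are dropped (logged).
    """
    out = {}
    for ds_region, atlas_list in corr.mapping.items():
        if not atlas_list:
            logger.warning("dataset region %r has no atlas match; dropped", ds_region)
            continue
        missing = [a for a in atlas_list if a not in atlas.columns]
        if missing:
            raise CorrespondenceError(
                f"atlas regions {missing} (for dataset region {ds_region!r}) "
                "not present in the regional matrix"
            )
        w = parc.volumes.reindex(atlas_list).to_numpy(dtype=float)
        if np.isnan(w).any():
            raise CorrespondenceError(
                f"no volume recorded for some of {atlas_list}"
            )
        vals = atlas[atlas_list].to_numpy(dtype=float)
        out[ds_region] = vals @ (w / w.sum())
    return pd.DataFrame(out, index=atlas.index)


def remove_seed_regions(
    regional: pd.DataFrame, dataset: TauDataset
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop seeded regions from both the regional matrix and the tau vector.

    Returns the matrix and tau aligned on the same non-seed regions, in the
    tau vector's region order.  Unseeded datasets pass through unchanged.
    """
    for seed in dataset.seed_regions:
        if seed not in regional.columns and seed not in dataset.tau.index:
            raise ConfigurationError(
                f"{dataset.name}: seed region {seed!r} not found"
            )
    keep = [
        r
        for r in dataset.tau.index
        if r not in dataset.seed_regions and r in regional.columns
    ]
    if len(keep) < len([r for r in dataset.tau.index if r not in dataset.seed_regions]):
        dropped = [
            r
            for r in dataset.tau.index
            if r not in dataset.seed_regions and r not in regional.columns
        ]
        logger.warning("%s: regions %s absent from the regional matrix; dropped",
                       dataset.name, dropped)
    return regional[keep], dataset.tau.loc[keep]
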