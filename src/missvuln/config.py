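"""Pipeline configuration and full-atlas reference constants."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic import SyntheticConfig

#: Dimensions and hyperparameters of the full-atlas mouse-brain analysis this
#: package scales down: AGEA coronal ISH expression (200 μm, ~50k voxels) over
#: the 424-region CCFv2 parcellation, a 3763-gene × 42-subclass scRNAseq
#: consensus signature matrix, and 12 PS19 tauopathy experiments.  Recorded as
#: reference provenance; the synthetic generator emulates this geometry at
#: desk scale.
ATLAS_SCALE = {
    "n_genes": 3763,
    "n_celltypes": 42,
    "n_voxels": 50246,
    "n_regions": 424,
    "n_datasets": 12,
    "subset_sweep_min": 400,
    "subset_sweep_max": 3100,
    "subset_size": 1300,
    "sv_g_size": 277,
    "sr_g_size": 100,
    "sv_c_size": 264,
    "sr_c_size": 104,
}


@dataclass
class PipelineConfig:
    """Everything needed to run the end-to-end analysis reproducibly.

    Fractions follow the full-atlas defaults: trim the worst 10% of genes by
    incremental noise, keep the top 25% of cell types (50% of genes) by
    correlation before multivariate modelling, and use the top decile of
    genes for the direct vulnerability sets.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    e_scheme: str = "max"
    c_scheme: str = "sum"
    trim_frac: float = 0.10
    subset_sizes: list[int] | None = None  # None → auto-scaled sweep
    keep_frac_celltypes: float = 0.25
    keep_frac_genes: float = 0.50
    geneset_frac: float = 0.10
    geneset_mode: str = "abs_split"
    quota_mode: str = "ceil"
    top_k: int = 5
    class_test_family: int | None = None  # None → number of tests performed
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        for name in ("trim_frac",):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        for name in ("keep_frac_celltypes", "keep_frac_genes", "geneset_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        # the bundle inherits the pipeline seed unless set explicitly
        if self.seed != self.synthetic.seed and self.synthetic.seed == 0:
            self.synthetic = SyntheticConfig(
                **{**asdict(self.synthetic), "seed": self.seed}
            )

    def default_subset_sizes(self) -> list[int]:
        """Sweep sizes scaled to the synthetic gene pool after trimming.

        Mirrors the full-atlas sweep bounds (400–3100 of 3763 genes, i.e.
        roughly 10–80% of the pool) with five evenly spaced sizes.
        """
        if self.subset_sizes is not None:
            return list(self.subset_sizes)
        import math

        pool = self.synthetic.n_genes - math.ceil(
            self.trim_frac * self.synthetic.n_genes
        )
        lo = max(self.synthetic.n_celltypes + 1, round(0.15 * pool))
        hi = round(0.75 * pool)
        sizes = sorted({round(x) for x in
                        [lo, lo + (hi - lo) * 0.25, lo + (hi - lo) * 0.5,
                         lo + (hi - lo) * 0.75, hi]})
        return [int(s) for s in sizes]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        text = (
            json.dumps(self.to_dict(), indent=1, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
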