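import logging

import pytest

from missvuln import PipelineConfig, SyntheticConfig, generate_bundle
from missvuln.pipeline import run_pipeline

logging.getLogger("missvuln").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline run on the default synthetic study conditions."""
    return run_pipeline(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def default_bundle(default_result):
    return default_result.bundle


@pytest.fixture
def small_cfg():
    """A tiny, fast bundle configuration for unit tests."""
    return SyntheticConfig(
        n_genes=60,
        n_celltypes=6,
        n_voxels=60,
        n_regions=6,
        n_datasets=4,
        markers_per_type=4,
        expression_noise_sd=0.0,
        tau_noise_sd=0.0,
        n_vulnerable=2,
        n_resilient=1,
        seed=11,
    )


@pytest.fixture
def small_bundle(small_cfg):
    return generate_bundle(small_cfg)
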