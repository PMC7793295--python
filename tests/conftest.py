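import pytest

from gataslc.pipeline import PipelineConfig, run_all
from gataslc.simulate import generate_genome, default_config


@pytest.fixture(scope="session")
def noiseless_results(tmp_path_factory):
    """Full pipeline run on noiseless planted data (exact recovery regime)."""
    cfg = PipelineConfig(seed=3, noise_sd=0.0, n_iter=300)
    outdir = tmp_path_factory.mktemp("noiseless_run")
    return run_all(cfg, outdir), cfg, outdir


@pytest.fixture(scope="session")
def synthetic_genome():
    """(sequences, genes, truth) for a default-scenario genome."""
    return generate_genome(default_config(seed=5))
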