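import numpy as np
import pytest

from spliceform.simulate import SimulationConfig, simulate_gene_set


@pytest.fixture(scope="session")
def gene_study():
    """A moderate synthetic gene set shared by translation tests."""
    cfg = SimulationConfig(seed=101, n_genes=30)
    models, genome, events, truth = simulate_gene_set(cfg)
    return cfg, models, genome, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
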