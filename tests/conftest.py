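import numpy as np
import pytest

from riboshift.simulate import TESimConfig, simulate_te_experiment


@pytest.fixture(scope="session")
def small_te_data():
    """A small paired experiment with planted effects, shared across tests."""
    cfg = TESimConfig(n_transcripts=300, frac_rna_de=0.05, frac_te_up=0.1,
                      seed=42)
    rna, ribo, truth = simulate_te_experiment(cfg)
    return cfg, rna, ribo, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
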