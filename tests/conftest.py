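import numpy as np
import pandas as pd
import pytest

from tregomics import SimConfig, generate_counts, generate_proteome, modlog


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic dataset shared across tests."""
    cfg = SimConfig(n_genes=300, seed=11)
    counts, design, truth = generate_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def small_proteome(small_sim):
    cfg, counts, design, truth = small_sim
    return generate_proteome(counts, design, truth, cfg)


@pytest.fixture(scope="session")
def small_modlog(small_sim):
    _, counts, _, _ = small_sim
    return modlog(counts)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_counts():
    """4 genes x 3 samples with hand-checkable structure."""
    from tregomics import CountMatrix

    values = pd.DataFrame(
        [[10, 20, 30], [100, 200, 300], [5, 10, 15], [1, 2, 3]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3"],
    )
    return CountMatrix(values)
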