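import numpy as np
import pytest
from hypothesis import settings

import tisig
from tisig.matrix import LAYER_LOGNORM, ExpressionMatrix

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated experiment shared across tests."""
    cfg = tisig.SimulationConfig(
        n_genes=600, n_control_cells=250, n_trained_cells=700, seed=11
    )
    counts, metadata, truth = tisig.simulate_counts(cfg)
    return counts, metadata, truth


@pytest.fixture(scope="session")
def small_lognorm(small_sim):
    counts, metadata, truth = small_sim
    return tisig.lognormalize(counts), metadata, truth


def make_lognorm(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, gene_ids, cell_ids, LAYER_LOGNORM)
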