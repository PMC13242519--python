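import numpy as np
import pytest

from grnloop.preprocess import CountMatrix
from grnloop.synthdata import make_ground_truth, simulate_dataset


@pytest.fixture
def small_counts():
    """4 cells x 5 genes with MT-/RPS genes for QC, one all-zero gene."""
    genes = ("ACTB", "MT-CO1", "RPS6", "TP53", "ZERO")
    cells = ("c1", "c2", "c3", "c4")
    counts = np.array([
        [15, 5, 0, 10, 0],
        [8, 2, 6, 4, 0],
        [0, 0, 0, 3, 0],
        [9, 1, 2, 0, 0],
    ], dtype=float)
    return CountMatrix(cells, genes, counts, time_label=0.0)


@pytest.fixture(scope="session")
def cascade_truth():
    """Small planted truth reused by fitting tests (session-scoped: frozen)."""
    return make_ground_truth(3, edge_density=0.4, seed=11)


@pytest.fixture(scope="session")
def cascade_noisefree(cascade_truth):
    return simulate_dataset(cascade_truth, noise_sd=0.0, seed=12)


@pytest.fixture(scope="session")
def cascade_noisy(cascade_truth):
    return simulate_dataset(cascade_truth, noise_sd=0.1, seed=13)
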