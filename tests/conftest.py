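import numpy as np
import pytest

from scse.intervals import FragmentIndex
from scse.preprocess import preprocess_matrix
from scse.simulate import SimulationConfig, simulate_dataset

# relaxed QC thresholds matching the desk-scale synthetic data (a few
# hundred peaks, not genome-wide)
SIM_QC = dict(min_peaks=20, min_cells_per_peak=10, min_cells_per_type=50)


@pytest.fixture(scope="session")
def dataset2():
    """Two cell types, planted enhancers, no SE clusters."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def dataset3():
    """Three cell types with planted SE clusters (full-feature dataset)."""
    return simulate_dataset(SimulationConfig(
        seed=5, n_cell_types=3, cells_per_type=100, n_se_clusters_per_type=2))


@pytest.fixture(scope="session")
def split2(dataset2):
    split, _ = preprocess_matrix(dataset2.matrix, **SIM_QC)
    return split


@pytest.fixture(scope="session")
def frag_index2(dataset2):
    return FragmentIndex(dataset2.fragments, dataset2.matrix.barcodes)


@pytest.fixture()
def rng():
    """Fresh seeded generator per test, so tests are order-independent."""
    return np.random.default_rng(1234)
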