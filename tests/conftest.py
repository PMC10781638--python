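import numpy as np
import pytest

from screpliseq import (
    BinaryReplicationMatrix,
    BinGrid,
    generate_truth,
    simulate_cell_states,
    simulate_read_counts,
)


@pytest.fixture(scope="session")
def small_truth():
    """Two-chromosome truth with staggered replication domains."""
    return generate_truth({"chr1": 300, "chr2": 300}, domain_length_bins=50, seed=42)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    cells = simulate_cell_states(small_truth, 20, seed=42)
    return simulate_read_counts(cells, small_truth.bins, depth_per_bin=50, seed=42)


@pytest.fixture(scope="session")
def truth_states():
    """60-cell binary matrix built directly from simulated truth states."""
    truth = generate_truth({"chr1": 600}, domain_length_bins=50, seed=9)
    cells = simulate_cell_states(truth, 60, seed=9)
    states = np.vstack([c.states for c in cells])
    brm = BinaryReplicationMatrix(truth.bins, states,
                                  [c.cell_id for c in cells])
    return truth, cells, brm


@pytest.fixture
def flat_grid():
    return BinGrid.from_chrom_sizes({"chr1": 50 * 50_000}, 50_000)
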