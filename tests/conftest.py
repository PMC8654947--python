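import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import dipscan as d  # noqa: E402


@pytest.fixture(scope="session")
def small_design():
    return d.make_design(recipient_length=30, n_motifs=5, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_design):
    return d.simulate_true_fitness(small_design, seed=8)


@pytest.fixture(scope="session")
def small_counts(small_design, small_truth):
    model = d.SortModel(reads_per_gate=20_000, cells_per_gate=8_000,
                        replicates=2, dropout_rate=0.05)
    return d.simulate_sort_counts(small_design, small_truth, model, seed=9)


@pytest.fixture(scope="session")
def helix_chain():
    """A 10-bead helical chain: linear topology, genuinely 3-D geometry."""
    t = np.arange(10, dtype=float)
    return np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * t], axis=1)


@pytest.fixture(scope="session")
def compact_cluster():
    rng = np.random.default_rng(0)
    return rng.normal(0.0, 3.0, size=(12, 3))


@pytest.fixture(scope="session")
def planted_fitness():
    """A planted 3-class fitness matrix with its true position classes."""
    design = d.make_design(seed=1)
    truth = d.simulate_true_fitness(design, seed=2)
    matrix = truth.fitness_true.drop(columns=[design.control_motif_id])
    labels = pd.Series({p: truth.position_class[p] for p in matrix.index})
    return matrix, labels
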