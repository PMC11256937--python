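import numpy as np
import pytest

from adaclust.io_preprocess import CountMatrix
from adaclust.synthetic import SimulationRecipe, simulate_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(2.0, size=(8, 5))
    return CountMatrix(counts.astype(np.int64),
                       cell_ids=[f"c{i}" for i in range(8)],
                       gene_ids=[f"g{j}" for j in range(5)])


@pytest.fixture
def small_clustered():
    recipe = SimulationRecipe(n_cells=300, n_genes=120, K=3, fold_change=8.0,
                              de_fraction=0.15, seed=7)
    return simulate_counts(recipe)
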