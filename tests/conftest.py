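import numpy as np
import pytest

from ecoregions import (
    PreprocessConfig,
    SyntheticLandscapeSpec,
    generate_landscape,
    pca_reduce,
    preprocess_features,
)
from ecoregions.synth import lattice_graph


@pytest.fixture(scope="session")
def quadrant_landscape():
    """20x20 rook lattice, 4 planted quadrant regions, 5 features, effect 3."""
    spec = SyntheticLandscapeSpec(rows=20, cols=20, k_true=4, n_features=5,
                                  effect_size=3.0, noise_sd=1.0,
                                  region_shape="blocks", seed=42)
    table, graph, truth = generate_landscape(spec)
    return table, graph, truth


@pytest.fixture(scope="session")
def quadrant_embedding(quadrant_landscape):
    table, graph, _ = quadrant_landscape
    clean = preprocess_features(table, graph, PreprocessConfig())
    return clean, pca_reduce(clean, PreprocessConfig())


@pytest.fixture(scope="session")
def grown_landscape():
    """20x20 lattice with 6 irregular contiguous regions and 12 themed features."""
    spec = SyntheticLandscapeSpec(rows=20, cols=20, k_true=6, n_features=12,
                                  effect_size=3.0, noise_sd=1.0, seed=11)
    return generate_landscape(spec)


@pytest.fixture
def path_graph():
    """6-node path a0-a1-...-a5."""
    from ecoregions import AdjacencyGraph

    ids = [f"a{i}" for i in range(6)]
    g = AdjacencyGraph(unit_ids=ids)
    for i in range(5):
        g.add_edge(ids[i], ids[i + 1])
    return g


@pytest.fixture
def small_lattice():
    return lattice_graph(5, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
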