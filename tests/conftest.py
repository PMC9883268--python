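import numpy as np
import pytest

import golsa as G


@pytest.fixture(scope="session")
def square_graph():
    return G.build_square_map()


@pytest.fixture(scope="session")
def trained_square(square_graph):
    """Square-map model trained by random exploration to full coverage."""
    return G.train_by_exploration(square_graph, 500, seed=11)


@pytest.fixture(scope="session")
def pattern_sets(trained_square):
    """Condition patterns for all layers (few repetitions, fixed seed)."""
    return G.build_condition_patterns(trained_square, n_reps=2, seed=7)


@pytest.fixture(scope="session")
def layer_rdms(pattern_sets):
    return {layer: G.compute_rdm(ps) for layer, ps in pattern_sets.items()}
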