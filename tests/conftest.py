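import numpy as np
import pytest

from topobind.tda.rips import PersistenceDiagram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_diagram(dim_pairs: dict[int, list[tuple[float, float]]],
                 max_radius: float = 10.0) -> PersistenceDiagram:
    """Build a diagram container directly from (birth, death) lists."""
    diagrams = {dim: np.array(pairs, dtype=float).reshape(-1, 2)
                for dim, pairs in dim_pairs.items()}
    return PersistenceDiagram(diagrams=diagrams, max_dim=max(dim_pairs),
                              max_radius=max_radius,
                              n_points=0)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
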