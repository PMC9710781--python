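import numpy as np
import pytest

from bioesn import Connectome, generate_synthetic_connectome


@pytest.fixture
def toy_connectome() -> Connectome:
    """3 areas, 3 links with distinct strengths (a->b: 5, b->c: 1, c->a: 3)."""
    w = np.array([
        [0.0, 5.0, 0.0],
        [0.0, 0.0, 1.0],
        [3.0, 0.0, 0.0],
    ])
    return Connectome(w, labels=("a", "b", "c"))


@pytest.fixture
def modular_connectome() -> Connectome:
    """Strongly modular 30-area synthetic connectome (desk-scale standard)."""
    return generate_synthetic_connectome(30, 3, 0.3, seed=11)


@pytest.fixture
def small_connectome() -> Connectome:
    return generate_synthetic_connectome(10, 2, 0.4, seed=7)
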