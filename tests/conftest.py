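import numpy as np
import pytest
from hypothesis import settings

from fcmdss.fcm_core import ConceptGraph, ReasoningConfig
from fcmdss.synthdata import worked_example

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def example():
    """The packaged three-concept illustration."""
    return worked_example()


@pytest.fixture
def free_config():
    return ReasoningConfig(mode="free", tol=1e-10, max_iter=500)


def random_contractive_graph(n: int, rng: np.random.Generator) -> ConceptGraph:
    """Dense random graph with spectral norm scaled below the contraction
    bound 4 (for steepness 1)."""
    w = rng.uniform(-1.0, 1.0, (n, n))
    w *= 0.8 / max(np.linalg.norm(w, 2), 1e-9)  # factor = w_norm / 4 < 1
    return ConceptGraph(
        names=[f"c{i}" for i in range(n)],
        mask=np.ones((n, n)),
        weights=w,
    )
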