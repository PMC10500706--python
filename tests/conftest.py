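import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_orientations(rng, n):
    """Uniform crystallite Euler triples for oracle comparisons."""
    return np.column_stack(
        [
            rng.uniform(0.0, 2.0 * np.pi, n),
            np.arccos(rng.uniform(-1.0, 1.0, n)),
            rng.uniform(0.0, 2.0 * np.pi, n),
        ]
    )
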