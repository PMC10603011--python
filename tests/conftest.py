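import numpy as np
import pytest

from entrobound import AbundanceVector


@pytest.fixture
def rng():
    return np.random.default_rng(20230501)


@pytest.fixture
def random_vectors(rng):
    """200 Dirichlet communities of assorted richness for property checks."""
    out = []
    for _ in range(200):
        n = int(rng.integers(2, 30))
        conc = float(rng.choice([0.2, 1.0, 5.0]))
        out.append(AbundanceVector(rng.dirichlet(np.full(n, conc)),
                                   renormalize=True))
    return out
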