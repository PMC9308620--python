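import numpy as np
import pytest

from siphtool import PHRepresentation, make_intensity, make_scaling
from siphtool.univariate import SIPHModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240717)


@pytest.fixture
def ph3():
    """A fixed, well-conditioned 3-phase representation."""
    return PHRepresentation(
        [0.4, 0.35, 0.25],
        [[-1.2, 0.4, 0.2], [0.3, -2.0, 0.6], [0.1, 0.5, -1.5]],
    )


@pytest.fixture
def ph2():
    return PHRepresentation([0.7, 0.3], [[-1.0, 0.4], [0.2, -2.5]])


@pytest.fixture
def burr_model(ph3):
    """Matrix-Burr: gamma scaling with a Weibull time transform."""
    return SIPHModel(ph3, make_intensity("weibull", (1.5,)),
                     make_scaling("gamma", (2.0,)))


def random_subintensity(rng, p):
    """Random dense sub-intensity with exits from every state."""
    T = rng.uniform(0.1, 1.0, (p, p))
    np.fill_diagonal(T, 0.0)
    ex = rng.uniform(0.2, 1.0, p)
    for k in range(p):
        T[k, k] = -(T[k].sum() + ex[k])
    return T
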