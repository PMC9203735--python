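import numpy as np
import pytest

from effconn.graphs import CausalGraph


@pytest.fixture
def bivariate_chain() -> CausalGraph:
    """VAR(1) with a single directed edge ch0 -> ch1 of weight 0.5."""
    a = np.zeros((1, 2, 2))
    a[0, 1, 0] = 0.5
    return CausalGraph(a, np.ones(2))


@pytest.fixture
def ar1_independent_4ch() -> CausalGraph:
    """Four mutually independent AR(1) channels (null connectivity)."""
    a = np.zeros((1, 4, 4))
    np.fill_diagonal(a[0], 0.5)
    return CausalGraph(a, np.ones(4))
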