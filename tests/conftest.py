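import numpy as np
import pytest

from selfassembly.lattice import build_geometry


@pytest.fixture
def ring8():
    return build_geometry(1, 8)


@pytest.fixture
def sheet3():
    return build_geometry(2, 3)


@pytest.fixture
def cube3():
    return build_geometry(3, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
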