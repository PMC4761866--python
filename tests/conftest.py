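import io

import numpy as np
import pytest

from isohome import vendored_coefficients_path
from isohome.geomag import (GaussCoefficientSeries, GaussCoefficientSet,
                            read_coefficients)


def make_dipole_set(g10=-30000.0, epoch=2000.0):
    g = np.zeros((2, 2))
    g[1, 0] = g10
    return GaussCoefficientSet(epoch, g, np.zeros((2, 2)))


@pytest.fixture(scope="session")
def dipole_set():
    return make_dipole_set()


@pytest.fixture(scope="session")
def dipole_series():
    return GaussCoefficientSeries([make_dipole_set(epoch=2000.0)])


@pytest.fixture(scope="session")
def degree3_set():
    """Random degree-3 coefficient set, frozen by seed."""
    rng = np.random.default_rng(42)
    g = np.zeros((4, 4))
    h = np.zeros((4, 4))
    for n in range(1, 4):
        for m in range(0, n + 1):
            g[n, m] = rng.uniform(-5000, 5000)
            if m > 0:
                h[n, m] = rng.uniform(-5000, 5000)
    g[1, 0] = -28000.0  # keep a dominant Earth-like dipole
    return GaussCoefficientSet(2000.0, g, h)


@pytest.fixture(scope="session")
def degree3_series(degree3_set):
    return GaussCoefficientSeries([degree3_set])


@pytest.fixture(scope="session")
def vendored_series():
    return read_coefficients(str(vendored_coefficients_path()))


TWO_EPOCH_TABLE = """\
# two-epoch dipole-only fixture
g/h n m 1900.0 1905.0
g 1 0 -30000 -29000
"""


@pytest.fixture()
def two_epoch_series():
    return read_coefficients(io.StringIO(TWO_EPOCH_TABLE))
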