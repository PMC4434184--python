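import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracle importable

from nucbend import BendingGeometry, EnergyModel, build_param_table


@pytest.fixture(scope="session")
def table():
    return build_param_table()


@pytest.fixture(scope="session")
def geom():
    return BendingGeometry()


@pytest.fixture(scope="session")
def model(table, geom):
    return EnergyModel(table, geom)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_window(rng, length=129):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def random_windows(rng):
    """Factory: n random windows of the given length."""

    def make(n, length=129):
        return [random_window(rng, length) for _ in range(n)]

    return make
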