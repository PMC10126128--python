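import numpy as np
import pytest

from dnarom.fixtures import default_iv_tables
from dnarom.transport import IVTable


@pytest.fixture(scope="session")
def iv_tables():
    """Default surrogate I-V table pair (generated once per session)."""
    return default_iv_tables()


def linear_iv_table(resistance: float, species: str = "linear") -> IVTable:
    """Ohmic I-V table (delta-independent), for crossbar unit tests."""
    bias = np.linspace(0.0, 1.0, 5)
    delta = np.array([0.0, 0.25])
    current = np.repeat((bias / resistance)[:, None], 2, axis=1)
    return IVTable(
        species=species,
        bias_grid=bias,
        delta_grid=delta,
        current=current,
        e_f_anchor=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
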