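import numpy as np
import pytest

from skyshine.transport import _XsPack
from skyshine.xsdata import MaterialTable, load_material


def absorber_tables(air_density=1.225e-3):
    """Tables with every interaction moved to the photoelectric channel
    (pure absorber media for attenuation-law tests)."""

    def absorb(t):
        return MaterialTable(t.material, t.energy_grid, t.mu_total,
                             np.zeros_like(t.mu_total),
                             np.zeros_like(t.mu_total), t.muen_over_rho)

    return _XsPack(absorb(load_material("air", density=air_density)),
                   absorb(load_material("concrete")))


@pytest.fixture(scope="session")
def air_table():
    return load_material("air")


@pytest.fixture(scope="session")
def concrete_table():
    return load_material("concrete")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
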