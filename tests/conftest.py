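import numpy as np
import pytest

from lipas.lipid_models import make_topology
from lipas.mc_ensemble import EnergyModel


@pytest.fixture(scope="session")
def default_model():
    return EnergyModel()


@pytest.fixture(scope="session")
def torsion_only_model():
    """Energy model with the LJ term disabled (pair list empty): the
    Boltzmann distribution factorizes over torsions, which makes exact
    enumeration oracles tractable."""
    return EnergyModel(min_bond_separation=99)


@pytest.fixture(scope="session")
def toy_hexane():
    """6-carbon saturated chain: 3 rotatable torsions."""
    return make_topology({"n_carbons": 6, "name": "toy-hexane"})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
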