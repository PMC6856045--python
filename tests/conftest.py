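import numpy as np
import pytest

from esim.chem import ConformerEnsemble
from esim.fixtures import build_panel
from esim.observers import place_observers


@pytest.fixture(scope="session")
def panel():
    return build_panel(seed=1)


@pytest.fixture(scope="session")
def pyrrolidone(panel):
    return panel["2-pyrrolidone"]


@pytest.fixture(scope="session")
def obs_pyrrolidone(pyrrolidone):
    return place_observers(pyrrolidone, spacing=2.0)


def single_conf(mol):
    return ConformerEnsemble(mol, [mol.coords.copy()], np.zeros(1))
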