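import numpy as np
import pytest

from smilesga.fixtures import REGISTRY
from smilesga.genetic_operators import OperatorConfig
from smilesga.molgraph import parse_smiles

ASPIRIN = REGISTRY["aspirin"].smiles
SIMEPREVIR = REGISTRY["simeprevir"].smiles


@pytest.fixture
def aspirin():
    return parse_smiles(ASPIRIN)


@pytest.fixture
def simeprevir():
    return parse_smiles(SIMEPREVIR)


@pytest.fixture
def op_config():
    return OperatorConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
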