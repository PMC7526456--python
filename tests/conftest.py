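import numpy as np
import pytest
from hypothesis import settings

from neosurf.epitopes import make_mep
from neosurf.structure import Atom
from neosurf.synthetic import GrooveSpec, make_groove_complex

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def groove_fixture():
    """One toy-groove complex with mixed up/down pattern and its labels."""
    seq, pattern = "LSCLNWSTL", "uududduud"
    s, labels = make_groove_complex(seq, pattern, GrooveSpec(seed=11))
    return s, labels


@pytest.fixture(scope="session")
def mep_44_1():
    return make_mep("44-1", "LSCLNWSTL", 3, "H-2Db")


def make_atom(x, y, z, r=1.7, element="C", name="X"):
    return Atom(name, element, np.array([x, y, z], float), radius=r)


@pytest.fixture
def atom_factory():
    return make_atom
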