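import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from foldability.sequences import ProteinSequence
from foldability.synthetic import make_toy_structure

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def wt6() -> ProteinSequence:
    return ProteinSequence(id="X", residues="MKVLGA")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue helix with a glycine in the middle."""
    seq = "MKVLEAIRKG" + "QWERTYIPSD"
    return make_toy_structure(seq, "H" * 20, seed=11, model_id="helix20")
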