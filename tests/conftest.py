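import pytest

from matepol.genome import generate_toy_mating_genome
from matepol.types import MatingType


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """One toy mating-locus genome fixture shared by the molecular tests."""
    root = tmp_path_factory.mktemp("toy_genome")
    return generate_toy_mating_genome(root, seed=0)


@pytest.fixture
def a1b1():
    return MatingType("A1", "B1")


@pytest.fixture
def a2b2():
    return MatingType("A2", "B2")
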