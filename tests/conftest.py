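import pytest

from clampmap.synthetic import GeneratorSpec, gen_toy_structure


@pytest.fixture(scope="session")
def helix30():
    """30-residue ideal poly-Ala helix used by PRE and SASA tests."""
    return gen_toy_structure(30, "helix")


@pytest.fixture(scope="session")
def helix20():
    return gen_toy_structure(20, "helix")


@pytest.fixture()
def spec():
    """Default generator spec (study conditions) at a fixed seed."""
    return GeneratorSpec(seed=7)
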