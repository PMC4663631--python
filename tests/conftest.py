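import pytest

from mitokaryo import reference


@pytest.fixture(scope="session")
def ancestral():
    return reference.load_ancestral_arrangement()


@pytest.fixture(scope="session")
def elephant():
    return reference.load_elephant_karyotype()


@pytest.fixture(scope="session")
def louse_karyotypes():
    return reference.load_reference_karyotypes()


@pytest.fixture(scope="session")
def louse_tree():
    return reference.load_phthiraptera_tree()
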