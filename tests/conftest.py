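import pytest

from nanodoe import load_reference_design, make_base_sequence, paper_factors


@pytest.fixture(scope="session")
def reference_design():
    """The packaged 25-run design with its published binding energies."""
    return load_reference_design()


@pytest.fixture(scope="session")
def factors():
    return paper_factors()


@pytest.fixture(scope="session")
def base_seq():
    """Synthetic stand-in nanobody sequence (documented wild types at key sites)."""
    return make_base_sequence()
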