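import pytest

from biorsm import antibiotic_design_table, antibiotic_factors


@pytest.fixture(scope="session")
def factors():
    return antibiotic_factors()


@pytest.fixture(scope="session")
def design():
    """The bundled 15-run antibiotic-digestion BBD with observed removals."""
    return antibiotic_design_table()
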