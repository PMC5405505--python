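import pytest

from apricot_gsi import (
    load_marker_panel,
    load_reference,
    load_reference_haplotypes,
    read_germplasm_table,
)
from apricot_gsi.germplasm import load_fixture_path


@pytest.fixture(scope="session")
def germplasm_table():
    return read_germplasm_table(load_fixture_path("table3_germplasm.csv"))


@pytest.fixture(scope="session")
def s_reference():
    return load_reference()


@pytest.fixture(scope="session")
def haplotype_table():
    return load_reference_haplotypes()


@pytest.fixture(scope="session")
def marker_panel():
    return load_marker_panel()
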