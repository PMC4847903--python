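import pytest

from tcchart.reference_data import BIOPSY_CASES, CELL_LINES


@pytest.fixture(scope="session")
def cell_lines():
    return CELL_LINES


@pytest.fixture(scope="session")
def biopsy_cases():
    return BIOPSY_CASES
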