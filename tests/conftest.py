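import pytest

from camsite.chemshift import RandomCoilTable


@pytest.fixture(scope="session")
def rc():
    return RandomCoilTable.wishart()
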