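import pytest

from famex import default_locus


@pytest.fixture(scope="session")
def locus():
    return default_locus()
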