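import pytest

from foodprofiler import load_lexicon, load_threshold_table


@pytest.fixture(scope="session")
def table():
    """Packaged WHO Euro (2015) threshold table."""
    return load_threshold_table()


@pytest.fixture(scope="session")
def lexicon():
    """Packaged sweetener lexicon."""
    return load_lexicon()
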