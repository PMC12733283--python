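import pytest

from cleftvar import fixtures as fx


@pytest.fixture(scope="session")
def final_set():
    """The packaged final annotation grid (variants, profiles, evidence)."""
    return fx.final_variant_set()


@pytest.fixture(scope="session")
def trio_records():
    return fx.table1_trios()
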