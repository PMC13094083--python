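import pytest

from dualcut import OutcomeModel, make_locus


@pytest.fixture(scope="session")
def locus_1kb():
    """1 kbp inter-cut interval with 200 bp margins, fixed seed."""
    return make_locus(interval_bp=1000, margin=200, seed=7)


@pytest.fixture(scope="session")
def default_model():
    return OutcomeModel()
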