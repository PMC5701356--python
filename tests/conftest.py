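import pytest

from clonesift.signature import ScoringParams
from clonesift.simulate import toy_germline


@pytest.fixture
def params() -> ScoringParams:
    """Default scoring: M=2, MM=2, IN=3, 70% length-ratio cutoff."""
    return ScoringParams()


@pytest.fixture(scope="session")
def toy_db():
    """The packaged toy germline (5 V / 4 D / 4 J segments), seed 0."""
    return toy_germline(0)
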