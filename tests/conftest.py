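import pytest

from dlcorrect.seqcore import encode_pair


@pytest.fixture
def enc():
    """Encode a pair of plain strings over their shared inferred alphabet."""

    def _enc(a: str, b: str):
        ea, eb, _ = encode_pair(a, b)
        return ea, eb

    return _enc
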