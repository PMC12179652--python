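import numpy as np
import pytest

from boletax.synthetic_data import LEFT_FLANK, RIGHT_FLANK

# 66-bp ITS2 minisatellite core motif used as the exact-array fixture
CORE_66 = (
    "TTCCCCTAGTAACTGCGAGTGAAGCGGGAAGAGCTCAAATTTCGAATCTGGCGGTCTCTTTGGCCG"
)


@pytest.fixture
def core_66():
    assert len(CORE_66) == 66
    return CORE_66


@pytest.fixture
def flanked():
    """Embed a construct between fixed repeat-free 100-bp flanks."""

    def _embed(insert: str) -> str:
        return LEFT_FLANK + insert + RIGHT_FLANK

    return _embed


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
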