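import pytest

from msapkit.core import BandMatrix, LanePresence


@pytest.fixture
def small_matrix() -> BandMatrix:
    """3 loci x 2 samples covering all four band types for sample S1.

    L1 is present in both lanes of both samples; L2 is HpaII-only in S1;
    L3 is absent from S1 but present in S2, so S1 scores it type IV.
    """
    cells = {
        ("L1", "S1"): LanePresence(1, 1),
        ("L1", "S2"): LanePresence(1, 1),
        ("L2", "S1"): LanePresence(1, 0),
        ("L2", "S2"): LanePresence(0, 1),
        ("L3", "S1"): LanePresence(0, 0),
        ("L3", "S2"): LanePresence(1, 1),
    }
    return BandMatrix(cells=cells)
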