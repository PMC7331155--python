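import pytest

from trudrop.indexes import IndexPair, SampleSheet
from trudrop.simulate import simulate_pool


@pytest.fixture
def trudrop_sheet() -> SampleSheet:
    """The two published TruDrop NovaSeq samples (unique dual indexed)."""
    return SampleSheet(
        [
            IndexPair("Mouse4", "CCGCGGTT", "AGCGCTAG"),
            IndexPair("Mouse5", "TTATAACC", "GATATCGA"),
        ]
    )


@pytest.fixture
def v2_sheet() -> SampleSheet:
    """Two published single-indexed V2 samples (6-base i7, same run)."""
    return SampleSheet(
        [
            IndexPair("Mouse4", "CTTGTA"),
            IndexPair("Mouse5", "GTGAAA"),
        ]
    )


@pytest.fixture(scope="session")
def hopped_sim():
    """A small fixed-seed dual-indexed pool with hopping, shared across
    tests (sheet, reads)."""
    sheet = SampleSheet(
        [
            IndexPair("Mouse4", "CCGCGGTT", "AGCGCTAG"),
            IndexPair("Mouse5", "TTATAACC", "GATATCGA"),
        ]
    )
    reads = simulate_pool(
        sheet,
        "TRUDROP",
        reads_per_sample=5000,
        hop_rate=0.0485,
        seed=11,
        read_lengths=(50, 60),
    )
    return sheet, reads
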