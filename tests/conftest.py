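import pytest

from asmscope.allele_methylation import BisRead
from asmscope.core_model import SnpVariant, Thresholds


@pytest.fixture
def th() -> Thresholds:
    return Thresholds()


@pytest.fixture
def snp_ag() -> SnpVariant:
    return SnpVariant("rs1", "chr1", 1005, "A", "G", het_freq=0.4)


def make_read(
    snp_base: str = "A",
    pattern: str = "MMUU",
    sample_id: str = "s1",
    amplicon_id: str = "amp1",
    snp_id: str = "rs1",
    start_pos: int = 1010,
    tissue: str = "PBL",
) -> BisRead:
    """A phased read whose CpG calls follow a compact M/U/. pattern."""
    return BisRead(
        sample_id=sample_id,
        amplicon_id=amplicon_id,
        tissue=tissue,
        individual_id=sample_id,
        snp_calls={snp_id: snp_base},
        cpg_calls={start_pos + 10 * i: c for i, c in enumerate(pattern)},
    )


@pytest.fixture
def read_factory():
    return make_read
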