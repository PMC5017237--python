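import pytest

from aortapanel import generate_callset, load_fixtures
from aortapanel.panel_model import TranscriptModel


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()


@pytest.fixture(scope="session")
def callset():
    return generate_callset(seed=7)


def make_transcript(
    exons,
    cds_sequence,
    strand="+",
    gene="TOY1",
    chrom="toy",
    cds_start=None,
    cds_end=None,
):
    """Construct a small TranscriptModel for hand-computed checks."""
    return TranscriptModel(
        gene=gene,
        accession=f"{gene}.1",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=exons[0][0] if cds_start is None else cds_start,
        cds_end=exons[-1][1] if cds_end is None else cds_end,
        cds_sequence=cds_sequence,
    )
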