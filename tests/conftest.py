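import numpy as np
import pytest

from steelseq.alignio import AlignedReadRecord, ReferenceGenome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_ref():
    """The worked signature example: A run at positions 6,8,11,13 anchored at 3."""
    return ReferenceGenome({"chr1": "GACATGACAGTACAT"})


def make_record(seq, cigar, chrom="chr1", start=0, quals=None, name="r", **kw):
    if quals == "const30":
        quals = [30] * len(seq)
    return AlignedReadRecord(
        read_name=name, chrom=chrom, start=start, cigar=cigar, seq=seq,
        quals=quals, **kw,
    )


@pytest.fixture
def record_factory():
    return make_record
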