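import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cleandeepseq.read_qc import AlignedReadRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_read(
    qname="frag0",
    chrom="amp1",
    pos=1,
    mapq=60,
    cigar=None,
    seq=None,
    qual=None,
    length=101,
    base="A",
    phred=35,
    is_reverse=False,
    mate_pos=None,
):
    """Factory for a well-formed read with uniform sequence/quality."""
    seq = seq if seq is not None else base * length
    qual = qual if qual is not None else np.full(len(seq), phred)
    return AlignedReadRecord(
        qname=qname,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        cigar=cigar or f"{len(seq)}M",
        seq=seq,
        qual=np.asarray(qual),
        is_reverse=is_reverse,
        mate_chrom=chrom,
        mate_pos=mate_pos or pos,
    )


@pytest.fixture
def read_factory():
    return make_read


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
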