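import numpy as np
import pytest

from idnaseq.fastq_io import ReadPair


def make_pair(
    r1="ACGTACGT",
    r2="TTGGCCAA",
    qv=40,
    barcode="ACGTACGT",
    barcode_qv=40,
    read_id="read1",
    r1_qual=None,
    r2_qual=None,
    index_qual=None,
):
    """Build an in-memory ReadPair with uniform (or explicit) qualities."""
    return ReadPair(
        read_id=read_id,
        r1_seq=r1,
        r1_qual=np.asarray(r1_qual if r1_qual is not None else [qv] * len(r1), dtype=np.int16),
        r2_seq=r2,
        r2_qual=np.asarray(r2_qual if r2_qual is not None else [qv] * len(r2), dtype=np.int16),
        index_seq=barcode,
        index_qual=np.asarray(
            index_qual if index_qual is not None else [barcode_qv] * len(barcode),
            dtype=np.int16,
        ),
    )


@pytest.fixture
def pair_factory():
    return make_pair
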