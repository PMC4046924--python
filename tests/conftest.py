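import numpy as np
import pytest

from condortho.io import BlastHit


def make_hit(query="t1", subject="g1", evalue=1e-50, bits=500.0, qlen=None, **kw):
    """A valid BlastHit with boring alignment fields."""
    fields = dict(
        query_id=query,
        subject_id=subject,
        percent_identity=95.0,
        alignment_length=100,
        mismatches=5,
        gap_opens=0,
        qstart=1,
        qend=100,
        sstart=1,
        send=100,
        evalue=evalue,
        bit_score=bits,
        query_length=qlen,
    )
    fields.update(kw)
    return BlastHit(**fields)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
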