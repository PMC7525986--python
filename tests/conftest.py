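import numpy as np
import pytest

from equimhc.seq_io import CodonAlignment


@pytest.fixture
def make_alignment():
    def _make(seqs, ids=None, **kwargs):
        ids = ids or [f"s{i}" for i in range(len(seqs))]
        return CodonAlignment(ids=ids, seqs=[s.upper() for s in seqs], **kwargs)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
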