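import numpy as np
import pytest

from identiscape.intervals import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out
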