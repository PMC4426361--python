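import numpy as np
import pytest

from dotkit.core_io import SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_genome(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20_000))
    return SeqRecord("chr_test", seq)
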