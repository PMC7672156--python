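import numpy as np
import pytest

from mirsite import MiRNA, Transcript, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_920)


@pytest.fixture
def annotated_transcript():
    """100-nt transcript, CDS 31-90 (60 nt, 20 codons)."""
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGU"), size=100))
    return Transcript("tx-demo", seq, cds_start=31, cds_end=90)


@pytest.fixture
def small_dataset():
    """Default-shaped synthetic dataset, fixed seed."""
    return make_dataset({"seed": 42})


@pytest.fixture
def mirna_factory():
    def make(seq, mid="mir-x"):
        return MiRNA(mid, seq)
    return make
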