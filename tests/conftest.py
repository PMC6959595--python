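import numpy as np
import pytest

from transub.seqio import AMINO_ACIDS, Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_sequence(rng):
    def make(length: int = 120) -> str:
        return "".join(rng.choice(list(AMINO_ACIDS), size=length))

    return make


@pytest.fixture
def toy_alignment():
    """Four-row, eight-column alignment with a hand-set reliability track."""
    return Alignment(
        ids=["s1", "s2", "s3", "s4"],
        seqs=[
            "AC-DEFGH",
            "ACWDE-GH",
            "AC-DEFGY",
            "GC-DEFGH",
        ],
        reliability=[9, 9, 1, 8, 7, 4, 3, 5],
    )
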