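import numpy as np
import pytest
from hypothesis import settings

from readgraph import UniqueReadSet

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def substitute(rng, seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = str(rng.choice([b for b in "ACGT" if b != out[p]]))
    return "".join(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture()
def tiny_reads():
    """Three reads with exactly one pair at distance 1 within [1, 2]."""
    return UniqueReadSet.from_sequences(["ACGT", "ACGA", "TTTT"])


@pytest.fixture(scope="session")
def chain_reads():
    """20 reads each one substitution away from the previous one."""
    gen = np.random.default_rng(5)
    seq = random_sequence(gen, 60)
    chain = [seq]
    pos = gen.choice(60, size=19, replace=False)  # distinct positions:
    for p in pos:                                 # distances stay additive
        seq = substitute(gen, seq, [int(p)])
        chain.append(seq)
    return UniqueReadSet.from_sequences(chain)


def full_dp_distance(s1: str, s2: str) -> int:
    """Independent quadratic-DP Levenshtein oracle via global alignment
    with unit mismatch/gap costs (score = -distance)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(match_score=0, mismatch_score=-1,
                                    open_gap_score=-1, extend_gap_score=-1)
    return round(-aligner.score(s1, s2))
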