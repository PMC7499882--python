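import random

import pytest

from ccdbg.bbf import ExactMembershipFilter


def random_dna(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(0xC0FFEE)


@pytest.fixture
def exact_filter():
    """Factory: error-free filter stand-in over an explicit k-mer set."""

    def make(seqs, k):
        flt = ExactMembershipFilter()
        for s in seqs:
            for i in range(len(s) - k + 1):
                flt.add(s[i : i + k])
        return flt

    return make
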