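import random

import pytest

from minibarc.seqio import GeneAlignment
from minibarc import synthetic as syn


@pytest.fixture
def rng():
    return random.Random(12345)


def random_alignment(rand: random.Random, n=None, L=None,
                     gap_prob=0.05, amb_prob=0.02) -> GeneAlignment:
    """A small random alignment with occasional gaps/ambiguities."""
    n = n or rand.randint(2, 6)
    L = L or rand.randint(4, 50)
    rows = []
    for _ in range(n):
        chars = []
        for _ in range(L):
            u = rand.random()
            if u < gap_prob:
                chars.append("-")
            elif u < gap_prob + amb_prob:
                chars.append(rand.choice("RYN"))
            else:
                chars.append(rand.choice("ACGT"))
        rows.append("".join(chars))
    return GeneAlignment(gene="rand", species_ids=[f"s{i}" for i in range(n)],
                         rows=rows)


@pytest.fixture
def planted_fixture():
    """Deterministic 5-species panel with two planted primer anchors."""
    cfg = syn.default_config(seed=7, n_reads=0)
    records, truth = syn.simulate_panel(cfg)
    return cfg, records, truth
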