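import numpy as np
import pytest

from methylpref.io import LabeledDataset, ProteinRecord
from methylpref.raac import load_scheme


@pytest.fixture(scope="session")
def op11():
    return load_scheme("Op11")


@pytest.fixture(scope="session")
def op20():
    return load_scheme("Op20")


def _random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_records(rng):
    """30 random canonical proteins, lengths 5..60."""
    return [
        ProteinRecord(f"r{i}", _random_protein(rng, int(rng.integers(5, 61))))
        for i in range(30)
    ]


@pytest.fixture()
def separable_dataset():
    """Two classes with disjoint dominant Op11 groups: positives are E/Q/R/K
    rich, negatives G/P rich.  Trivially separable by k=1 composition."""
    rng = np.random.default_rng(7)
    pos_pool, neg_pool = list("EQRK"), list("GP")
    filler = list("ACDFHILMNSTVWY")

    def make(pool, prefix, n=20):
        recs = []
        for i in range(n):
            L = int(rng.integers(60, 120))
            n_sig = int(0.7 * L)
            seq = list(rng.choice(pool, size=n_sig)) + list(
                rng.choice(filler, size=L - n_sig)
            )
            rng.shuffle(seq)
            recs.append(ProteinRecord(f"{prefix}{i}", "".join(seq)))
        return recs

    pos, neg = make(pos_pool, "pos"), make(neg_pool, "neg")
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledDataset(records=pos + neg, labels=labels)
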