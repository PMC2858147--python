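import numpy as np
import pytest

from phylorec import LocusAlignment, dataset_from_alignments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignment(locus, ids, seqs):
    return LocusAlignment.from_sequences(locus, list(ids), list(seqs))


@pytest.fixture
def toy_dataset():
    """Three tiny loci over four strains; strains a and b are identical."""
    loci = [
        make_alignment("l1", "abcd", ["ACGT", "ACGT", "AGGT", "AGGA"]),
        make_alignment("l2", "abcd", ["TTTT", "TTTT", "TTCT", "TACT"]),
        make_alignment("l3", "abcd", ["GGGG", "GGGG", "GGGG", "CGGG"]),
    ]
    return dataset_from_alignments(loci)


def random_alignment(rng, n, length, ids=None, alphabet="ACGT", locus="rand"):
    ids = ids or [f"t{i}" for i in range(n)]
    rows = rng.choice(list(alphabet), size=(n, length))
    return make_alignment(locus, ids, ["".join(r) for r in rows])
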