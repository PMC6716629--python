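import numpy as np
import pytest

from bimotif import BipartiteSpec, Placement, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    return BipartiteSpec(l_left=3, l_right=3, gap_min=1, gap_max=2)


def random_records(rng, n, length, with_n=False):
    recs = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if with_n and i == 0:
            pos = int(rng.integers(length))
            seq = seq[:pos] + "N" + seq[pos + 1 :]
        recs.append(SequenceRecord(id=f"s{i}", seq=seq))
    return recs


def random_placements(rng, records, spec):
    out = []
    for i, rec in enumerate(records):
        gap = int(rng.integers(spec.gap_min, spec.gap_max + 1))
        start = int(rng.integers(len(rec) - spec.span(gap) + 1))
        out.append(Placement(seq_index=i, left_start=start, gap=gap))
    return out
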