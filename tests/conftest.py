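import numpy as np
import pytest

from cnetrace.align import PairwiseAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20110104)


def random_alignment_rows(rng, n_ref, max_extra_cols=60):
    """Random gapped alignment rows with n_ref reference bases."""
    bases = "ACGT"
    ref = []
    qry = []
    placed = 0
    while placed < n_ref:
        kind = rng.random()
        if kind < 0.8:  # substitution column
            r = bases[rng.integers(4)]
            q = r if rng.random() < 0.6 else bases[rng.integers(4)]
            ref.append(r)
            qry.append(q)
            placed += 1
        elif kind < 0.9:  # deletion in query
            ref.append(bases[rng.integers(4)])
            qry.append("-")
            placed += 1
        else:  # insertion in query
            if len(ref) - placed < max_extra_cols:
                ref.append("-")
                qry.append(bases[rng.integers(4)])
    return "".join(ref), "".join(qry)


def make_alignment(ref_row, qry_row, ref="refsp", qry="qrysp"):
    return PairwiseAlignment(ref, qry, ref_row, qry_row, score=0.0)
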