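import numpy as np
import pytest

from cladebarcode import Alignment
from cladebarcode.msa import NUCLEOTIDES


def random_alignment(
    seed: int,
    n_samples: int = 12,
    length: int = 60,
    p_mut: float = 0.1,
    p_missing: float = 0.05,
) -> Alignment:
    """Unstructured random alignment for property tests."""
    rng = np.random.default_rng(seed)
    anc = rng.integers(4, size=length)
    arr = np.empty((n_samples, length), dtype="U1")
    for j, b in enumerate(anc):
        arr[:, j] = NUCLEOTIDES[b]
    mut = rng.random((n_samples, length)) < p_mut
    for i, j in zip(*np.nonzero(mut)):
        arr[i, j] = NUCLEOTIDES[rng.integers(4)]
    miss = rng.random((n_samples, length)) < p_missing
    arr[miss] = np.where(rng.random(miss.sum()) < 0.5, "N", "-")
    return Alignment(
        sample_ids=tuple(f"s{i}" for i in range(n_samples)),
        rows=tuple("".join(r) for r in arr),
    )


@pytest.fixture
def aln_from_columns():
    """Build an alignment by stacking explicit column strings."""

    def build(*columns: str) -> Alignment:
        n = len(columns[0])
        assert all(len(c) == n for c in columns)
        rows = tuple("".join(col[i] for col in columns) for i in range(n))
        return Alignment(
            sample_ids=tuple(f"s{i}" for i in range(n)), rows=rows
        )

    return build
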