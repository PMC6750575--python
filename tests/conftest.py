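import numpy as np
import pytest

from riverpg.genotypes import GenotypeTable


def make_table(calls, site_of=None, loci=None, group_of=None):
    """Build a GenotypeTable from a nested list of (a, b) calls per sample."""
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    ids = [f"s{i + 1}" for i in range(n)]
    loci = loci or [f"L{l + 1}" for l in range(L)]
    site_of = site_of or {i: "pop1" for i in ids}
    if isinstance(site_of, list):
        site_of = dict(zip(ids, site_of))
    return GenotypeTable(ids, loci, calls, site_of, group_of)


@pytest.fixture
def toy_table():
    """4 diploids, 1 locus: calls (1,2),(1,1),(2,2),(1,2) -> p = {1:.5, 2:.5}."""
    return make_table([[[1, 2]], [[1, 1]], [[2, 2]], [[1, 2]]])


@pytest.fixture
def two_pop_fixed():
    """Two sites of 6, fixed for different alleles at 2 loci."""
    a = np.full((6, 2, 2), 1)
    b = np.full((6, 2, 2), 2)
    return make_table(np.concatenate([a, b]), ["A"] * 6 + ["B"] * 6)


def random_symmetric(n, rng):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
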