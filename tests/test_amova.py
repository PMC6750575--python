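import itertools

import numpy as np
import pytest

from riverpg.amova import amova
from riverpg.simulate import sample_genotypes

from .conftest import make_table


def brute_force_ss(copies, clusters):
    """SS within clusters from explicit pairwise 0/1 distances."""
    ss = 0.0
    for c in set(clusters):
        members = [a for a, cl in zip(copies, clusters) if cl == c]
        m = len(members)
        d = sum(1 for x, y in itertools.combinations(members, 2) if x != y)
        ss += d / m
    return ss


# 3 populations x 4 individuals x 1 locus worked fixture
FIXTURE_CALLS = [
    [[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]],   # pop A
    [[1, 2]], [[2, 2]], [[2, 2]], [[2, 3]],   # pop B
    [[3, 3]], [[1, 3]], [[3, 3]], [[2, 3]],   # pop C
]
FIXTURE_SITES = ["A"] * 4 + ["B"] * 4 + ["C"] * 4


def test_components_match_brute_force_oracle():
    t = make_table(FIXTURE_CALLS, FIXTURE_SITES)
    hierarchy = {"A": "g1", "B": "g1", "C": "g2"}
    res = amova(t, hierarchy, n_perm=0)

    copies = [a for call in FIXTURE_CALLS for a in call[0]]
    ind = [i for i in range(12) for _ in range(2)]
    pop = [s for s in FIXTURE_SITES for _ in range(2)]
    grp = [hierarchy[p] for p in pop]

    ss_tot = brute_force_ss(copies, [0] * 24)
    ss_wg = brute_force_ss(copies, grp)
    ss_wp = brute_force_ss(copies, pop)
    ss_wi = brute_force_ss(copies, ind)
    assert res.sum_of_squares["within_individuals"] == pytest.approx(ss_wi, abs=1e-9)
    assert res.sum_of_squares["among_individuals_within_populations"] == \
        pytest.approx(ss_wp - ss_wi, abs=1e-9)
    assert res.sum_of_squares["among_populations_within_groups"] == \
        pytest.approx(ss_wg - ss_wp, abs=1e-9)
    assert res.sum_of_squares["among_groups"] == pytest.approx(ss_tot - ss_wg, abs=1e-9)

    # independent component solution from the mean squares
    df_wi, df_ai, df_ap, df_ag = 12, 12 - 3, 3 - 2, 2 - 1
    ms_wi = ss_wi / df_wi
    ms_ai = (ss_wp - ss_wi) / df_ai
    ms_ap = (ss_wg - ss_wp) / df_ap
    ms_ag = (ss_tot - ss_wg) / df_ag
    s2_d = ms_wi
    s2_c = (ms_ai - s2_d) / 2
    # copies per pop = 8, per group: g1 = 16, g2 = 8, total 24
    n_prime = (24 - (64 + 64) / 16 - 64 / 8) / (3 - 2)
    n_dprime = ((64 + 64) / 16 + 64 / 8 - (64 * 3) / 24) / (2 - 1)
    n_tprime = (24 - (16**2 + 8**2) / 24) / (2 - 1)
    s2_b = (ms_ap - s2_d - 2 * s2_c) / n_prime
    s2_a = (ms_ag - s2_d - 2 * s2_c - n_dprime * s2_b) / n_tprime
    got = res.variance_components
    assert got["sigma2_d"] == pytest.approx(s2_d, abs=1e-9)
    assert got["sigma2_c"] == pytest.approx(s2_c, abs=1e-9)
    assert got["sigma2_b"] == pytest.approx(s2_b, abs=1e-9)
    assert got["sigma2_a"] == pytest.approx(s2_a, abs=1e-9)


def test_group_fixed_alleles():
    calls, sites, grp = [], [], {}
    for g, (allele, pops) in enumerate([(1, ["p1", "p2"]), (2, ["p3", "p4"])]):
        for p in pops:
            grp[p] = f"g{g}"
            for _ in range(5):
                calls.append([[allele, allele]])
                sites.append(p)
    res = amova(make_table(calls, sites), grp, n_perm=0)
    assert res.F_CT == 1.0 and res.F_SC == 0.0


def test_percentages_and_nested_identity():
    rng = np.random.default_rng(3)
    parts, sites = [], []
    for p in range(4):
        freqs = rng.dirichlet(np.ones(4) * 2, size=3)
        parts.append(sample_genotypes(freqs, 15, F_IS=0.2, seed=50 + p).calls)
        sites.extend([f"p{p}"] * 15)
    t = make_table(np.concatenate(parts), sites)
    res = amova(t, {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}, n_perm=0)
    assert sum(res.percent_of_total.values()) == pytest.approx(100.0, abs=1e-9)
    lhs = 1 - res.F_IT
    rhs = (1 - res.F_CT) * (1 - res.F_SC) * (1 - res.F_IS)
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_panmictic_null_f_statistics_near_zero():
    vals = []
    for rep in range(20):
        rng = np.random.default_rng(700 + rep)
        freqs = rng.dirichlet(np.ones(5) * 5, size=6)
        parts = [sample_genotypes(freqs, 100, seed=int(rng.integers(2**31))).calls
                 for _ in range(4)]
        sites = [s for p in range(4) for s in [f"p{p}"] * 100]
        t = make_table(np.concatenate(parts), sites)
        res = amova(t, {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}, n_perm=0)
        vals.append((res.F_CT, res.F_SC, res.F_IS))
    means = np.mean(vals, axis=0)
    assert np.all(np.abs(means) < 0.02)


def test_negative_components_not_truncated():
    # panmictic data regularly produces small negative among-group components
    found_negative = False
    for rep in range(10):
        rng = np.random.default_rng(40 + rep)
        freqs = rng.dirichlet(np.ones(4) * 4, size=4)
        parts = [sample_genotypes(freqs, 25, seed=int(rng.integers(2**31))).calls
                 for _ in range(4)]
        sites = [s for p in range(4) for s in [f"p{p}"] * 25]
        t = make_table(np.concatenate(parts), sites)
        res = amova(t, {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}, n_perm=0)
        if res.variance_components["sigma2_a"] < 0:
            found_negative = True
            assert res.percent_of_total["among_groups"] < 0
            assert sum(res.percent_of_total.values()) == pytest.approx(100, abs=1e-9)
    assert found_negative


def test_permutation_p_values():
    rng = np.random.default_rng(8)
    freqs = rng.dirichlet(np.ones(4) * 4, size=3)
    parts = [sample_genotypes(freqs, 15, seed=i).calls for i in range(4)]
    sites = [s for p in range(4) for s in [f"p{p}"] * 15]
    t = make_table(np.concatenate(parts), sites)
    res = amova(t, {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"},
                n_perm=49, seed=1)
    for k in ("F_CT", "F_SC", "F_IS", "F_IT"):
        assert 1 / 50 <= res.p_values[k] <= 1.0


def test_zero_variance_error():
    t = make_table([[[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]]],
                   ["A", "A", "B", "B"])
    with pytest.raises(ValueError, match="zero total variance"):
        amova(t, {"A": "g", "B": "g"}, n_perm=0)


def test_df_accounting():
    t = make_table(FIXTURE_CALLS, FIXTURE_SITES)
    res = amova(t, {"A": "g1", "B": "g1", "C": "g2"}, n_perm=0)
    # per locus: df sum = 2 * (non-missing individuals) - 1
    assert sum(res.df.values()) == 2 * 12 - 1
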