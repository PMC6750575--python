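"""Four-level hierarchical AMOVA on diploid genotypes.

Gene copies are nested as copy < individual < population < group, with the
allele-identity distance (0 for identical labels, 1 otherwise). Sums of
squares follow the usual decomposition of squared distances within nesting
levels; with 0/1 distances every within-cluster SS reduces to allele
counts: ``SS_W(cluster of m copies) = (m^2 - sum_a m_a^2) / (2m)``.

Variance components come from the nested expected-mean-square equations for
unbalanced designs (copies per individual are exactly 2, so the individual-
level coefficient is 2). F-statistic analogues are

    F_CT = s2_a / s2_T            F_SC = s2_b / (s2_b + s2_c + s2_d)
    F_IS = s2_c / (s2_c + s2_d)   F_IT = (s2_a + s2_b + s2_c) / s2_T

which satisfy ``(1 - F_IT) = (1 - F_CT)(1 - F_SC)(1 - F_IS)`` identically.
Components may be negative and are reported unmodified. Missing calls are
dropped per locus (pairwise deletion); per-locus components and degrees of
freedom are summed across loci before forming the F ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeTable

__all__ = ["AmovaResult", "amova"]

_LEVELS = ("among_groups", "among_populations_within_groups",
           "among_individuals_within_populations", "within_individuals")


@dataclass
class AmovaResult:
    df: dict[str, float]
    sum_of_squares: dict[str, float]
    variance_components: dict[str, float]  # keys sigma2_a .. sigma2_d
    percent_of_total: dict[str, float]
    F_CT: float
    F_SC: float
    F_IS: float
    F_IT: float
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    @property
    def total_variance(self) -> float:
        return sum(self.variance_components.values())


def _ss_within(copy_alleles: np.ndarray, cluster_ids: np.ndarray) -> float:
    """Sum over clusters of SS within, for 0/1 allele-identity distance."""
    ss = 0.0
    order = np.argsort(cluster_ids, kind="stable")
    cids = cluster_ids[order]
    vals = copy_alleles[order]
    bounds = np.flatnonzero(np.diff(cids)) + 1
    for grp in np.split(vals, bounds):
        m = grp.shape[0]
        if m == 0:
            continue
        _, counts = np.unique(grp, return_counts=True)
        ss += (m * m - float(np.sum(counts * counts))) / (2.0 * m)
    return ss


def _locus_decomposition(alleles, ind, pop, grp):
    """SS and EMS bookkeeping for one locus.

    ``alleles`` is the flat vector of non-missing gene copies; ``ind``,
    ``pop``, ``grp`` are equal-length integer labels for each copy.
    """
    n_ind = len(np.unique(ind))
    pops = np.unique(pop)
    groups = np.unique(grp)
    P, G = len(pops), len(groups)
    N = alleles.shape[0]  # copies

    ss_tot = _ss_within(alleles, np.zeros_like(ind))
    ss_wg = _ss_within(alleles, grp)
    ss_wp = _ss_within(alleles, pop)
    ss_wi = _ss_within(alleles, ind)

    ss = {
        "among_groups": ss_tot - ss_wg,
        "among_populations_within_groups": ss_wg - ss_wp,
        "among_individuals_within_populations": ss_wp - ss_wi,
        "within_individuals": ss_wi,
    }
    df = {
        "among_groups": G - 1,
        "among_populations_within_groups": P - G,
        "among_individuals_within_populations": n_ind - P,
        "within_individuals": n_ind,
    }

    # unbalanced nested EMS coefficients (units = gene copies)
    pop_sizes = np.array([np.sum(pop == p) for p in pops], dtype=float)
    grp_of_pop = np.array([grp[pop == p][0] for p in pops])
    grp_sizes = np.array([np.sum(grp == g) for g in groups], dtype=float)
    sum_np2_over_ng = 0.0
    for gi, g in enumerate(groups):
        s = pop_sizes[grp_of_pop == g]
        sum_np2_over_ng += float(np.sum(s * s)) / grp_sizes[gi]
    n_prime = ((N - sum_np2_over_ng) / (P - G)) if P > G else 0.0
    n_dprime = ((sum_np2_over_ng - float(np.sum(pop_sizes**2)) / N) / (G - 1)) if G > 1 else 0.0
    n_tprime = ((N - float(np.sum(grp_sizes**2)) / N) / (G - 1)) if G > 1 else 0.0
    return ss, df, n_prime, n_dprime, n_tprime


def _components(ss, df, n_prime, n_dprime, n_tprime):
    ms = {lvl: (ss[lvl] / df[lvl] if df[lvl] > 0 else 0.0) for lvl in _LEVELS}
    s2_d = ms["within_individuals"]
    s2_c = (ms["among_individuals_within_populations"] - s2_d) / 2.0 \
        if df["among_individuals_within_populations"] > 0 else 0.0
    s2_b = (ms["among_populations_within_groups"] - s2_d - 2.0 * s2_c) / n_prime \
        if df["among_populations_within_groups"] > 0 and n_prime > 0 else 0.0
    s2_a = (ms["among_groups"] - s2_d - 2.0 * s2_c - n_dprime * s2_b) / n_tprime \
        if df["among_groups"] > 0 and n_tprime > 0 else 0.0
    return s2_a, s2_b, s2_c, s2_d


def _flatten(t: GenotypeTable, hierarchy: dict[str, str]):
    """Flat per-copy arrays (allele, individual, pop, group) per locus."""
    sites = t.sites
    pop_code = {s: i for i, s in enumerate(sites)}
    grp_labels = {hierarchy[s] for s in sites}
    grp_code = {g: i for i, g in enumerate(sorted(grp_labels))}
    site_idx = t.site_index()
    per_locus = []
    for l in range(t.n_loci):
        col = t.calls[:, l, :]
        nm = col[:, 0] != MISSING
        idx = np.flatnonzero(nm)
        alleles = col[idx].ravel()
        ind = np.repeat(idx, 2)
        pop = np.repeat(site_idx[idx], 2)
        grp = np.array([grp_code[hierarchy[sites[p]]] for p in pop])
        per_locus.append((alleles.astype(np.int64), ind, pop, grp))
    return per_locus


def _amova_stats(per_locus):
    tot_ss = {lvl: 0.0 for lvl in _LEVELS}
    tot_df = {lvl: 0.0 for lvl in _LEVELS}
    comps = np.zeros(4)
    for alleles, ind, pop, grp in per_locus:
        if alleles.size == 0:
            continue
        ss, df, n1, n2, n3 = _locus_decomposition(alleles, ind, pop, grp)
        for lvl in _LEVELS:
            tot_ss[lvl] += ss[lvl]
            tot_df[lvl] += df[lvl]
        comps += np.array(_components(ss, df, n1, n2, n3))
    return tot_ss, tot_df, comps


def _ratio(num: float, den: float) -> float:
    # a zero denominator means no variance below that level: ratio taken as 0
    return num / den if den != 0.0 else 0.0


def _f_stats(comps):
    s2_a, s2_b, s2_c, s2_d = comps
    tot = s2_a + s2_b + s2_c + s2_d
    f_ct = _ratio(s2_a, tot)
    f_sc = _ratio(s2_b, s2_b + s2_c + s2_d)
    f_is = _ratio(s2_c, s2_c + s2_d)
    f_it = _ratio(s2_a + s2_b + s2_c, tot)
    return f_ct, f_sc, f_is, f_it


def amova(t: GenotypeTable, hierarchy: dict[str, str] | None = None,
          n_perm: int = 10_000, seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA with permutation tests.

    Parameters
    ----------
    hierarchy : dict, optional
        Site -> group map. Defaults to ``t.group_of``; with a single group
        the among-groups level is degenerate (df 0).
    n_perm : int
        Permutations per statistic; schemes are populations-among-groups
        (F_CT), individuals-among-populations-within-groups (F_SC), and
        gene-copies-among-individuals-within-populations (F_IS). F_IT is
        tested by permuting copies among individuals across the whole table.
    """
    if hierarchy is None:
        hierarchy = t.group_of or {s: "all" for s in t.sites}
    for s in t.sites:
        if s not in hierarchy:
            raise ValueError(f"site {s!r} missing from hierarchy")
    per_locus = _flatten(t, hierarchy)
    tot_ss, tot_df, comps = _amova_stats(per_locus)
    if not np.any(comps):
        raise ValueError("zero total variance: all genotypes identical")
    f_ct, f_sc, f_is, f_it = _f_stats(comps)
    tot = comps.sum()
    pct = {
        "among_groups": 100.0 * comps[0] / tot,
        "among_populations_within_groups": 100.0 * comps[1] / tot,
        "among_individuals_within_populations": 100.0 * comps[2] / tot,
        "within_individuals": 100.0 * comps[3] / tot,
    }
    res = AmovaResult(
        df=tot_df, sum_of_squares=tot_ss,
        variance_components=dict(zip(("sigma2_a", "sigma2_b", "sigma2_c", "sigma2_d"),
                                     comps.tolist())),
        percent_of_total=pct,
        F_CT=f_ct, F_SC=f_sc, F_IS=f_is, F_IT=f_it,
        n_permutations=n_perm,
    )
    if n_perm > 0:
        res.p_values = _permutation_p(t, hierarchy, per_locus,
                                      (f_ct, f_sc, f_is, f_it), n_perm, seed)
    return res


def _permutation_p(t, hierarchy, per_locus, obs, n_perm, seed):
    rng = np.random.default_rng(seed)
    sites = t.sites
    site_idx = t.site_index()
    grp_of_site = [hierarchy[s] for s in sites]
    exceed = {"F_CT": 0, "F_SC": 0, "F_IS": 0, "F_IT": 0}
    n_sites = len(sites)

    for _ in range(n_perm):
        # F_CT: permute whole populations among groups
        perm_groups = [grp_of_site[i] for i in rng.permutation(n_sites)]
        h = dict(zip(sites, perm_groups))
        stats = _f_stats(_amova_stats(_flatten(t, h))[2])
        if stats[0] >= obs[0]:
            exceed["F_CT"] += 1

        # F_SC: permute individuals among populations within each group
        new_site_idx = site_idx.copy()
        for g in set(grp_of_site):
            members = np.flatnonzero(np.isin(site_idx,
                                             [i for i, gg in enumerate(grp_of_site) if gg == g]))
            new_site_idx[members] = new_site_idx[rng.permutation(members)]
        t2 = GenotypeTable(list(t.sample_ids), list(t.locus_ids), t.calls.copy(),
                           {s: sites[new_site_idx[j]] for j, s in enumerate(t.sample_ids)},
                           None)
        stats = _f_stats(_amova_stats(_flatten(t2, hierarchy))[2])
        if stats[1] >= obs[1]:
            exceed["F_SC"] += 1

        # F_IS: permute gene copies among individuals within populations
        stats = _f_stats(_amova_stats(_shuffle_copies(per_locus, rng, within="pop"))[2])
        if stats[2] >= obs[2]:
            exceed["F_IS"] += 1

        # F_IT: permute gene copies among all individuals
        stats = _f_stats(_amova_stats(_shuffle_copies(per_locus, rng, within="all"))[2])
        if stats[3] >= obs[3]:
            exceed["F_IT"] += 1

    return {k: (v + 1) / (n_perm + 1) for k, v in exceed.items()}


def _shuffle_copies(per_locus, rng, within="pop"):
    out = []
    for alleles, ind, pop, grp in per_locus:
        new_alleles = alleles.copy()
        if within == "pop":
            for p in np.unique(pop):
                sel = np.flatnonzero(pop == p)
                new_alleles[sel] = new_alleles[rng.permutation(sel)]
        else:
            rng.shuffle(new_alleles)
        out.append((new_alleles, ind, pop, grp))
    return out
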