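"""Synthetic data with the statistical structure of an Amazonian
riverine microsatellite study: 8 loci typed over 9 sites of 20-76
mosquitoes, low-to-moderate site differentiation, appreciable inbreeding,
heavy three-way ancestral admixture, and a hub-and-spoke transport network
centred on one river city.

Differentiation uses the Balding-Nichols model: site allele frequencies are
Dirichlet draws around an ancestral vector with concentration
``(1-F)/F``, so ``Var(p_site) = p(1-p)F`` and pairwise F_ST is recoverable
at scale ``F``. Inbreeding is a mixture: with probability ``F_IS`` an
individual's two copies are identical by descent (one draw duplicated),
else two independent draws. Admixed tables mirror the uncorrelated-
frequencies admixture model itself: ``q_i ~ Dirichlet(alpha 1_K)``, each
copy picks a cluster from ``q_i`` then an allele from that cluster's
frequencies. All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, FragmentPanel, GenotypeTable
from .transport import DEFAULT_GAMMAS, SiteGeography, TransportNetwork

__all__ = [
    "SimulationSpec",
    "balding_nichols_frequencies",
    "sample_genotypes",
    "sample_family_genotypes",
    "simulate_admixed_table",
    "simulate_study_region",
    "simulate_fragment_panel",
    "simulate_study_genotypes",
    "STUDY_SITE_SIZES",
]

#: Site sample sizes of the emulated field design (9 sampling locations).
STUDY_SITE_SIZES = {
    "BarrioFlorida": 31, "Aucayo": 20, "IndianaMazan": 32, "Nauta": 55,
    "Tamshiaco": 76, "IquitosA": 21, "IquitosB": 40, "IquitosC": 35,
    "IquitosD": 29,
}


@dataclass
class SimulationSpec:
    """Study conditions for the end-to-end synthetic dataset."""

    n_sites: int = 9
    n_per_site: dict[str, int] = field(default_factory=lambda: dict(STUDY_SITE_SIZES))
    n_loci: int = 8
    n_alleles_per_locus: int = 5
    F: float = 0.05          # Balding-Nichols differentiation
    F_IS: float = 0.2        # within-site inbreeding
    K: int | None = None     # set for admixture-model generation instead of F
    alpha: float = 1.0
    household_clustering: bool = False  # sample siblings in triplets
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ValueError("F must be in (0, 1)")
        if not (0.0 <= self.F_IS < 1.0):
            raise ValueError("F_IS must be in [0, 1)")
        if any(v <= 0 for v in self.n_per_site.values()) or self.n_loci <= 0:
            raise ValueError("counts must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def balding_nichols_frequencies(ancestral: np.ndarray, F: float, n_sites: int,
                                seed: int | None = None) -> np.ndarray:
    """Per-site allele frequency vectors around an ancestral vector.

    Each site is a Dirichlet draw with parameter ``ancestral * (1-F)/F``;
    expected pairwise F_ST between sites is approximately ``F``.
    """
    ancestral = np.asarray(ancestral, dtype=float)
    if not np.isclose(ancestral.sum(), 1.0):
        raise ValueError("ancestral frequencies must sum to 1")
    if not (0.0 < F < 1.0):
        raise ValueError("F must be in (0, 1)")
    if np.count_nonzero(ancestral) < 2:
        import warnings

        warnings.warn("degenerate ancestral vector: returning it unchanged")
        return np.tile(ancestral, (n_sites, 1))
    rng = np.random.default_rng(seed)
    conc = ancestral * (1.0 - F) / F
    return rng.dirichlet(conc, size=n_sites)


def sample_genotypes(freqs: np.ndarray, n_individuals: int, F_IS: float = 0.0,
                     seed: int | None = None,
                     site: str = "pop1", locus_prefix: str = "L",
                     sample_prefix: str = "s") -> GenotypeTable:
    """Draw diploid genotypes at ``L`` loci from per-locus frequencies.

    ``freqs`` is (L, A). With probability ``F_IS`` an individual's call at a
    locus is one allele draw duplicated (identical by descent), else two
    independent draws — so observed heterozygosity shrinks by the factor
    ``1 - F_IS`` relative to random mating.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    if not (0.0 <= F_IS < 1.0):
        raise ValueError("F_IS must be in [0, 1)")
    rng = np.random.default_rng(seed)
    L, A = freqs.shape
    calls = np.zeros((n_individuals, L, 2), dtype=np.int32)
    for l in range(L):
        cum = np.cumsum(freqs[l])
        cum /= cum[-1]
        a1 = np.searchsorted(cum, rng.random(n_individuals)) + 1
        a2 = np.searchsorted(cum, rng.random(n_individuals)) + 1
        ibd = rng.random(n_individuals) < F_IS
        a2[ibd] = a1[ibd]
        calls[:, l, 0] = a1
        calls[:, l, 1] = a2
    ids = [f"{sample_prefix}{i + 1}" for i in range(n_individuals)]
    loci = [f"{locus_prefix}{l + 1}" for l in range(L)]
    return GenotypeTable(ids, loci, calls, {i: site for i in ids})


def sample_family_genotypes(freqs: np.ndarray, n_individuals: int,
                            F_IS: float = 0.0, family_size: int = 3,
                            seed: int | None = None, site: str = "pop1",
                            sample_prefix: str = "s") -> GenotypeTable:
    """Household-clustered sampling: siblings share two drawn parents.

    Emulates collecting up to ``family_size`` mosquitoes per household:
    for each family two parents are drawn from the site's allele
    frequencies (with inbreeding ``F_IS``), and each collected individual
    is an offspring receiving one allele from each parent. Elevates
    within-site relatedness relative to independent sampling.
    """
    rng = np.random.default_rng(seed)
    out = []
    remaining = n_individuals
    fam_seed = lambda: int(rng.integers(2**31 - 1))  # noqa: E731
    while remaining > 0:
        k = min(family_size, remaining)
        parents = sample_genotypes(freqs, 2, F_IS, seed=fam_seed(), site=site)
        pc = parents.calls  # (2, L, 2)
        L = pc.shape[1]
        cols = np.arange(L)[None, :]
        a = pc[0, cols, rng.integers(0, 2, size=(k, L))]
        b = pc[1, cols, rng.integers(0, 2, size=(k, L))]
        out.append(np.sort(np.stack([a, b], axis=2).astype(np.int32), axis=2))
        remaining -= k
    calls = np.concatenate(out)[:n_individuals]
    ids = [f"{sample_prefix}{i + 1}" for i in range(n_individuals)]
    loci = [f"L{l + 1}" for l in range(freqs.shape[0])]
    return GenotypeTable(ids, loci, calls, {i: site for i in ids})


def simulate_study_genotypes(spec: SimulationSpec) -> GenotypeTable:
    """Multi-site table under Balding-Nichols differentiation + inbreeding."""
    rng = np.random.default_rng(spec.seed)
    sites = list(spec.n_per_site)[: spec.n_sites]
    A = spec.n_alleles_per_locus
    tables = []
    for l in range(spec.n_loci):
        anc = rng.dirichlet(np.full(A, 5.0))
        site_freqs = balding_nichols_frequencies(
            anc, spec.F, len(sites), seed=int(rng.integers(2**31 - 1)))
        tables.append(site_freqs)  # (n_sites, A)
    calls = []
    ids: list[str] = []
    site_of: dict[str, str] = {}
    for si, site in enumerate(sites):
        n = spec.n_per_site[site]
        freqs = np.stack([tables[l][si] for l in range(spec.n_loci)])
        sampler = sample_family_genotypes if spec.household_clustering \
            else sample_genotypes
        sub = sampler(freqs, n, spec.F_IS,
                      seed=int(rng.integers(2**31 - 1)),
                      site=site, sample_prefix=f"{site}_")
        calls.append(sub.calls)
        ids.extend(sub.sample_ids)
        site_of.update(sub.site_of)
    loci = [f"L{l + 1}" for l in range(spec.n_loci)]
    group_of = {s: ("Iquitos" if s.startswith("Iquitos") else s) for s in sites}
    return GenotypeTable(ids, loci, np.concatenate(calls), site_of, group_of)


def simulate_admixed_table(K: int, alpha: float, cluster_freqs: np.ndarray,
                           n_individuals: int, seed: int | None = None,
                           site_of: list[str] | None = None) -> tuple[GenotypeTable, np.ndarray]:
    """Generate genotypes from the admixture model; returns (table, true Q).

    ``cluster_freqs`` is (L, K, A) with valid simplexes along the allele
    axis. ``q_i ~ Dirichlet(alpha 1_K)``; each allele copy picks cluster k
    with probability ``q_ik`` then an allele from ``cluster_freqs[l, k]``.
    """
    cluster_freqs = np.asarray(cluster_freqs, dtype=float)
    L, K2, A = cluster_freqs.shape
    if K2 != K:
        raise ValueError("cluster_freqs K axis mismatch")
    if not np.allclose(cluster_freqs.sum(axis=2), 1.0, atol=1e-9):
        raise ValueError("cluster frequencies must sum to 1 per (locus, cluster)")
    rng = np.random.default_rng(seed)
    q = rng.dirichlet(np.full(K, alpha), size=n_individuals)
    calls = np.zeros((n_individuals, L, 2), dtype=np.int32)
    cum_q = np.cumsum(q, axis=1)
    for copy in range(2):
        for l in range(L):
            # each allele copy picks its ancestral cluster independently
            z = (rng.random((n_individuals, 1)) >= cum_q).sum(axis=1)
            cum = np.cumsum(cluster_freqs[l], axis=1)  # (K, A)
            u = rng.random(n_individuals)
            calls[:, l, copy] = (u[:, None] >= cum[z]).sum(axis=1) + 1
    ids = [f"ind{i + 1}" for i in range(n_individuals)]
    if site_of is None:
        site_map = {i: "pop1" for i in ids}
    else:
        site_map = dict(zip(ids, site_of))
    loci = [f"L{l + 1}" for l in range(L)]
    return GenotypeTable(ids, loci, calls, site_map), q


def simulate_study_region(seed: int = 0) -> tuple[list[SiteGeography], TransportNetwork]:
    """Seven river towns with an Iquitos-centred star transport network.

    Pairwise Euclidean distances span roughly 15-125 km; the only
    terrestrial edge is the 95 km Iquitos-Nauta highway; all other links
    are fluvial. Trip counts are concentrated on Iquitos (hub-and-spoke),
    drawn reproducibly from the given seed; infestation probabilities are
    the field rates 0.71 / 0.35 / 0.125 for large barges, medium barges and
    buses.
    """
    rng = np.random.default_rng(seed)
    towns = [
        SiteGeography("Iquitos", 0.0, 0.0, 406_340),
        SiteGeography("Nauta", 0.0, -95.0, 13_983),
        SiteGeography("Tamshiaco", 6.0, -29.0, 4_583),
        SiteGeography("Aucayo", 20.0, -22.0, 806),
        SiteGeography("BarrioFlorida", -15.0, 25.0, 728),
        SiteGeography("Indiana", 8.0, 16.0, 3_300),
        SiteGeography("Mazan", 18.0, 28.0, 3_294),
    ]
    # river winding makes fluvial edges ~1.2-1.4x the straight line
    edges = [
        ("Iquitos", "Tamshiaco", "fluvial", 36.0),
        ("Tamshiaco", "Nauta", "fluvial", 82.0),
        ("Tamshiaco", "Aucayo", "fluvial", 20.0),
        ("Iquitos", "Indiana", "fluvial", 23.0),
        ("Indiana", "Mazan", "fluvial", 20.0),
        ("Iquitos", "BarrioFlorida", "fluvial", 38.0),
        ("Iquitos", "Nauta", "terrestrial", 95.0),
    ]
    spokes = ["Nauta", "Tamshiaco", "Aucayo", "BarrioFlorida", "Indiana", "Mazan"]
    trips: dict[str, dict[tuple[str, str], int]] = {vt: {} for vt in DEFAULT_GAMMAS}
    for town in spokes:
        # busy fluvial corridors get most of the barge traffic
        large = int(rng.integers(0, 12)) if town in ("Tamshiaco", "Indiana", "Mazan") else int(rng.integers(0, 3))
        medium = int(rng.integers(2, 15))
        trips["large_barge"][("Iquitos", town)] = large
        trips["medium_barge"][("Iquitos", town)] = medium
    trips["bus"][("Iquitos", "Nauta")] = int(rng.integers(5, 20))
    net = TransportNetwork([t.site for t in towns], edges,
                           dict(DEFAULT_GAMMAS), trips)
    return towns, net


def simulate_fragment_panel(t: GenotypeTable, motif_length: int = 3,
                            size_noise_sd: float = 0.0, base: float = 100.0,
                            seed: int | None = None) -> FragmentPanel:
    """Inverse of allele binning: fragment = base + label*motif + noise."""
    if size_noise_sd >= motif_length / 4:
        raise ValueError("size_noise_sd must be < motif_length/4")
    rng = np.random.default_rng(seed)
    sizes = base + t.calls.astype(float) * motif_length
    sizes[t.calls == MISSING] = np.nan
    if size_noise_sd > 0:
        sizes = sizes + rng.normal(0.0, size_noise_sd, size=sizes.shape)
    return FragmentPanel(list(t.sample_ids), list(t.locus_ids), sizes,
                         {loc: motif_length for loc in t.locus_ids},
                         dict(t.site_of))
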