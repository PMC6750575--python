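"""Pairwise F_ST (Weir-Cockerham theta) with permutation significance.

Theta is the variance-component estimator of Weir & Cockerham (1984):
per locus and allele the among-population (a), among-individual (b) and
within-individual (c) components are computed from sample sizes, allele
frequencies and heterozygote frequencies; the multilocus estimate is the
ratio of sums, ``theta = sum a / sum (a + b + c)`` over loci and alleles.
Significance comes from shuffling individuals between the two sites
(site sizes fixed); ``p = (#{theta_perm >= theta_obs} + 1)/(n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeTable

__all__ = ["FstMatrix", "pairwise_fst", "wc_theta_pair"]


@dataclass
class FstMatrix:
    labels: list[str]
    theta: np.ndarray  # symmetric, diagonal 0; NaN where undefined
    p: np.ndarray      # permutation p-values; NaN where undefined/untested
    n_permutations: int

    def pair(self, a: str, b: str) -> float:
        return float(self.theta[self.labels.index(a), self.labels.index(b)])


def _encode_pair(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual dosage / het-carrier / non-missing arrays.

    Returns ``D`` (n, L, A) allele dosage, ``Het`` (n, L, A) indicator of a
    heterozygous call carrying the allele, and ``NM`` (n, L) non-missing.
    Allele labels are densified per locus.
    """
    n, L, _ = calls.shape
    A = 0
    codes = np.zeros((n, L, 2), dtype=np.int64)
    for l in range(L):
        col = calls[:, l, :]
        alleles = np.unique(col[col != MISSING])
        A = max(A, len(alleles))
        lut = {int(a): i for i, a in enumerate(alleles)}
        for i, a in enumerate(alleles):
            codes[:, l, :][col == a] = lut[int(a)]
    NM = (calls[:, :, 0] != MISSING)
    D = np.zeros((n, L, A), dtype=np.float64)
    idx_n, idx_l = np.nonzero(NM)
    for copy in range(2):
        np.add.at(D, (idx_n, idx_l, codes[idx_n, idx_l, copy]), 1.0)
    Het = (D == 1.0).astype(np.float64)
    het_call = (calls[:, :, 0] != calls[:, :, 1]) & NM
    Het *= het_call[:, :, None]
    return D, Het, NM.astype(np.float64)


def _theta_from_counts(n1, n2, c1, c2, h1, h2):
    """Vectorized theta for stacked permutations.

    All inputs are (P, L) or (P, L, A); returns (theta (P,), defined (P,)).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)  # need n_bar > 1
        nb = (n1 + n2) / 2.0
        nc = 2.0 * nb - (n1**2 + n2**2) / (2.0 * nb)
        p1 = c1 / (2.0 * n1[..., None])
        p2 = c2 / (2.0 * n2[..., None])
        pbar = (c1 + c2) / (2.0 * (n1 + n2))[..., None]
        s2 = (n1[..., None] * (p1 - pbar) ** 2 + n2[..., None] * (p2 - pbar) ** 2) / nb[..., None]
        hbar = (h1 + h2) / (n1 + n2)[..., None]
        pq = pbar * (1.0 - pbar)
        inner = pq - s2 / 2.0 - hbar / 4.0
        a = (nb / nc)[..., None] * (s2 - inner / (nb - 1.0)[..., None])
        b = (nb / (nb - 1.0))[..., None] * (pq - s2 / 2.0
                                            - ((2.0 * nb - 1.0) / (4.0 * nb))[..., None] * hbar)
        c = hbar / 2.0
        a = np.where(ok[..., None], a, 0.0)
        bc = np.where(ok[..., None], a + b + c, 0.0)
        num = a.sum(axis=(-2, -1))
        den = bc.sum(axis=(-2, -1))
        theta = num / den
    return theta, den != 0.0


def wc_theta_pair(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Multilocus Weir-Cockerham theta for two populations.

    Parameters are ``(n, L, 2)`` call arrays (0 = missing). Returns NaN when
    no locus is informative for the pair.
    """
    D, Het, NM = _encode_pair(np.concatenate([calls_a, calls_b]))
    na = calls_a.shape[0]
    n1 = NM[:na].sum(axis=0)[None, :]
    n2 = NM[na:].sum(axis=0)[None, :]
    c1 = D[:na].sum(axis=0)[None]
    c2 = D[na:].sum(axis=0)[None]
    h1 = Het[:na].sum(axis=0)[None]
    h2 = Het[na:].sum(axis=0)[None]
    theta, ok = _theta_from_counts(n1, n2, c1, c2, h1, h2)
    return float(theta[0]) if ok[0] else float("nan")


def _pair_test(calls_a, calls_b, n_perm, rng, chunk=2048):
    D, Het, NM = _encode_pair(np.concatenate([calls_a, calls_b]))
    n = D.shape[0]
    na = calls_a.shape[0]
    Df = D.reshape(n, -1)
    Hf = Het.reshape(n, -1)
    totD = Df.sum(axis=0)
    totH = Hf.sum(axis=0)
    totN = NM.sum(axis=0)
    L, A = D.shape[1], D.shape[2]

    def theta_for(M):  # M: (P, n) 0/1 membership of pop A
        n1 = M @ NM
        c1 = (M @ Df).reshape(-1, L, A)
        h1 = (M @ Hf).reshape(-1, L, A)
        return _theta_from_counts(n1, totN[None] - n1,
                                  c1, totD.reshape(1, L, A) - c1,
                                  h1, totH.reshape(1, L, A) - h1)

    M_obs = np.zeros((1, n))
    M_obs[0, :na] = 1.0
    theta_obs, ok = theta_for(M_obs)
    if not ok[0]:
        return float("nan"), float("nan")
    t_obs = float(theta_obs[0])
    if n_perm <= 0:
        return t_obs, float("nan")
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        M = np.zeros((m, n))
        for r in range(m):
            M[r, rng.permutation(n)[:na]] = 1.0
        tp, okp = theta_for(M)
        tp = np.where(okp, tp, -np.inf)
        exceed += int(np.sum(tp >= t_obs))
        done += m
    p = (exceed + 1) / (n_perm + 1)
    return t_obs, p


def pairwise_fst(t: GenotypeTable, n_perm: int = 10_000,
                 seed: int | None = None) -> FstMatrix:
    """All pairwise multilocus theta values with permutation p-values."""
    sites = t.sites
    if len(sites) < 2:
        raise ValueError("need >= 2 sites")
    site_idx = t.site_index()
    sizes = np.bincount(site_idx)
    if np.any(sizes < 2):
        small = [sites[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"sites with < 2 individuals: {small}")
    rng = np.random.default_rng(seed)
    k = len(sites)
    theta = np.zeros((k, k))
    p = np.full((k, k), np.nan)
    np.fill_diagonal(p, np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            ca = t.calls[site_idx == i]
            cb = t.calls[site_idx == j]
            th, pv = _pair_test(ca, cb, n_perm, rng)
            theta[i, j] = theta[j, i] = th
            p[i, j] = p[j, i] = pv
    return FstMatrix(sites, theta, p, n_perm)
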