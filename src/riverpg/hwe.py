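"""Exact Hardy-Weinberg tests with enumeration and Markov-chain engines.

The test conditions on the observed allele counts: under random mating every
pairing of the ``2n`` gene copies into ``n`` diploids is equally likely
(Levene), giving the genotype-array probability

    P(array) = [n! / prod n_ij!] * [prod m_i! / (2n)!] * 2^H,

with ``n_ij`` genotype counts, ``m_i`` allele counts and ``H`` heterozygous
individuals. The p-value sums P over arrays no more probable than the
observed one. Small problems are enumerated exactly (rational arithmetic);
larger ones use the Guo-Thompson switch chain, here run on the labelled
allele-copy representation where the stationary law is uniform over pairings
so every between-individual swap is accepted. The hot loop is numba-jitted
when numba is importable, with a pure-python fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .genotypes import GenotypeTable

__all__ = [
    "HweResult",
    "genotype_array_probability",
    "enumerate_arrays",
    "hwe_exact_enumeration",
    "hwe_exact_mcmc",
    "hwe_test",
    "sidak_threshold",
    "apply_sidak",
]

ENUM_MAX_ALLELES = 4
ENUM_MAX_N = 25

_LOG2 = math.log(2.0)


@dataclass
class HweResult:
    site: str
    locus: str
    p_value: float
    engine: str  # "enumeration" | "mcmc"
    mc_se: float
    chain_steps: int
    dememorization_steps: int
    significant_after_sidak: bool | None = None


# ---------------------------------------------------------------------------
# array probability and enumeration
# ---------------------------------------------------------------------------

def _margins(counts: dict[tuple[int, int], int]) -> dict[int, int]:
    m: dict[int, int] = {}
    for (a, b), c in counts.items():
        if c < 0:
            raise ValueError("negative genotype count")
        m[a] = m.get(a, 0) + c
        m[b] = m.get(b, 0) + c
    return m


def genotype_array_probability_exact(counts: dict[tuple[int, int], int]) -> Fraction:
    """Exact rational Levene probability of a genotype array."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty genotype array")
    m = _margins(counts)
    if sum(m.values()) != 2 * n:
        raise ValueError("inconsistent genotype counts")
    h = sum(c for (a, b), c in counts.items() if a != b)
    num = math.factorial(n) * 2**h
    for mi in m.values():
        num *= math.factorial(mi)
    den = math.factorial(2 * n)
    for c in counts.values():
        den *= math.factorial(c)
    return Fraction(num, den)


def genotype_array_probability(counts: dict[tuple[int, int], int]) -> float:
    """Levene/Guo-Thompson conditional probability of a genotype array.

    ``counts`` maps unordered allele pairs ``(a, b)`` with ``a <= b`` to the
    number of individuals with that genotype.
    """
    counts = {(min(a, b), max(a, b)): c for (a, b), c in counts.items()}
    return float(genotype_array_probability_exact(counts))


def enumerate_arrays(allele_counts: dict[int, int]):
    """Yield every genotype array (count dict) with the given allele margins."""
    alleles = sorted(allele_counts)
    if any(c < 0 for c in allele_counts.values()) or sum(allele_counts.values()) % 2:
        raise ValueError("allele counts must be non-negative with even total")
    k = len(alleles)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    rem = [allele_counts[a] for a in alleles]
    current: dict[tuple[int, int], int] = {}

    def rec(pi: int):
        if pi == len(pairs):
            if all(r == 0 for r in rem):
                yield dict(current)
            return
        i, j = pairs[pi]
        # last chance to use up allele i?
        later_uses_i = any(i in p for p in pairs[pi + 1:])
        if i == j:
            hi = rem[i] // 2
        else:
            hi = min(rem[i], rem[j])
        for c in range(hi, -1, -1):
            take = 2 * c if i == j else c
            rem[i] -= take if i == j else c
            if i != j:
                rem[j] -= c
            ok = rem[i] >= 0 and rem[j] >= 0
            if ok and not later_uses_i and rem[i] != 0:
                ok = False
            if ok:
                if c:
                    current[(alleles[i], alleles[j])] = c
                yield from rec(pi + 1)
                current.pop((alleles[i], alleles[j]), None)
            if i == j:
                rem[i] += take
            else:
                rem[i] += c
                rem[j] += c

    yield from rec(0)


def _counts_from_calls(calls: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for a, b in calls:
        key = (int(min(a, b)), int(max(a, b)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def exact_p_enumeration(counts: dict[tuple[int, int], int]) -> float:
    """Exact p-value by full enumeration (rational tie handling)."""
    m = _margins(counts)
    p_obs = genotype_array_probability_exact(counts)
    total = Fraction(0)
    for arr in enumerate_arrays(m):
        p = genotype_array_probability_exact(arr)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def hwe_exact_enumeration(t: GenotypeTable, site: str, locus: str) -> HweResult:
    """Full-enumeration exact HWE test; requires <= 4 alleles and n <= 25."""
    calls = t.calls_at(site, locus)
    counts = _counts_from_calls(calls)
    m = _margins(counts)
    n = sum(counts.values())
    if len(m) > ENUM_MAX_ALLELES or n > ENUM_MAX_N:
        raise ValueError(
            f"enumeration bound exceeded ({len(m)} alleles, n={n}); use the MCMC engine")
    if len(m) < 2:
        return HweResult(site, locus, 1.0, "enumeration", 0.0, 0, 0)
    p = exact_p_enumeration(counts)
    return HweResult(site, locus, p, "enumeration", 0.0, 0, 0)


# ---------------------------------------------------------------------------
# Guo-Thompson switch chain
# ---------------------------------------------------------------------------

def _chain_kernel(x, k, pos, burnin, log_tol):  # pragma: no cover - jitted twin below
    n2 = x.shape[0]
    cnt = np.zeros((k, k), dtype=np.int64)
    s = 0.0
    h = 0
    for i in range(0, n2, 2):
        a, b = x[i], x[i + 1]
        if a > b:
            a, b = b, a
        cnt[a, b] += 1
        if a != b:
            h += 1
    for a in range(k):
        for b in range(a, k):
            c = cnt[a, b]
            for t in range(2, c + 1):
                s -= math.log(t)
    s += h * _LOG2
    s_ref = s + log_tol
    nsteps = pos.shape[0] - burnin
    nb = 50
    bsize = nsteps // nb
    if bsize < 1:
        bsize = 1
    batch_hits = np.zeros(nb, dtype=np.float64)
    hits = 0
    for step in range(pos.shape[0]):
        u = pos[step, 0]
        v = pos[step, 1]
        if (u >> 1) != (v >> 1):
            a = x[u]
            b = x[v]
            if a != b:
                a2 = x[u ^ 1]
                b2 = x[v ^ 1]
                # remove old genotypes
                i1, j1 = (a, a2) if a <= a2 else (a2, a)
                s += math.log(cnt[i1, j1])
                cnt[i1, j1] -= 1
                if i1 != j1:
                    s -= _LOG2
                i2, j2 = (b, b2) if b <= b2 else (b2, b)
                s += math.log(cnt[i2, j2])
                cnt[i2, j2] -= 1
                if i2 != j2:
                    s -= _LOG2
                x[u] = b
                x[v] = a
                i1, j1 = (b, a2) if b <= a2 else (a2, b)
                cnt[i1, j1] += 1
                s -= math.log(cnt[i1, j1])
                if i1 != j1:
                    s += _LOG2
                i2, j2 = (a, b2) if a <= b2 else (b2, a)
                cnt[i2, j2] += 1
                s -= math.log(cnt[i2, j2])
                if i2 != j2:
                    s += _LOG2
        if step >= burnin:
            if s <= s_ref:
                hits += 1
                bi = (step - burnin) // bsize
                if bi < nb:
                    batch_hits[bi] += 1
    return hits, batch_hits, bsize


try:  # optional acceleration
    from numba import njit

    _chain_kernel_jit = njit(cache=True, fastmath=False)(_chain_kernel)
except Exception:  # pragma: no cover
    _chain_kernel_jit = _chain_kernel


def _run_chain(calls: np.ndarray, steps: int, burnin: int, seed) -> tuple[float, float]:
    alleles = np.unique(calls.ravel())
    code = {int(a): i for i, a in enumerate(alleles)}
    k = len(alleles)
    x = np.array([code[int(a)] for a in calls.ravel()], dtype=np.int64)
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, x.shape[0], size=(burnin + steps, 2), dtype=np.int64)
    hits, batch_hits, bsize = _chain_kernel_jit(x, k, pos, burnin, 1e-7)
    p = hits / steps
    bm = batch_hits / bsize
    nb = len(bm)
    mc_se = float(np.std(bm, ddof=1) / math.sqrt(nb)) if nb > 1 else 0.0
    return float(p), mc_se


def exact_p_mcmc(counts: dict[tuple[int, int], int], steps: int = 1_000_000,
                 burnin: int = 100_000, seed: int | None = None) -> tuple[float, float]:
    """Chain p-value and Monte Carlo SE for a genotype-count array."""
    if len(_margins(counts)) < 2:
        return 1.0, 0.0
    calls = np.array([g for g, c in counts.items() for _ in range(c)], dtype=np.int64)
    return _run_chain(calls, steps, burnin, seed)


def hwe_exact_mcmc(t: GenotypeTable, site: str, locus: str,
                   steps: int = 1_000_000, burnin: int = 100_000,
                   seed: int | None = None) -> HweResult:
    """Markov-chain exact HWE test (switch chain, dememorization = burn-in).

    With a fixed ``seed`` the result is bit-identical across runs.
    """
    calls = t.calls_at(site, locus)
    counts = _counts_from_calls(calls)
    if len(_margins(counts)) < 2:
        return HweResult(site, locus, 1.0, "mcmc", 0.0, steps, burnin)
    p, mc_se = _run_chain(calls, steps, burnin, seed)
    return HweResult(site, locus, p, "mcmc", mc_se, steps, burnin)


def hwe_test(t: GenotypeTable, site: str, locus: str,
             steps: int = 1_000_000, burnin: int = 100_000,
             seed: int | None = None) -> HweResult:
    """Exact test with automatic engine switch at the enumeration bound."""
    calls = t.calls_at(site, locus)
    counts = _counts_from_calls(calls)
    n = sum(counts.values())
    if len(_margins(counts)) <= ENUM_MAX_ALLELES and n <= ENUM_MAX_N:
        return hwe_exact_enumeration(t, site, locus)
    return hwe_exact_mcmc(t, site, locus, steps=steps, burnin=burnin, seed=seed)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def sidak_threshold(alpha: float, m: int) -> float:
    """Per-test significance level controlling the family-wise rate at alpha.

    ``1 - (1 - alpha)**(1/m)``; e.g. alpha=0.05 over 72 tests gives 0.00071.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def apply_sidak(results: list[HweResult], alpha: float = 0.05,
                m: int | None = None) -> float:
    """Flag results significant at the Sidak-corrected level; returns it."""
    if m is None:
        m = len(results)
    thr = sidak_threshold(alpha, m)
    for r in results:
        r.significant_after_sidak = r.p_value < thr
    return thr
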