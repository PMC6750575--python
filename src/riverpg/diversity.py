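"""Per-site, per-locus diversity statistics: Ho, He and F_IS.

Expected heterozygosity uses Nei's unbiased small-sample estimator
``He = 2n/(2n-1) * (1 - sum p_a^2)`` with ``n`` the number of individuals
carrying a non-missing call (pairwise deletion per locus). The inbreeding
coefficient is Nei's ``F_IS = 1 - Ho/He`` (positive = heterozygote deficit),
and the multilocus value weights each locus by its per-locus sample size:
``F_IS(multi) = 1 - sum_l N_l Ho_l / sum_l N_l He_l``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "LocusDiversity",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity_unbiased",
    "fis_table",
]


class EmptyLocusError(ValueError):
    """No non-missing calls at the requested (site, locus)."""


@dataclass
class LocusDiversity:
    site: str
    locus: str
    N: int
    Ho: float
    He: float
    Fis: float | None  # None when He == 0 (monomorphic)


def allele_frequencies(t: GenotypeTable, site: str, locus: str) -> tuple[dict[int, float], int]:
    """Allele frequency map and gene-copy count (2N) for one site x locus."""
    calls = t.calls_at(site, locus)
    if calls.shape[0] == 0:
        raise EmptyLocusError(f"no data at site={site!r} locus={locus!r}")
    alleles, counts = np.unique(calls.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): c / total for a, c in zip(alleles, counts)}, int(total)


def observed_heterozygosity(t: GenotypeTable, site: str, locus: str) -> float:
    calls = t.calls_at(site, locus)
    if calls.shape[0] == 0:
        raise EmptyLocusError(f"no data at site={site!r} locus={locus!r}")
    return float(np.mean(calls[:, 0] != calls[:, 1]))


def expected_heterozygosity_unbiased(t: GenotypeTable, site: str, locus: str) -> float:
    freqs, two_n = allele_frequencies(t, site, locus)
    p = np.array(list(freqs.values()))
    if two_n <= 1:
        return 0.0
    he = two_n / (two_n - 1) * (1.0 - np.sum(p * p))
    return float(max(he, 0.0))


def _cell_stats(calls: np.ndarray) -> tuple[int, float, float]:
    """(N, Ho, He) from a (m, 2) array of non-missing calls."""
    n = calls.shape[0]
    ho = float(np.mean(calls[:, 0] != calls[:, 1]))
    _, counts = np.unique(calls.ravel(), return_counts=True)
    two_n = 2 * n
    p = counts / two_n
    he = 0.0 if two_n <= 1 else max(two_n / (two_n - 1) * (1.0 - float(np.sum(p * p))), 0.0)
    return n, ho, he


def fis_table(t: GenotypeTable) -> tuple[list[LocusDiversity], dict[str, float | None]]:
    """Per-(site, locus) diversity rows plus per-site multilocus F_IS.

    Returns
    -------
    rows : list of LocusDiversity
        One row per site x locus with >= 1 non-missing call.
    multilocus : dict
        Site -> sample-size-weighted multilocus F_IS, or None when every
        locus at the site is monomorphic.
    """
    if t.n_samples == 0:
        raise ValueError("empty genotype table")
    rows: list[LocusDiversity] = []
    multilocus: dict[str, float | None] = {}
    for site in t.sites:
        num = den = 0.0
        for locus in t.locus_ids:
            calls = t.calls_at(site, locus)
            if calls.shape[0] == 0:
                continue
            n, ho, he = _cell_stats(calls)
            fis = None if he == 0 else 1.0 - ho / he
            rows.append(LocusDiversity(site, locus, n, ho, he, fis))
            num += n * ho
            den += n * he
        multilocus[site] = None if den == 0 else 1.0 - num / den
    return rows, multilocus


def diversity_frame(t: GenotypeTable) -> pd.DataFrame:
    """Long-format diversity table (site, locus, N, Ho, He, Fis)."""
    rows, multi = fis_table(t)
    df = pd.DataFrame([r.__dict__ for r in rows])
    extra = pd.DataFrame(
        [{"site": s, "locus": "ALL", "N": np.nan, "Ho": np.nan, "He": np.nan,
          "Fis": multi[s]} for s in t.sites])
    return pd.concat([df, extra], ignore_index=True)
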