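"""Genotype containers and I/O for diploid microsatellite data.

The central container is :class:`GenotypeTable`: diploid calls for samples x
loci, with per-sample site labels and an optional site->group hierarchy.
Allele "labels" are small positive integers (repeat-number offsets, see
:func:`bin_fragments`), and a missing call is coded as the pair ``(0, 0)``
regardless of the on-disk convention (GenePop ``000``, CSV ``-``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeTable",
    "FragmentPanel",
    "GenotypeParseError",
    "BinningConflictError",
    "read_genepop",
    "write_genepop",
    "read_csv_genotypes",
    "write_csv_genotypes",
    "bin_fragments",
]

#: Sentinel allele label for a missing call (both copies).
MISSING = 0


class GenotypeParseError(ValueError):
    """Raised on malformed genotype input; carries the offending line number."""


class BinningConflictError(ValueError):
    """Two fragment-size clusters at one locus map to the same allele label."""


@dataclass
class GenotypeTable:
    """Diploid calls for ``n_samples x n_loci`` with site metadata.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample labels, one per row of ``calls``.
    locus_ids : list of str
        Unique locus labels, one per column of ``calls``.
    calls : ndarray of shape (n_samples, n_loci, 2), int
        Allele labels; each non-missing call is stored sorted
        ``(min, max)``; missing calls are ``(0, 0)``.
    site_of : dict
        Maps every sample id to its site label.
    group_of : dict, optional
        Maps site labels to group labels for hierarchical analyses.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    site_of: dict[str, str]
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        # canonical unordered storage
        self.calls = np.sort(self.calls, axis=2)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        if np.any(self.calls < 0):
            raise ValueError("allele labels must be >= 1 (0 reserved for missing)")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half_missing):
            raise ValueError("a call must have two allele labels or be fully missing")
        for s in self.sample_ids:
            if s not in self.site_of:
                raise ValueError(f"sample {s!r} has no site assignment")
        if self.group_of is not None:
            sites = set(self.site_of.values())
            unknown = set(self.group_of) - sites
            if unknown:
                raise ValueError(f"group_of references unknown sites: {sorted(unknown)}")

    # -- derived views --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def sites(self) -> list[str]:
        """Site labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.site_of[s], None)
        return list(seen)

    def site_index(self) -> np.ndarray:
        """Integer site index per sample, following :attr:`sites` order."""
        order = {lab: i for i, lab in enumerate(self.sites)}
        return np.array([order[self.site_of[s]] for s in self.sample_ids])

    def locus_pos(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def calls_at(self, site: str, locus: str) -> np.ndarray:
        """Non-missing calls (m, 2) for one site x locus cell."""
        if site not in self.sites:
            raise KeyError(f"unknown site {site!r}")
        mask = np.array([self.site_of[s] == site for s in self.sample_ids])
        c = self.calls[mask, self.locus_pos(locus), :]
        return c[c[:, 0] != MISSING]

    def subset_sites(self, keep: list[str]) -> "GenotypeTable":
        mask = np.array([self.site_of[s] in keep for s in self.sample_ids])
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        grp = None
        if self.group_of is not None:
            grp = {s: g for s, g in self.group_of.items() if s in keep}
        return GenotypeTable(ids, list(self.locus_ids), self.calls[mask],
                             {s: self.site_of[s] for s in ids}, grp)

    def relabel_sites(self, mapping: dict[str, str]) -> "GenotypeTable":
        """Merge/rename sites, e.g. collapsing all Iquitos sub-sites to one."""
        site_of = {s: mapping.get(self.site_of[s], self.site_of[s])
                   for s in self.sample_ids}
        return GenotypeTable(list(self.sample_ids), list(self.locus_ids),
                             self.calls.copy(), site_of, None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.locus_ids == other.locus_ids
                and np.array_equal(self.calls, other.calls)
                and self.site_of == other.site_of
                and self.group_of == other.group_of)


@dataclass
class FragmentPanel:
    """Raw fragment lengths (bp) per sample x locus, before allele binning."""

    sample_ids: list[str]
    locus_ids: list[str]
    sizes: np.ndarray  # (n_samples, n_loci, 2) float, NaN = missing
    motif_length: dict[str, int] = field(default_factory=dict)
    site_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if np.any(self.sizes[np.isfinite(self.sizes)] <= 0):
            raise ValueError("fragment lengths must be positive")
        for loc in self.locus_ids:
            m = self.motif_length.get(loc)
            if m not in (2, 3, 4, 5, 6):
                raise ValueError(f"motif_length for {loc!r} must be in 2..6, got {m}")


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _decode_genepop_call(tok: str, lineno: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenotypeParseError(f"line {lineno}: bad genotype token {tok!r}")
    if not tok.isdigit():
        raise GenotypeParseError(f"line {lineno}: bad genotype token {tok!r}")
    a, b = int(tok[:w]), int(tok[w:])
    if a == 0 or b == 0:
        return (MISSING, MISSING)
    return (min(a, b), max(a, b))


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a GenePop 4.x file (2- or 3-digit allele dialect).

    One site per ``POP`` block. ``00``/``000`` alleles decode to missing.
    Site labels are taken from a ``sites=a,b,c`` clause in the title line
    when present, else ``pop1..popN``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty file")
    title = lines[0]
    site_labels: list[str] | None = None
    m = re.search(r"sites=([^;]+)", title)
    if m:
        site_labels = [s.strip() for s in m.group(1).split(",") if s.strip()]

    # locus names: one per line, or comma-separated on one line, until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError("no POP block found")

    sample_ids: list[str] = []
    site_of: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    pop = -1
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            pop += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenotypeParseError(f"line {lineno + 1}: expected 'id , genotypes'")
        sid, geno = line.split(",", 1)
        sid = sid.strip()
        if sid in site_of:
            raise GenotypeParseError(f"line {lineno + 1}: duplicate sample id {sid!r}")
        toks = geno.split()
        if len(toks) != len(loci):
            raise GenotypeParseError(
                f"line {lineno + 1}: {len(toks)} genotypes for {len(loci)} loci")
        rows.append([_decode_genepop_call(t, lineno + 1) for t in toks])
        sample_ids.append(sid)
        if site_labels is not None:
            if pop >= len(site_labels):
                raise GenotypeParseError(
                    f"line {lineno + 1}: more POP blocks than declared sites")
            site_of[sid] = site_labels[pop]
        else:
            site_of[sid] = f"pop{pop + 1}"

    calls = np.array(rows, dtype=np.int32).reshape(len(sample_ids), len(loci), 2)
    return GenotypeTable(sample_ids, loci, calls, site_of)


def write_genepop(t: GenotypeTable, path: str | Path, title: str = "riverpg export") -> None:
    """Write the canonical GenePop dialect (3-digit, sites in title line)."""
    out = [f"{title}; sites={','.join(t.sites)}"]
    out.extend(t.locus_ids)
    site_idx = t.site_index()
    for pop in range(len(t.sites)):
        out.append("POP")
        for j in np.flatnonzero(site_idx == pop):
            toks = []
            for l in range(t.n_loci):
                a, b = t.calls[j, l]
                toks.append(f"{a:03d}{b:03d}")
            out.append(f"{t.sample_ids[j]} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _decode_csv_call(tok: str) -> tuple[int, int]:
    tok = tok.strip()
    if tok in ("", "-", "-/-", "./."):
        return (MISSING, MISSING)
    parts = tok.split("/")
    if len(parts) != 2:
        raise GenotypeParseError(f"bad genotype {tok!r}: expected 'a1/a2'")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise GenotypeParseError(f"bad genotype {tok!r}") from None
    if a == 0 or b == 0:
        return (MISSING, MISSING)
    return (min(a, b), max(a, b))


def read_csv_genotypes(path: str | Path) -> GenotypeTable:
    """Read a genotype CSV with columns ``sample, site, <locus1>, <locus2>, ...``.

    Calls are ``a1/a2`` strings; ``-`` or ``-/-`` is missing. Produces a
    table equivalent to the GenePop reader on the same data.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("sample", "site"):
        if col not in df.columns:
            raise GenotypeParseError(f"missing required column {col!r}")
    loci = [c for c in df.columns if c not in ("sample", "site")]
    if not loci:
        raise GenotypeParseError("no locus columns found")
    sample_ids = df["sample"].tolist()
    calls = np.zeros((len(df), len(loci), 2), dtype=np.int32)
    for l, loc in enumerate(loci):
        for j, tok in enumerate(df[loc].fillna("-")):
            calls[j, l] = _decode_csv_call(tok)
    site_of = dict(zip(sample_ids, df["site"]))
    return GenotypeTable(sample_ids, loci, calls, site_of)


def write_csv_genotypes(t: GenotypeTable, path: str | Path) -> None:
    rows = []
    for j, sid in enumerate(t.sample_ids):
        row = {"sample": sid, "site": t.site_of[sid]}
        for l, loc in enumerate(t.locus_ids):
            a, b = t.calls[j, l]
            row[loc] = "-/-" if a == MISSING else f"{a}/{b}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fragment-size binning
# ---------------------------------------------------------------------------

def _cluster_sizes(sizes: np.ndarray, gap: float) -> list[np.ndarray]:
    """Single-linkage 1-D clustering: split the sorted sizes at gaps >= gap."""
    order = np.argsort(sizes)
    s = sizes[order]
    breaks = np.flatnonzero(np.diff(s) >= gap) + 1
    return [g for g in np.split(s, breaks)]


def bin_fragments(panel: FragmentPanel, gap_fraction: float = 0.5) -> GenotypeTable:
    """Bin raw fragment sizes into integer allele labels, per locus.

    Sorted unique fragment sizes are clustered by single linkage, splitting
    wherever consecutive sizes differ by at least
    ``gap_fraction * motif_length``. Each cluster becomes one allele with
    label ``1 + round((cluster_mean - smallest_cluster_mean) / motif_length)``,
    so labels are repeat-number offsets shared between real and synthetic
    data. Labels must be strictly increasing with fragment size; a collision
    raises :class:`BinningConflictError`.
    """
    if not (0 < gap_fraction < 1):
        raise ValueError("gap_fraction must be in (0, 1)")
    n, L = len(panel.sample_ids), len(panel.locus_ids)
    calls = np.zeros((n, L, 2), dtype=np.int32)
    for l, loc in enumerate(panel.locus_ids):
        motif = panel.motif_length[loc]
        obs = panel.sizes[:, l, :]
        finite = np.isfinite(obs)
        vals = obs[finite]
        if vals.size == 0:
            continue
        clusters = _cluster_sizes(vals, gap_fraction * motif)
        means = np.array([c.mean() for c in clusters])
        labels = 1 + np.round((means - means.min()) / motif).astype(int)
        if len(set(labels.tolist())) != len(labels):
            dup = [means[labels == lab] for lab in np.unique(labels)
                   if (labels == lab).sum() > 1]
            raise BinningConflictError(
                f"locus {loc!r}: clusters with means {dup} map to one label")
        edges = [c.max() for c in clusters]
        assign = np.searchsorted(edges, obs, side="left")
        assign = np.clip(assign, 0, len(clusters) - 1)
        lab = labels[assign]
        lab[~finite] = MISSING
        # a call is missing if either copy is
        any_missing = ~finite.all(axis=1)
        lab[any_missing] = MISSING
        calls[:, l, :] = np.sort(lab, axis=1)
    site_of = panel.site_of or {s: "pop1" for s in panel.sample_ids}
    return GenotypeTable(list(panel.sample_ids), list(panel.locus_ids),
                         calls, dict(site_of))
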