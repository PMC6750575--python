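"""Bayesian admixture clustering (uncorrelated allele frequencies).

Model: individual ``i`` has membership vector ``q_i ~ Dirichlet(alpha)``
over K clusters; cluster ``k`` has allele frequencies ``p_kl ~
Dirichlet(lambda)`` at locus ``l``, independent across clusters and loci
(the "uncorrelated frequencies" model). Each observed allele copy descends
from cluster ``k`` with probability ``q_ik`` and is then a draw from
``p_kl``. A three-block Gibbs sampler alternates: copy origins ``z``
(categorical, ``Pr(z=k) proportional to q_ik p_kl(a)``), frequencies ``p``
(Dirichlet, lambda + assigned counts) and memberships ``q`` (Dirichlet,
alpha + per-cluster copy counts). Missing calls contribute nothing.

Model choice uses the standard estimator of the model log-probability from
the likelihood trace, ``lnPD = mean(l) - var(l)/2``, and the Evanno
second-difference statistic ``deltaK = mean|L''(K)| / sd(L(K))`` across
replicate runs; the selected K maximizes deltaK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "AdmixtureRun",
    "EvannoSummary",
    "gibbs_admixture",
    "estimate_lnPD",
    "evanno",
    "align_labels",
    "dominant_membership",
    "write_structure_file",
]


@dataclass
class AdmixtureRun:
    K: int
    seed: int | None
    alpha: float
    lam: float
    Q: np.ndarray            # (n_individuals, K) posterior-mean memberships
    P: np.ndarray            # (L, K, A_max) posterior-mean cluster frequencies
    loglik_trace: np.ndarray
    lnPD: float
    sample_ids: list[str]
    allele_labels: list[np.ndarray]  # per locus, labels for the A axis


@dataclass
class EvannoSummary:
    K_values: list[int]
    n_runs: dict[int, int]
    mean_L: dict[int, float]
    sd_L: dict[int, float]
    L_prime: dict[int, float]
    L_doubleprime: dict[int, float]
    deltaK: dict[int, float]
    selected_K: int


def _encode(t: GenotypeTable):
    """Flat copy arrays: individual index, locus index, dense allele code."""
    n, L = t.n_samples, t.n_loci
    allele_labels = []
    ind_idx, loc_idx, allele_idx = [], [], []
    n_alleles = np.zeros(L, dtype=int)
    for l in range(L):
        col = t.calls[:, l, :]
        labels = np.unique(col[col != MISSING])
        allele_labels.append(labels)
        n_alleles[l] = len(labels)
        lut = np.zeros(int(labels.max()) + 1 if len(labels) else 1, dtype=np.int64)
        for c, a in enumerate(labels):
            lut[a] = c
        nm = col[:, 0] != MISSING
        rows = np.flatnonzero(nm)
        for copy in range(2):
            ind_idx.append(rows)
            loc_idx.append(np.full(rows.shape, l))
            allele_idx.append(lut[col[rows, copy]])
    return (np.concatenate(ind_idx), np.concatenate(loc_idx),
            np.concatenate(allele_idx), n_alleles, allele_labels)


def gibbs_admixture(t: GenotypeTable, K: int, burnin: int = 2_000,
                    iters: int = 10_000, alpha: float = 1.0, lam: float = 1.0,
                    thin: int = 10, seed: int | None = None) -> AdmixtureRun:
    """Run the Gibbs sampler; returns posterior means and the lnPD estimate.

    Defaults are desk-scale; the full field protocol uses
    ``burnin=100_000, iters=200_000``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if t.n_samples == 0:
        raise ValueError("empty genotype table")
    rng = np.random.default_rng(seed)
    n, L = t.n_samples, t.n_loci
    ind_idx, loc_idx, allele_idx, n_alleles, allele_labels = _encode(t)
    A = int(n_alleles.max())
    n_copies = ind_idx.shape[0]
    valid = np.zeros((L, A), dtype=bool)
    for l in range(L):
        valid[l, :n_alleles[l]] = True

    # initial values
    q = rng.dirichlet(np.full(K, alpha), size=n)
    p = np.zeros((L, K, A))
    for l in range(L):
        p[l, :, :n_alleles[l]] = rng.dirichlet(np.full(n_alleles[l], lam), size=K)

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    trace = []
    n_kept = 0
    flat_la = loc_idx * A + allele_idx  # index into (L*A) per copy

    for sweep in range(burnin + iters):
        # copy-origin assignments z
        w = q[ind_idx] * p.transpose(0, 2, 1).reshape(L * A, K)[flat_la]  # (n_copies, K)
        if K == 1:
            z = np.zeros(n_copies, dtype=np.int64)
        else:
            cum = np.cumsum(w, axis=1)
            u = rng.random(n_copies) * cum[:, -1]
            z = (u[:, None] >= cum).sum(axis=1)
        # cluster allele frequencies
        counts = np.zeros((L, K, A))
        np.add.at(counts.reshape(-1), (loc_idx * K + z) * A + allele_idx, 1.0)
        g = rng.standard_gamma(lam + counts)
        g[:, :, :] *= valid[:, None, :]
        p = g / g.sum(axis=2, keepdims=True)
        # memberships
        ik = np.zeros((n, K))
        np.add.at(ik.reshape(-1), ind_idx * K + z, 1.0)
        gq = rng.standard_gamma(alpha + ik)
        q = gq / gq.sum(axis=1, keepdims=True)
        if sweep >= burnin and (sweep - burnin) % thin == 0:
            ll = float(np.sum(np.log(
                (q[ind_idx] * p.transpose(0, 2, 1).reshape(L * A, K)[flat_la]).sum(axis=1))))
            trace.append(ll)
            q_sum += q
            p_sum += p
            n_kept += 1

    trace_arr = np.array(trace)
    q_mean = q_sum / n_kept
    p_mean = p_sum / n_kept
    if K == 1:
        q_mean = np.ones((n, 1))
    return AdmixtureRun(K, seed, alpha, lam, q_mean, p_mean, trace_arr,
                        estimate_lnPD(trace_arr), list(t.sample_ids), allele_labels)


def loglik_at(t: GenotypeTable, Q: np.ndarray, P: np.ndarray) -> float:
    """Observed-data log-likelihood under given memberships and frequencies."""
    ind_idx, loc_idx, allele_idx, n_alleles, _ = _encode(t)
    A = P.shape[2]
    flat = P.transpose(0, 2, 1).reshape(-1, P.shape[1])[loc_idx * A + allele_idx]
    return float(np.sum(np.log((Q[ind_idx] * flat).sum(axis=1))))


def estimate_lnPD(trace: np.ndarray) -> float:
    """Model log-probability estimate: ``mean(trace) - var(trace)/2``.

    Uses the sample variance (ddof=1); requires a trace of length >= 2
    (a constant trace returns its value).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty likelihood trace")
    if trace.size == 1:
        return float(trace[0])
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def evanno(runs: list[AdmixtureRun]) -> EvannoSummary:
    """Evanno deltaK model choice over replicate runs grouped by K.

    Requires >= 3 consecutive K values with >= 2 runs each. ``deltaK`` is
    defined for interior K with positive replicate spread; the selected K
    maximizes it.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.lnPD)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(by_k[k]) < 2:
            raise ValueError(f"need >= 2 runs per K (K={k} has {len(by_k[k])})")
    mean_l = {k: float(np.mean(by_k[k])) for k in ks}
    sd_l = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    lp = {k: mean_l[k] - mean_l[k - 1] for k in ks[1:]}
    lpp = {k: abs(lp[k + 1] - lp[k]) for k in ks[1:-1]}
    dk: dict[int, float] = {}
    for k in ks[1:-1]:
        dk[k] = lpp[k] / sd_l[k] if sd_l[k] > 0 else float("nan")
    finite = {k: v for k, v in dk.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("deltaK undefined everywhere (zero replicate spread)")
    selected = max(finite, key=finite.get)
    return EvannoSummary(ks, {k: len(by_k[k]) for k in ks}, mean_l, sd_l,
                         lp, lpp, dk, selected)


def align_labels(runs: list[AdmixtureRun],
                 reference: AdmixtureRun | None = None) -> list[AdmixtureRun]:
    """Permute cluster labels of each run to best match the reference run.

    The permutation maximizes ``sum_i sum_k min(Q_ref[i,k], Q_run[i,perm(k)])``
    (solved as an assignment problem, hence bijective). Label switching
    between MCMC runs is a pure relabelling, so this loses nothing.
    """
    if not runs:
        return []
    ref = reference or runs[0]
    out = []
    for r in runs:
        if r.K != ref.K:
            raise ValueError("runs must share K for label alignment")
        K = r.K
        score = np.zeros((K, K))
        for k_ref in range(K):
            for k_run in range(K):
                score[k_ref, k_run] = np.minimum(ref.Q[:, k_ref], r.Q[:, k_run]).sum()
        rows, cols = linear_sum_assignment(-score)
        perm = cols[np.argsort(rows)]
        out.append(AdmixtureRun(r.K, r.seed, r.alpha, r.lam,
                                r.Q[:, perm], r.P[:, perm, :],
                                r.loglik_trace, r.lnPD, r.sample_ids,
                                r.allele_labels))
    return out


def dominant_membership(Q: np.ndarray, site_of: list[str],
                        threshold: float = 0.8) -> dict:
    """Fractions of individuals with dominant membership in the modal cluster.

    An individual is *dominant* when its largest membership coefficient
    exceeds ``threshold``. The modal cluster is the cluster most often
    dominant overall; per-site and overall fractions count dominance in
    that cluster (mirroring the share of individuals assigned to the single
    most common genetic group).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be inside (0, 1)")
    Q = np.asarray(Q, dtype=float)
    top = Q.argmax(axis=1)
    dom = Q.max(axis=1) > threshold
    if dom.any():
        modal = int(np.bincount(top[dom], minlength=Q.shape[1]).argmax())
    else:
        modal = int(np.bincount(top, minlength=Q.shape[1]).argmax())
    in_modal = dom & (top == modal)
    sites = list(dict.fromkeys(site_of))
    site_arr = np.array(site_of)
    per_site = {s: float(in_modal[site_arr == s].mean()) for s in sites}
    return {
        "modal_cluster": modal,
        "overall_fraction": float(in_modal.mean()),
        "n_dominant": int(in_modal.sum()),
        "n_individuals": int(Q.shape[0]),
        "per_site_fraction": per_site,
        "overall_fraction_any_cluster": float(dom.mean()),
    }


def write_structure_file(t: GenotypeTable, path) -> None:
    """Write a STRUCTURE-format genotype file (two rows per individual)."""
    sites = {s: i + 1 for i, s in enumerate(t.sites)}
    lines = ["\t".join(["id", "pop"] + list(t.locus_ids))]
    for j, sid in enumerate(t.sample_ids):
        for copy in range(2):
            row = [sid, str(sites[t.site_of[sid]])]
            for l in range(t.n_loci):
                a = int(t.calls[j, l, copy])
                row.append(str(a if a != MISSING else -9))
            lines.append("\t".join(row))
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
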