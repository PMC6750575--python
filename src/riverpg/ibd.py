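"""Isolation by distance: Mantel tests of F_ST against distance models.

The Mantel statistic is the Pearson correlation of the off-diagonal upper
triangles of two labelled symmetric matrices; significance comes from
jointly permuting rows and columns of the second matrix. Distance models
(Euclidean, fluvial path, shortest path) are tested one-tailed for a
positive correlation (classical isolation by distance); the PrPI transport
similarity is tested one-tailed for a *negative* correlation, since heavier
weighted traffic predicts lower F_ST. When too few pairs carry transport
data the PrPI comparison is emitted with ``test_skipped`` set and no
p-value, matching the practice of plotting those points without a test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fst import FstMatrix
from .transport import DistanceMatrix

__all__ = ["MantelResult", "mantel_test", "ibd_suite"]


@dataclass
class MantelResult:
    model: str
    r: float
    p: float | None
    n_permutations: int
    n_sites: int
    tail: str = "greater"
    test_skipped: bool = False


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in a distance triangle; r undefined")
    return float((xc @ yc) / denom)


def mantel_test(d1: DistanceMatrix | np.ndarray, d2: DistanceMatrix | np.ndarray,
                n_perm: int = 10_000, seed: int | None = None,
                tail: str = "greater", labels: list[str] | None = None) -> MantelResult:
    """Mantel permutation test between two labelled symmetric matrices.

    Rows and columns of the second matrix are relabelled jointly each
    permutation; ``p = (#{as or more extreme} + 1)/(n_perm + 1)``.
    """
    if tail not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown tail {tail!r}")
    name = "mantel"
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if d1.labels != d2.labels:
            raise ValueError("label mismatch between matrices")
        name = d2.model
    m1 = d1.values if isinstance(d1, DistanceMatrix) else np.asarray(d1, float)
    m2 = d2.values if isinstance(d2, DistanceMatrix) else np.asarray(d2, float)
    n = m1.shape[0]
    if n < 4:
        raise ValueError("need >= 4 sites for a Mantel test")
    x = _upper(m1)
    r_obs = _pearson(x, _upper(m2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(x, _upper(m2[np.ix_(perm, perm)]))
        if tail == "greater":
            count += r_p >= r_obs
        elif tail == "less":
            count += r_p <= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return MantelResult(name, r_obs, p, n_perm, n, tail)


def ibd_suite(fst: FstMatrix, models: list[DistanceMatrix],
              n_perm: int = 10_000, seed: int | None = None,
              min_pairs: int = 6) -> tuple[list[MantelResult], list[dict]]:
    """Mantel tests of an F_ST matrix against each distance model.

    Returns the test results plus long-format scatter records
    ``{pair, model, distance, fst}`` for isolation-by-distance plots.
    Models whose ``defined`` mask covers fewer than ``min_pairs`` pairs
    (the PrPI case) are reported with ``test_skipped`` and no p-value.
    """
    rng = np.random.default_rng(seed)
    results: list[MantelResult] = []
    scatter: list[dict] = []
    k = len(fst.labels)
    for model in models:
        if model.labels != fst.labels:
            raise ValueError(f"model {model.model!r} labels do not match F_ST labels")
        tail = "less" if model.is_similarity else "greater"
        iu = np.triu_indices(k, 1)
        defined = model.defined[iu] if model.defined is not None else np.ones(len(iu[0]), bool)
        for a, b, keep in zip(*iu, defined):
            if keep:
                scatter.append({"pair": f"{fst.labels[a]}|{fst.labels[b]}",
                                "model": model.model,
                                "distance": float(model.values[a, b]),
                                "fst": float(fst.theta[a, b])})
        n_pairs = int(defined.sum())
        if n_pairs < min_pairs:
            r = float("nan")
            if n_pairs >= 3:
                x = fst.theta[iu][defined]
                y = model.values[iu][defined]
                r = _pearson(x, y)
            results.append(MantelResult(model.model, r, None, 0, k, tail,
                                        test_skipped=True))
            continue
        sub_seed = int(rng.integers(2**31 - 1))
        results.append(mantel_test(FstDistance(fst), model, n_perm=n_perm,
                                   seed=sub_seed, tail=tail))
    return results, scatter


class FstDistance(DistanceMatrix):
    """Adapter presenting an FstMatrix as a DistanceMatrix for Mantel input."""

    def __init__(self, fst: FstMatrix):
        vals = fst.theta.copy()
        # permutation-test noise can leave tiny negative estimates; Mantel
        # correlation is unaffected by keeping them as-is
        super().__init__(list(fst.labels), np.where(np.isnan(vals), 0.0, vals),
                         "fst", is_similarity=False)

    def __post_init__(self):  # skip the non-negativity check for theta
        pass
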