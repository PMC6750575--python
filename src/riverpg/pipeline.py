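"""Config-driven orchestration of the full analysis sequence.

Stage order mirrors the study protocol: per-site diversity -> exact HWE
tests with a Sidak family-wise correction -> pairwise F_ST on all sites and
again with the city sub-sites collapsed -> hierarchical AMOVA -> distance
models and PrPI -> Mantel isolation-by-distance suite -> admixture K sweep
with Evanno deltaK -> dominant-membership summary. Every stage is a pure
function of (inputs, config, seeds); outputs are TSV/JSON files plus a
markdown report. A failed stage is recorded and later independent stages
still run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as adm
from . import diversity, fst, hwe, ibd, transport
from .amova import amova
from .genotypes import GenotypeTable, read_csv_genotypes, read_genepop
from .simulate import SimulationSpec, simulate_study_genotypes, simulate_study_region

__all__ = ["RunConfig", "run_all", "format_percent", "load_config"]

log = logging.getLogger("riverpg")

#: genotype site -> geography town for the collapsed (6-population) analyses
DEFAULT_TOWN_OF = {
    "BarrioFlorida": "BarrioFlorida", "Aucayo": "Aucayo",
    "IndianaMazan": "Indiana", "Nauta": "Nauta", "Tamshiaco": "Tamshiaco",
    "Iquitos": "Iquitos",
}


def format_percent(numerator: int, denominator: int) -> str:
    """Report-style percentage at one decimal place, e.g. 45/72 -> '62.5%'."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return f"{100.0 * numerator / denominator:.1f}%"


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    genotypes: str | None = None          # GenePop (.gen) or CSV path; None -> simulate
    simulate: dict = field(default_factory=dict)   # SimulationSpec overrides
    collapse_map: dict = field(default_factory=dict)  # site -> merged label
    hierarchy: dict = field(default_factory=dict)     # site -> group (AMOVA)
    town_of: dict = field(default_factory=lambda: dict(DEFAULT_TOWN_OF))
    hwe_steps: int = 20_000
    hwe_burnin: int = 2_000
    alpha: float = 0.05
    n_tests_override: int | None = None
    fst_permutations: int = 200
    amova_permutations: int = 100
    mantel_permutations: int = 999
    min_prpi_pairs: int = 6
    k_range: tuple[int, int] = (1, 5)
    runs_per_k: int = 3
    admix_burnin: int = 500
    admix_iters: int = 2_000
    admix_thin: int = 10
    dominance_threshold: float = 0.8
    paper_protocol: bool = False

    def __post_init__(self) -> None:
        if self.paper_protocol:
            self.hwe_steps, self.hwe_burnin = 1_000_000, 100_000
            self.fst_permutations = 10_000
            self.amova_permutations = 10_000
            self.mantel_permutations = 10_000
            self.k_range = (1, 10)
            self.runs_per_k = 10
            self.admix_burnin, self.admix_iters = 100_000, 200_000
        lo, hi = self.k_range
        if lo < 1 or hi < lo:
            raise ValueError("k_range must be a contiguous range starting >= 1")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "k_range" in data:
        data["k_range"] = tuple(data["k_range"])
    return RunConfig(**data)


def _load_genotypes(cfg: RunConfig) -> GenotypeTable:
    if cfg.genotypes is None:
        spec = SimulationSpec(seed=cfg.seed, **cfg.simulate)
        return simulate_study_genotypes(spec)
    p = Path(cfg.genotypes)
    if p.suffix.lower() in (".gen", ".genepop", ".txt"):
        return read_genepop(p)
    return read_csv_genotypes(p)


def _collapse(t: GenotypeTable, cfg: RunConfig) -> GenotypeTable:
    if cfg.collapse_map:
        return t.relabel_sites(cfg.collapse_map)
    auto = {s: "Iquitos" for s in t.sites if s.startswith("Iquitos")}
    return t.relabel_sites(auto) if auto else t


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a results dict and writes files to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    results: dict = {"stages": {}}
    t0 = time.time()

    def stage(name, fn):
        start = time.time()
        try:
            value = fn()
            results[name] = value
            results["stages"][name] = {"status": "ok", "seconds": round(time.time() - start, 2)}
            log.info("stage %s ok (%.1fs)", name, time.time() - start)
            return value
        except Exception as exc:  # keep later stages running
            results["stages"][name] = {"status": "failed", "error": str(exc)}
            log.exception("stage %s failed", name)
            return None

    table = stage("load", lambda: _load_genotypes(cfg))
    if table is None:
        return results
    geo, net = simulate_study_region(seed=cfg.seed)

    def _diversity():
        df = diversity.diversity_frame(table)
        df.to_csv(out / "diversity.tsv", sep="\t", index=False)
        return df
    stage("diversity", _diversity)

    def _hwe():
        res = []
        for site in table.sites:
            for locus in table.locus_ids:
                res.append(hwe.hwe_test(table, site, locus,
                                        steps=cfg.hwe_steps, burnin=cfg.hwe_burnin,
                                        seed=int(rng.integers(2**31 - 1))))
        m = cfg.n_tests_override or len(res)
        thr = hwe.apply_sidak(res, cfg.alpha, m)
        df = pd.DataFrame([r.__dict__ for r in res])
        df.to_csv(out / "hwe.tsv", sep="\t", index=False)
        n_in_hwe = int(sum(not r.significant_after_sidak for r in res))
        return {"results": res, "threshold": thr, "n_tests": m,
                "n_in_hwe": n_in_hwe,
                "pct_in_hwe": format_percent(n_in_hwe, len(res))}
    stage("hwe", _hwe)

    def _fst_full():
        mat = fst.pairwise_fst(table, n_perm=cfg.fst_permutations,
                               seed=int(rng.integers(2**31 - 1)))
        _write_matrix(mat.theta, mat.labels, out / "fst_all_sites.tsv", mat.p)
        return mat
    stage("fst_all_sites", _fst_full)

    collapsed = _collapse(table, cfg)

    def _fst_collapsed():
        mat = fst.pairwise_fst(collapsed, n_perm=cfg.fst_permutations,
                               seed=int(rng.integers(2**31 - 1)))
        _write_matrix(mat.theta, mat.labels, out / "fst_collapsed.tsv", mat.p)
        return mat
    fst_c = stage("fst_collapsed", _fst_collapsed)

    def _amova():
        hierarchy = cfg.hierarchy or table.group_of
        res = amova(table, hierarchy, n_perm=cfg.amova_permutations,
                    seed=int(rng.integers(2**31 - 1)))
        rows = []
        names = {"among_groups": "sigma2_a", "among_populations_within_groups": "sigma2_b",
                 "among_individuals_within_populations": "sigma2_c",
                 "within_individuals": "sigma2_d"}
        for lvl, comp in names.items():
            rows.append({"level": lvl, "df": res.df[lvl], "SS": res.sum_of_squares[lvl],
                         "variance_component": res.variance_components[comp],
                         "percent": res.percent_of_total[lvl]})
        pd.DataFrame(rows).to_csv(out / "amova.tsv", sep="\t", index=False)
        (out / "amova_f.json").write_text(json.dumps(
            {"F_CT": res.F_CT, "F_SC": res.F_SC, "F_IS": res.F_IS,
             "F_IT": res.F_IT, "p_values": res.p_values}, indent=2))
        return res
    stage("amova", _amova)

    def _distances():
        town_of = {s: cfg.town_of.get(s, s) for s in collapsed.sites}
        missing = [s for s, town in town_of.items() if town not in net.nodes]
        if missing:
            raise ValueError(f"no geography for sites: {missing}")
        idx = [net.nodes.index(town_of[s]) for s in collapsed.sites]
        labels = collapsed.sites
        models = []
        for dm in (transport.euclidean_matrix(geo),
                   transport.path_matrix(net, ("fluvial",)),
                   transport.path_matrix(net),
                   transport.prpi_matrix(net)):
            sub = dm.values[np.ix_(idx, idx)]
            defined = dm.defined[np.ix_(idx, idx)] if dm.defined is not None else None
            models.append(transport.DistanceMatrix(labels, sub, dm.model,
                                                   dm.is_similarity, defined))
        rows = []
        for m in models:
            iu = np.triu_indices(len(labels), 1)
            for a, b in zip(*iu):
                rows.append({"model": m.model, "from": labels[a], "to": labels[b],
                             "value": m.values[a, b]})
        pd.DataFrame(rows).to_csv(out / "distances.tsv", sep="\t", index=False)
        return models
    models = stage("distances", _distances)

    if models is not None and fst_c is not None:
        def _ibd():
            res, scatter = ibd.ibd_suite(fst_c, models,
                                         n_perm=cfg.mantel_permutations,
                                         seed=int(rng.integers(2**31 - 1)),
                                         min_pairs=cfg.min_prpi_pairs)
            pd.DataFrame(scatter).to_csv(out / "ibd_scatter.tsv", sep="\t", index=False)
            (out / "mantel.json").write_text(json.dumps(
                [r.__dict__ for r in res], indent=2))
            return res
        stage("ibd", _ibd)

    def _admixture():
        lo, hi = cfg.k_range
        runs: list[adm.AdmixtureRun] = []
        for K in range(lo, hi + 1):
            for _ in range(cfg.runs_per_k):
                runs.append(adm.gibbs_admixture(
                    table, K, burnin=cfg.admix_burnin, iters=cfg.admix_iters,
                    thin=cfg.admix_thin, seed=int(rng.integers(2**31 - 1))))
        summary = adm.evanno(runs)
        pd.DataFrame([{"K": k, "n_runs": summary.n_runs[k],
                       "mean_L": summary.mean_L[k], "sd_L": summary.sd_L[k],
                       "L_prime": summary.L_prime.get(k),
                       "L_doubleprime": summary.L_doubleprime.get(k),
                       "deltaK": summary.deltaK.get(k)}
                      for k in summary.K_values]).to_csv(
            out / "evanno.tsv", sep="\t", index=False)
        best = [r for r in runs if r.K == summary.selected_K]
        best = adm.align_labels(best)
        Q = np.mean([r.Q for r in best], axis=0)
        site_of = [table.site_of[s] for s in table.sample_ids]
        qdf = pd.DataFrame(Q, columns=[f"q_{k + 1}" for k in range(Q.shape[1])])
        qdf.insert(0, "site", site_of)
        qdf.insert(0, "individual", table.sample_ids)
        qdf.to_csv(out / "q_matrix.tsv", sep="\t", index=False)
        dom = adm.dominant_membership(Q, site_of, cfg.dominance_threshold)
        (out / "membership.json").write_text(json.dumps(dom, indent=2))
        return {"runs": runs, "evanno": summary, "Q": Q, "dominance": dom}
    stage("admixture", _admixture)

    results["wall_seconds"] = round(time.time() - t0, 1)
    _write_report(results, cfg, out)
    return results


def _write_matrix(values: np.ndarray, labels: list[str], path: Path,
                  p: np.ndarray | None = None) -> None:
    """Lower-triangle matrix TSV with significance stars (p < 0.05)."""
    lines = ["\t" + "\t".join(labels)]
    for i, lab in enumerate(labels):
        cells = []
        for j in range(len(labels)):
            if j > i:
                cells.append("")
            elif j == i:
                cells.append("0")
            else:
                star = "*" if p is not None and np.isfinite(p[i, j]) and p[i, j] < 0.05 else ""
                v = values[i, j]
                cells.append(("NA" if not np.isfinite(v) else f"{v:.5f}") + star)
        lines.append(lab + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def _write_report(results: dict, cfg: RunConfig, out: Path) -> None:
    lines = ["# riverpg analysis report", ""]
    lines.append(f"Seed: {cfg.seed}; wall time: {results.get('wall_seconds', '?')} s")
    lines.append("")
    for name, st in results["stages"].items():
        mark = "ok" if st["status"] == "ok" else f"FAILED ({st.get('error')})"
        lines.append(f"- stage `{name}`: {mark}")
    lines.append("")
    hw = results.get("hwe")
    if hw:
        lines.append(f"HWE: {hw['n_in_hwe']} of {len(hw['results'])} tests in "
                     f"equilibrium ({hw['pct_in_hwe']}); Sidak threshold "
                     f"{hw['threshold']:.5f} over {hw['n_tests']} tests.")
    am = results.get("amova")
    if am:
        pct = am.percent_of_total
        lines.append(
            "AMOVA percent of variance: "
            + ", ".join(f"{k}={v:.2f}%" for k, v in pct.items())
            + f"; F_CT={am.F_CT:.5f}, F_SC={am.F_SC:.5f}, F_IS={am.F_IS:.5f}, "
              f"F_IT={am.F_IT:.5f}")
    admix = results.get("admixture")
    if admix:
        dom = admix["dominance"]
        lines.append(
            f"Admixture: selected K = {admix['evanno'].selected_K}; "
            f"{dom['n_dominant']} of {dom['n_individuals']} individuals "
            f"({format_percent(dom['n_dominant'], dom['n_individuals'])}) show "
            f"dominant membership (> {cfg.dominance_threshold}) in the modal cluster.")
    mant = results.get("ibd")
    if mant:
        for r in mant:
            if r.test_skipped:
                lines.append(f"Mantel [{r.model}]: skipped (too few pairs with data); "
                             f"r={r.r if np.isfinite(r.r) else 'NA'}")
            else:
                lines.append(f"Mantel [{r.model}]: r={r.r:.3f}, p={r.p:.4f} ({r.tail})")
    (out / "report.md").write_text("\n".join(lines) + "\n")
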