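"""End-to-end analysis pipeline: load -> global metrics -> null ensemble ->
rich club -> centrality -> modules -> knotty centres -> central core ->
perturbation -> optional enrichment, with every artifact written to disk and a
manifest sufficient to reproduce the run."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import networkx as nx
import yaml

from . import centrality as ce
from . import enrichment as en
from . import io as nio
from . import knotty as kn
from . import mcode as mc
from . import metrics as me
from . import nulls as nu
from . import perturb as pe
from . import richclub as rc


@dataclass
class AnalysisConfig:
    edges_path: str = ""
    out_dir: str = "netarch_out"
    score_min: float = 0.4
    n_null: int = 1000
    seed: int = 42
    rho_min: float = 1.0
    sd_mult: float = 3.0
    swaps_per_edge: int = 10
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    min_module_size: int = 3
    n_random_triads: int = 100
    path_scope: str = "pairs"
    gmt_path: str | None = None
    enrich_mode: str = "ease"

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    global_metrics: dict | None = None
    richclub: dict | None = None
    centrality: dict | None = None
    modules: dict | None = None
    knotty: dict | None = None
    perturbation: dict | None = None
    enrichment: list | None = None
    errors: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["config"] = asdict(self.config)
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: AnalysisConfig, graph: nx.Graph | None = None) -> AnalysisReport:
    """Execute every analysis stage; a stage failure is recorded in
    ``report.errors`` and later stages that can still run do so.

    ``graph`` may be passed directly (e.g. a synthetic network); otherwise the
    edge list at ``config.edges_path`` is loaded.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report = AnalysisReport(config=config)
    timings: dict[str, float] = {}
    out = config.out_dir

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - partial reports by contract
                report.errors[name] = f"{type(exc).__name__}: {exc}"
            timings[name] = round(time.perf_counter() - t0, 3)

        return deco

    if graph is None:
        G = nio.load_scored_edges(config.edges_path, config.score_min)
    else:
        G = graph

    @stage("global_metrics")
    def _metrics():
        gm = me.global_metrics(G, path_scope=config.path_scope)
        report.global_metrics = gm.as_dict()

    ensemble = None

    @stage("null_ensemble")
    def _nulls():
        nonlocal ensemble
        ensemble = nu.make_ensemble(
            G, n=config.n_null, seed=config.seed, swaps_per_edge=config.swaps_per_edge
        )

    profile = None
    club: set = set()

    @stage("richclub")
    def _richclub():
        nonlocal profile, club
        if ensemble is None:
            raise RuntimeError("null ensemble unavailable")
        profile = rc.rho_profile(G, ensemble)
        regime = rc.detect_regime(profile, rho_min=config.rho_min)
        summary = {"regime": list(regime) if regime else None}
        if regime is not None:
            p_per_k, p_pooled = rc.regime_significance(profile)
            club = rc.club_members(G, regime)
            summary.update(
                {
                    "p_pooled": p_pooled,
                    "n_members": len(club),
                    "members": sorted(club),
                }
            )
        profile.to_frame().to_csv(os.path.join(out, "richclub_profile.tsv"), sep="\t", index=False)
        with open(os.path.join(out, "richclub_summary.json"), "wt") as fh:
            json.dump(summary, fh, indent=2)
        report.richclub = summary

    table = None
    core: set = set()
    triad: set = set()

    @stage("centrality")
    def _centrality():
        nonlocal table, core, triad
        table = ce.centrality_table(G)
        core = ce.central_core(table, sd_mult=config.sd_mult)
        brokers = ce.top_brokers(table, n=20)
        if len(core) == 3:
            triad = set(core)
        else:
            zsum = table[["z_degree", "z_closeness", "z_betweenness"]].sum(axis=1)
            triad = set(zsum.sort_values(ascending=False).index[:3])
        table.to_csv(os.path.join(out, "centrality.tsv"), sep="\t")
        with open(os.path.join(out, "central_core.json"), "wt") as fh:
            json.dump({"sd_mult": config.sd_mult, "core": sorted(core), "triad": sorted(triad)}, fh, indent=2)
        report.centrality = {
            "central_core": sorted(core),
            "triad": sorted(triad),
            "top_brokers": brokers,
        }

    modules = None
    collapsed = None

    @stage("modules")
    def _modules():
        nonlocal modules, collapsed
        params = mc.MCODEParams(
            degree_cutoff=config.mcode_degree_cutoff,
            node_score_cutoff=config.mcode_node_score_cutoff,
            k_core=config.mcode_k_core,
            max_depth=config.mcode_max_depth,
        )
        source = G.subgraph(club).copy() if club else G
        found = mc.mcode_find(source, params)
        modules = mc.filter_modules(found, config.min_module_size)
        collapsed = mc.collapse(G, modules, restrict_to=(set(G.nodes()) - club) if club else None)
        rows = []
        for i, (m, s) in enumerate(modules.modules, start=1):
            for v in sorted(m):
                rows.append(f"{v}\tM{i}\t{s:.6g}")
        with open(os.path.join(out, "modules.tsv"), "wt") as fh:
            fh.write("node\tmodule_id\tmodule_score\n")
            fh.write("\n".join(rows) + ("\n" if rows else ""))
        nx.write_graphml(collapsed.graph, os.path.join(out, "collapsed.graphml"))
        report.modules = {
            "n_found": len(found),
            "n_kept": len(modules),
            "sizes": sorted((len(m) for m, _ in modules.modules), reverse=True),
        }

    @stage("knotty")
    def _knotty():
        res_full = kn.find_knotty_centre(G, seed=config.seed)
        results = {"full": res_full}
        if club:
            results["club"] = kn.find_knotty_centre(G.subgraph(club).copy(), seed=config.seed)
        if collapsed is not None and collapsed.graph.number_of_edges() >= 2:
            results["collapsed"] = kn.find_knotty_centre(collapsed.graph, seed=config.seed)
        payload: dict = {}
        for name, res in results.items():
            payload[name] = (
                None
                if res is None
                else {"members": sorted(res.members), "kc_score": res.kc_score, "method": res.method}
            )
        if results.get("full") and results.get("club"):
            payload["overlap_full_club"] = list(
                kn.overlap_fraction(results["full"].members, results["club"].members)
            )
        if results.get("collapsed") and collapsed is not None:
            supernodes = collapsed.module_supernodes()
            members = results["collapsed"].members
            payload["collapsed_module_fraction"] = (
                len(set(members) & supernodes) / len(members) if members else 0.0
            )
        with open(os.path.join(out, "knotty.json"), "wt") as fh:
            json.dump(payload, fh, indent=2)
        report.knotty = payload

    @stage("perturbation")
    def _perturb():
        if len(triad) != 3:
            raise RuntimeError("no 3-node triad available")
        pool = club - triad if club else set(G.nodes()) - triad
        if len(pool) < 3:
            raise RuntimeError("comparison pool too small")
        res = pe.triad_experiment(
            G, triad, pool, n_random=config.n_random_triads, seed=config.seed
        )
        with open(os.path.join(out, "perturbation.tsv"), "wt") as fh:
            fh.write("metric\ttargeted\trandom_mean\trandom_sd\tratio\tp\n")
            for m in res.metric_names:
                rcs = res.random_changes[m]
                mean = sum(rcs) / len(rcs) if rcs else float("nan")
                sd = (
                    (sum((x - mean) ** 2 for x in rcs) / (len(rcs) - 1)) ** 0.5
                    if len(rcs) > 1
                    else float("nan")
                )
                fh.write(
                    f"{m}\t{res.targeted_change[m]}\t{mean:.6g}\t{sd:.6g}"
                    f"\t{res.ratio[m]}\t{res.p_value[m]}\n"
                )
        report.perturbation = {
            "triad": sorted(triad),
            "ratio": res.ratio,
            "p_value": res.p_value,
            "n_random": res.n_random,
        }

    @stage("enrichment")
    def _enrich():
        if not config.gmt_path:
            return
        collection = nio.read_gmt(config.gmt_path)
        background = set(G.nodes())
        query = club if club else set(G.nodes())
        rows = en.enrich(query, collection, background, mode=config.enrich_mode)
        with open(os.path.join(out, "enrichment.tsv"), "wt") as fh:
            fh.write("term\thits\tset_size\tterm_size\tbackground_size\tp\tp_adjusted\tscore\n")
            for r in rows:
                fh.write(
                    f"{r.term}\t{r.hits}\t{r.set_size}\t{r.term_size}\t{r.background_size}"
                    f"\t{r.p:.6g}\t{r.p_adjusted:.6g}\t{r.enrichment_score:.6g}\n"
                )
        report.enrichment = [asdict(r) for r in rows]

    report.manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "input_sha256": _sha256(config.edges_path) if graph is None and config.edges_path else None,
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
        "timings_s": timings,
    }
    with open(os.path.join(out, "report.json"), "wt") as fh:
        json.dump(report.as_dict(), fh, indent=2, default=str)
    return report
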