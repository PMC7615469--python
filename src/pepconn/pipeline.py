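"""End-to-end orchestration: build networks, measure topology, classify
couples, cluster the mesoscale, and analyze co-expression, producing a
self-contained machine-readable report.

Stages run in dependency order; a failure in one analysis stage is logged
and flagged in the report without aborting independent stages. All random
stages draw from named seeds echoed into the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import build as nb
from . import coexpression as cx
from . import mesoscale as ms
from . import pairtypes as pt
from . import topology as tp
from .core import ExpressionMatrix, InteractionEntry, NeuronAnnotation, couples_at_threshold
from .io import (
    load_annotations,
    load_expression,
    load_interactions,
    load_wired,
)
from .roster import canonical_roster

log = logging.getLogger("pepconn")


@dataclass
class RunConfig:
    expression: str | None = None
    interactions: str | None = None
    anatomy: str | None = None
    wired: dict[str, str] = field(default_factory=dict)  # name -> path
    ec50_max: float = 500e-9  # molar; headline threshold 500 nM
    ec50_unit: str = "M"
    expression_threshold: int = 4
    model: str = "short"
    n_null: int = 100
    swaps_per_edge: int = 10
    seed: int = 42
    perplexity: float = 30.0
    coexpression_alpha: float = 0.05
    out_dir: str | None = None

    def validate(self) -> None:
        for p in (self.expression, self.interactions, self.anatomy,
                  *self.wired.values()):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.model not in ("long", "mid", "short", "contact"):
            raise ValueError(f"unknown model {self.model!r}")


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run(
    config: RunConfig,
    *,
    expr: ExpressionMatrix | None = None,
    entries: list[InteractionEntry] | None = None,
    annotations: dict[str, NeuronAnnotation] | None = None,
) -> dict:
    """Execute the full pipeline and return the report dict.

    Inputs may be passed in memory (synthetic runs) or read from the paths
    in ``config``; in-memory objects win.
    """
    t0 = time.time()
    config.validate()
    if expr is None:
        roster = canonical_roster()
        expr = load_expression(config.expression, roster,
                               threshold_level=config.expression_threshold)
    roster = expr.roster
    if entries is None:
        entries = load_interactions(config.interactions, ec50_unit=config.ec50_unit)
    if annotations is None:
        annotations = load_annotations(config.anatomy, roster)

    report: dict = {
        "config": {
            "ec50_max": config.ec50_max, "model": config.model,
            "n_null": config.n_null, "swaps_per_edge": config.swaps_per_edge,
            "seed": config.seed, "perplexity": config.perplexity,
            "coexpression_alpha": config.coexpression_alpha,
            "expression_threshold": expr.threshold_level,
        },
        "stages": {},
        "errors": {},
    }

    def stage(name):
        def deco(fn):
            t = time.time()
            try:
                report["stages"][name] = fn()
                log.info("stage %s done in %.2fs", name, time.time() - t)
            except Exception as e:  # independent stages keep running
                log.warning("stage %s failed: %s", name, e)
                report["errors"][name] = f"{type(e).__name__}: {e}"
            return fn
        return deco

    # --- build -------------------------------------------------------
    couples = couples_at_threshold(entries, config.ec50_max)
    index = nb.SpatialIndex(annotations, roster)
    couples = [c for c in couples
               if c.npp_gene in expr and c.gpcr_gene in expr]
    long_nets = [nb.build_pair_network(expr, c) for c in couples]
    nets = [nb.apply_spatial_filter(nv, config.model, index)
            for nv in long_nets]
    agg = nb.aggregate(nets, config.model)
    hist, argmax = nb.edge_weight_distribution(agg)
    n_single = sum(1 for nv in nets if nv.n_components() == 1)
    report["stages"]["build"] = {
        "n_couples": len(couples),
        "n_single_component_couples": n_single,
        "edge_weight_histogram": hist,
        "max_weight_edges": argmax[:20],
        "adjacency_hash": _hash(agg.W.tolist()),
    }

    A = agg.binary()

    @stage("metrics")
    def _metrics():
        m = tp.network_metrics(A)
        return {
            "N": m.N, "K": m.K, "density": m.density,
            "transitivity": m.transitivity, "reciprocity": m.reciprocity,
            "reciprocal_edges": m.reciprocal_edges,
        }

    deg = tp.degrees(A, names=roster.names)

    @stage("rich_club")
    def _rich_club():
        nulls, diag = tp.degree_preserving_nulls(
            A, n=config.n_null, swaps_per_edge=config.swaps_per_edge,
            seed=config.seed,
        )
        rc = tp.rich_club(
            A, nulls, names=roster.names,
            swaps_per_edge=config.swaps_per_edge, seed=config.seed,
        )
        out = {
            "onset_k": rc.onset_k, "n_members": len(rc.members),
            "members": list(rc.members), "n_null": rc.n_null,
            "min_realized_swaps": min(diag["realized_swaps"]),
        }
        if len(rc.member_indices) >= 2:
            out["club_density"] = tp.subnetwork_density(A, rc.member_indices)
        return out

    @stage("classify")
    def _classify():
        rows = []
        for c, nv in zip(couples, nets):
            tc = pt.classify_topology(expr, c)
            rows.append({
                "couple": str(c), "class": tc.value,
                "n_npp": tc.n_npp_neurons, "n_gpcr": tc.n_gpcr_neurons,
                "n_components": nv.n_components(),
            })
        counts: dict[str, int] = {}
        for r in rows:
            counts[r["class"]] = counts.get(r["class"], 0) + 1
        return {"couples": rows, "class_counts": counts}

    @stage("ranges")
    def _ranges():
        exclusive = pt.exclusive_couples(entries, config.ec50_max)
        exclusive = [c for c in exclusive
                     if c.npp_gene in expr and c.gpcr_gene in expr]
        recv = {c.gpcr_gene: pt.minimal_range(expr, c, index, "receiver_view")
                for c in exclusive}
        send = {c.npp_gene: pt.minimal_range(expr, c, index, "sender_view")
                for c in exclusive}
        return {
            "n_exclusive": len(exclusive),
            "receiver": pt.range_summary(recv),
            "sender": pt.range_summary(send),
        }

    @stage("mesoscale")
    def _mesoscale():
        coords = ms.embed(
            agg, method="tsne", perplexity=min(
                config.perplexity, (len(roster) - 1) / 3.001
            ),
            seed=config.seed,
        )
        labels = ms.cluster_embedding(coords, indegree=deg.k_in)
        gs = ms.group_statistics(labels, deg)
        D = ms.intergroup_connectivity(agg, labels)
        return {
            "labels": {n: str(l) for n, l in zip(roster.names, labels)},
            "group_stats": {k: v for k, v in gs.items() if k != "groups"},
            "intergroup_density": np.where(np.isnan(D), None, D).tolist(),
        }

    @stage("coexpress")
    def _coexpress():
        npp_genes = sorted({e.npp_gene for e in entries if e.npp_gene in expr})
        gpcr_genes = sorted({e.gpcr_gene for e in entries if e.gpcr_gene in expr})
        sig, tested = cx.enriched_pairs(
            expr, npp_genes, gpcr_genes, config.coexpression_alpha,
            couples=couples,
        )
        G = cx.cascade_network(sig, entries, ec50_max=config.ec50_max)
        import networkx as nx

        n_comp = (nx.number_weakly_connected_components(G)
                  if G.number_of_nodes() else 0)
        return {
            "n_tested": len(tested), "n_significant": len(sig),
            "n_cognate_significant": sum(1 for s in sig if s.cognate),
            "cascade_nodes": G.number_of_nodes(),
            "cascade_edges": G.number_of_edges(),
            "cascade_components": n_comp,
        }

    @stage("autocrine")
    def _autocrine():
        profiles, summary = cx.autocrine_profiles(expr, couples)
        corr = cx.autocrine_degree_correlation(
            profiles, {"neuropeptide": deg}, roster.names
        )
        return {
            "fraction_with_autocrine": summary["fraction_with_autocrine"],
            "percent_by_type": summary["percent_by_type"],
            "degree_correlation": corr,
        }

    report["runtime_s"] = time.time() - t0
    report["report_hash"] = _hash(
        {k: v for k, v in report["stages"].items() if k != "mesoscale"}
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=str)
        )
        write_aggregate(agg, out)
    return report


def write_aggregate(agg: nb.AggregateNetwork, out_dir: str | Path) -> None:
    """Write the aggregate network as edge list, adjacency CSV and GraphML."""
    import networkx as nx
    import pandas as pd

    out = Path(out_dir)
    names = agg.roster.names if agg.roster else tuple(
        str(i) for i in range(agg.W.shape[0])
    )
    ii, jj = np.nonzero(agg.W)
    pd.DataFrame({
        "pre": [names[i] for i in ii],
        "post": [names[j] for j in jj],
        "weight": agg.W[ii, jj],
    }).to_csv(out / f"aggregate_{agg.model}_edges.csv", index=False)
    pd.DataFrame(agg.W, index=list(names), columns=list(names)).to_csv(
        out / f"aggregate_{agg.model}_adjacency.csv"
    )
    G = nx.from_numpy_array(agg.W, create_using=nx.DiGraph)
    nx.relabel_nodes(G, dict(enumerate(names)), copy=False)
    nx.write_graphml(G, out / f"aggregate_{agg.model}.graphml")


def sensitivity_run(
    config: RunConfig,
    ec50_list: list[float],
    model_list: list[str],
    **inputs,
) -> list[dict]:
    """Compare headline statistics across EC50 thresholds and models."""
    if len(ec50_list) * len(model_list) < 2:
        raise ValueError("need at least 2 settings")
    rows = []
    for ec50 in ec50_list:
        for model in model_list:
            cfg = RunConfig(**{**config.__dict__, "ec50_max": ec50,
                               "model": model, "out_dir": None})
            rep = run(cfg, **inputs)
            met = rep["stages"].get("metrics", {})
            rc = rep["stages"].get("rich_club", {})
            rows.append({
                "ec50_max": ec50, "model": model,
                "density": met.get("density"), "K": met.get("K"),
                "rich_club_size": rc.get("n_members"),
            })
    return rows
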