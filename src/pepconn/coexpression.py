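"""Ligand-receptor co-expression enrichment, signaling cascades, and
autocrine loops.

For every (precursor gene, receptor gene) combination in the interaction
dataset's gene universe, a one-sided Fisher exact test asks whether the two
genes co-occur in more neurons than expected from their marginal expression
frequencies over the 302-neuron panel; Benjamini-Hochberg correction
controls the FDR across the full universe. Enriched pairs become nodes of a
cascade network, with a directed edge whenever one node's ligand activates
another node's receptor — chains of such nodes are candidate neuroendocrine
signaling cascades. Co-expression of a ligand with its own cognate receptor
in one neuron is an autocrine loop (a self-edge of the connectome).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, GeneCouple, InteractionEntry


@dataclass
class CoexpressionPair:
    npp_gene: str
    gpcr_gene: str
    n11: int  # both expressed
    n10: int  # NPP only
    n01: int  # GPCR only
    n00: int  # neither
    p: float
    q: float = float("nan")
    cognate: bool = False


def fisher_enrichment(
    expr: ExpressionMatrix, npp_gene: str, gpcr_gene: str
) -> CoexpressionPair:
    """One-sided (enrichment) Fisher exact test for co-occurrence."""
    a = expr.row(npp_gene)
    b = expr.row(gpcr_gene)
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="greater")
    return CoexpressionPair(
        npp_gene=npp_gene, gpcr_gene=gpcr_gene,
        n11=n11, n10=n10, n01=n01, n00=n00, p=float(p),
    )


def randomized_pvalue(
    pair: CoexpressionPair, rng: np.random.Generator
) -> float:
    """Randomized (fuzzy) p-value transform of the exact enrichment test.

    Discrete exact tests produce sub-uniform p-values; the transform
    p' = p - U * pmf(observed), with U ~ Uniform(0, 1), is exactly uniform
    under the null for a valid test and is the standard way to verify
    calibration of a discrete test. Used for diagnostics only — analyses
    consume the exact conservative p.
    """
    N = pair.n11 + pair.n10 + pair.n01 + pair.n00
    R1 = pair.n11 + pair.n10
    C1 = pair.n11 + pair.n01
    point = stats.hypergeom.pmf(pair.n11, N, R1, C1)
    return float(pair.p - rng.random() * point)


def enriched_pairs(
    expr: ExpressionMatrix,
    npp_genes: list[str],
    gpcr_genes: list[str],
    alpha: float,
    couples: list[GeneCouple] | None = None,
) -> tuple[list[CoexpressionPair], list[CoexpressionPair]]:
    """BH-corrected enrichment over the full NPP x GPCR gene universe.

    Returns ``(significant, all_tested)``; significant pairs have q <=
    ``alpha`` and carry a ``cognate`` flag marking membership in the active
    couple set.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cognate_keys = {c.key for c in couples} if couples else set()
    tested: list[CoexpressionPair] = []
    for n in npp_genes:
        for g in gpcr_genes:
            pair = fisher_enrichment(expr, n, g)
            pair.cognate = (n, g) in cognate_keys
            tested.append(pair)
    if not tested:
        return [], []
    pvals = np.array([t.p for t in tested])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for t, q in zip(tested, qvals):
        t.q = float(q)
    significant = [t for t in tested if t.q <= alpha]
    return significant, tested


def cascade_network(
    enriched: list[CoexpressionPair],
    entries: list[InteractionEntry],
    ec50_max: float | None = None,
) -> nx.DiGraph:
    """Directed cascade graph over enriched co-expression pairs.

    Nodes are (NPP, GPCR) co-expression pairs; an edge u -> v is drawn when
    u's ligand gene activates v's receptor gene in the interaction data
    (gene-level linking, optionally restricted to entries with EC50 <=
    ``ec50_max``).
    """
    active = {
        (e.npp_gene, e.gpcr_gene)
        for e in entries
        if ec50_max is None or e.ec50 <= ec50_max
    }
    G = nx.DiGraph()
    nodes = [(p.npp_gene, p.gpcr_gene) for p in enriched]
    G.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and (u[0], v[1]) in active:
                G.add_edge(u, v)
    return G


@dataclass
class AutocrineProfile:
    neuron: str
    couples: frozenset[GeneCouple]

    @property
    def count(self) -> int:
        return len(self.couples)


def autocrine_profiles(
    expr: ExpressionMatrix, couples: list[GeneCouple]
) -> tuple[dict[str, AutocrineProfile], dict]:
    """Per-neuron autocrine couple sets and a nervous-system summary.

    A neuron harbors an autocrine loop for a couple when it expresses both
    the ligand and the receptor gene. The summary reports the fraction of
    neurons with at least one loop, per-type percentages, and per-couple
    neuron counts.
    """
    roster = expr.roster
    names = roster.names
    per_neuron: dict[str, set[GeneCouple]] = {n: set() for n in names}
    per_couple: dict[str, int] = {}
    for c in couples:
        both = expr.row(c.npp_gene) & expr.row(c.gpcr_gene)
        per_couple[str(c)] = int(both.sum())
        for i in np.nonzero(both)[0]:
            per_neuron[names[i]].add(c)
    profiles = {
        n: AutocrineProfile(neuron=n, couples=frozenset(s))
        for n, s in per_neuron.items()
    }
    flagged = [n for n in names if profiles[n].count > 0]
    by_type: dict[str, float] = {}
    for t in set(roster.type_of.values()):
        members = [n for n in names if roster.type_of[n] == t]
        with_loops = sum(1 for n in members if profiles[n].count > 0)
        by_type[t] = 100.0 * with_loops / len(members) if members else 0.0
    summary = {
        "fraction_with_autocrine": len(flagged) / len(names),
        "percent_by_type": by_type,
        "per_couple_counts": per_couple,
        "n_neurons_flagged": len(flagged),
    }
    return profiles, summary


def autocrine_degree_correlation(
    profiles: dict[str, AutocrineProfile],
    degree_tables: dict[str, "DegreeTable"],
    roster_names: tuple[str, ...],
    permutations: int = 0,
    seed: int = 0,
) -> dict[str, dict]:
    """Correlate per-neuron autocrine diversity with network degrees.

    For each supplied network, reports Pearson r (and two-sided p) of the
    autocrine couple count against total, in- and out-degree; with
    ``permutations`` > 0 adds a permutation p-value for the total-degree
    correlation.
    """
    counts = np.array([profiles[n].count for n in roster_names], dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for name, dt in degree_tables.items():
        res: dict[str, float] = {}
        for key, vec in (("k", dt.k), ("k_in", dt.k_in), ("k_out", dt.k_out)):
            v = vec.astype(float)
            if np.std(v) == 0 or np.std(counts) == 0:
                res[f"r_{key}"] = float("nan")
                res[f"p_{key}"] = float("nan")
                res[f"degenerate_{key}"] = True
                continue
            r, p = stats.pearsonr(counts, v)
            res[f"r_{key}"] = float(r)
            res[f"p_{key}"] = float(p)
        if permutations > 0 and not res.get("degenerate_k"):
            obs = res["r_k"]
            null = np.empty(permutations)
            v = dt.k.astype(float)
            for b in range(permutations):
                null[b] = np.corrcoef(rng.permutation(counts), v)[0, 1]
            res["perm_p_k"] = float(
                (np.sum(np.abs(null) >= abs(obs)) + 1) / (permutations + 1)
            )
        out[name] = res
    return out
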