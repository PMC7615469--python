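"""Synthetic expression / interaction / anatomy triples with ground truth.

The generator emulates the statistical shape of the three inputs the
connectome pipeline consumes — a binary gene x neuron expression matrix
with log-normal per-gene breadth, a peptide-receptor interaction table with
log-uniform EC50s and configurable receptor promiscuity, and per-neuron
anatomy (process bundles mapped to body regions, a nerve ring with four
strata, and a separated pharynx) — while planting motifs whose downstream
signatures are known by construction: broadcaster/integrative couples, a
densely interwired rich-club hub set, enriched co-expressed gene pairs and
autocrine loops. Every output is loadable by the package's readers, and the
returned ground-truth record lists each planted motif so recovery can be
scored exactly.

Bundle regions are assigned per bundle and neurons inherit the region of
their bundles (extra bundles are drawn within-region), so the spatial
models nest by construction: contact implies shared bundle, shared bundle
implies shared region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionMatrix, InteractionEntry, NeuronAnnotation
from .io import NERVE_RING_BUNDLE, PHARYNX_BUNDLE
from .roster import NeuronRoster


def synthetic_roster(n_neurons: int) -> NeuronRoster:
    """A neutral n-neuron roster (one class per neuron, cycled types)."""
    names = tuple(f"N{i:03d}" for i in range(n_neurons))
    types = ("sensory", "interneuron", "motor")
    return NeuronRoster(
        names=names,
        class_of={n: n for n in names},
        type_of={n: types[i % 3] for i, n in enumerate(names)},
    )


@dataclass
class SynthConfig:
    """Study conditions for the generator; defaults mirror the real inputs
    (302 neurons, 55 precursor and 56 receptor genes, 27 bundles, 4 nerve
    ring strata, EC50s spanning pM to uM)."""

    n_neurons: int = 302
    n_npp: int = 55
    n_gpcr: int = 56
    # per-gene expressing-neuron count: round(lognormal), clipped to [1, n]
    breadth_log_mean: float = 2.5
    breadth_log_sigma: float = 1.0
    ec50_log10_range: tuple[float, float] = (-12.0, -6.0)
    mean_ligands_per_receptor: float = 2.6
    n_bundles: int = 27
    region_props: dict = field(
        default_factory=lambda: {"head": 0.60, "midbody": 0.15, "tail": 0.25}
    )
    n_strata: int = 4
    frac_pharynx: float = 20 / 302
    # most neurons project into the nerve ring, the dominant neuropil
    nerve_ring_weight: float = 0.6
    extra_bundle_prob: float = 0.3
    # planted motifs (all off by default)
    n_broadcaster: int = 0
    broadcaster_npp_breadth: int = 5
    broadcaster_gpcr_breadth: int = 120
    n_integrative: int = 0
    integrative_npp_breadth: int = 120
    integrative_gpcr_breadth: int = 5
    rich_club_h: int = 0
    rich_club_density: float = 1.0
    rich_club_couples: int = 3
    n_enriched_pairs: int = 0
    enriched_overlap: int = 20
    n_autocrine_neurons: int = 0
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SynthConfig.seed is mandatory")
        n = self.n_neurons
        checks = [("rich_club_h", self.rich_club_h, self.rich_club_h > 0),
                  ("n_autocrine_neurons", self.n_autocrine_neurons, True)]
        if self.n_broadcaster > 0:
            checks += [("broadcaster_npp_breadth", self.broadcaster_npp_breadth, True),
                       ("broadcaster_gpcr_breadth", self.broadcaster_gpcr_breadth, True)]
        if self.n_integrative > 0:
            checks += [("integrative_npp_breadth", self.integrative_npp_breadth, True),
                       ("integrative_gpcr_breadth", self.integrative_gpcr_breadth, True)]
        if self.n_enriched_pairs > 0:
            checks += [("enriched_overlap", self.enriched_overlap, True)]
        for name, v, active in checks:
            if active and not 0 <= v <= n:
                raise ValueError(
                    f"{name}={v} exceeds n_neurons={n}; motif demands "
                    "cannot exceed the neuron count"
                )


def _sample_breadth(cfg: SynthConfig, rng: np.random.Generator) -> int:
    b = int(round(rng.lognormal(cfg.breadth_log_mean, cfg.breadth_log_sigma)))
    return int(np.clip(b, 1, cfg.n_neurons))


def _sample_ec50(cfg: SynthConfig, rng: np.random.Generator) -> float:
    lo, hi = cfg.ec50_log10_range
    return float(10.0 ** rng.uniform(lo, hi))


def generate(
    cfg: SynthConfig,
) -> tuple[ExpressionMatrix, list[InteractionEntry], dict[str, NeuronAnnotation], dict]:
    """Draw one synthetic dataset; byte-identical given the same config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    roster = synthetic_roster(cfg.n_neurons)
    n = cfg.n_neurons
    names = roster.names

    # ---- anatomy -----------------------------------------------------
    regions = list(cfg.region_props)
    probs = np.array([cfg.region_props[r] for r in regions], dtype=float)
    probs = probs / probs.sum()
    bundle_names = [PHARYNX_BUNDLE, NERVE_RING_BUNDLE] + [
        f"bundle_{k:02d}" for k in range(3, cfg.n_bundles + 1)
    ]
    bundle_region = {PHARYNX_BUNDLE: "head", NERVE_RING_BUNDLE: "head"}
    other = bundle_names[2:]
    # guarantee each region owns at least one non-pharynx bundle
    for k, b in enumerate(other):
        if k < len(regions):
            bundle_region[b] = regions[k]
        else:
            bundle_region[b] = regions[int(rng.choice(len(regions), p=probs))]

    # primary-bundle weights: pharynx fixed fraction, nerve ring heavy
    w = np.empty(len(bundle_names))
    w[0] = cfg.frac_pharynx
    w[1] = (1 - cfg.frac_pharynx) * cfg.nerve_ring_weight
    w[2:] = (1 - w[0] - w[1]) / len(other)
    w = w / w.sum()
    by_region: dict[str, list[str]] = {r: [] for r in regions}
    for b in other:
        by_region[bundle_region[b]].append(b)

    ann: dict[str, NeuronAnnotation] = {}
    for name in names:
        primary = bundle_names[int(rng.choice(len(bundle_names), p=w))]
        if primary == PHARYNX_BUNDLE:
            ann[name] = NeuronAnnotation(
                neuron=name, bundles=frozenset({PHARYNX_BUNDLE}),
                region="head", strata=frozenset(), in_pharynx=True,
            )
            continue
        region = bundle_region[primary]
        bundles = {primary}
        if rng.random() < cfg.extra_bundle_prob:
            pool = [b for b in by_region[region] if b != primary]
            if region == "head" and primary != NERVE_RING_BUNDLE:
                pool.append(NERVE_RING_BUNDLE)
            if pool:
                bundles.add(pool[int(rng.integers(len(pool)))])
        strata: frozenset[int] = frozenset()
        if NERVE_RING_BUNDLE in bundles:
            k = 1 if rng.random() < 0.7 else 2
            strata = frozenset(
                int(s) + 1
                for s in rng.choice(cfg.n_strata, size=k, replace=False)
            )
        ann[name] = NeuronAnnotation(
            neuron=name, bundles=frozenset(bundles), region=region,
            strata=strata, in_pharynx=False,
        )

    # ---- expression --------------------------------------------------
    genes: list[str] = []
    rows: list[np.ndarray] = []

    def add_gene(gene: str, neuron_idx: np.ndarray) -> None:
        row = np.zeros(n, dtype=bool)
        row[neuron_idx] = True
        genes.append(gene)
        rows.append(row)

    npp_genes = [f"npp_{k:03d}" for k in range(1, cfg.n_npp + 1)]
    gpcr_genes = [f"gpcr_{k:03d}" for k in range(1, cfg.n_gpcr + 1)]
    for g in npp_genes + gpcr_genes:
        b = _sample_breadth(cfg, rng)
        add_gene(g, rng.choice(n, size=b, replace=False))

    # ---- interactions ------------------------------------------------
    entries: list[InteractionEntry] = []
    for g in gpcr_genes:
        n_lig = 1 + rng.poisson(max(cfg.mean_ligands_per_receptor - 1, 0))
        n_lig = min(n_lig, len(npp_genes))
        partners = rng.choice(len(npp_genes), size=n_lig, replace=False)
        for pi in partners:
            npp = npp_genes[pi]
            for pep in range(1 + int(rng.random() < 0.3)):
                entries.append(
                    InteractionEntry(
                        peptide_id=f"{npp}_pep{pep + 1}",
                        npp_gene=npp, gpcr_gene=g,
                        ec50=_sample_ec50(cfg, rng),
                    )
                )

    truth: dict = {
        "roster": list(names),
        "broadcasters": [], "integrative": [], "rich_club_hubs": [],
        "rich_club_couples": [], "enriched_pairs": [], "autocrine": None,
    }
    strong = 1e-9  # EC50 well below any sensible couple threshold

    def plant_couple(tag: str, npp_breadth: int, gpcr_breadth: int) -> tuple[str, str]:
        npp, gpcr = f"npp_{tag}", f"gpcr_{tag}"
        add_gene(npp, rng.choice(n, size=npp_breadth, replace=False))
        add_gene(gpcr, rng.choice(n, size=gpcr_breadth, replace=False))
        entries.append(
            InteractionEntry(
                peptide_id=f"{npp}_pep1", npp_gene=npp, gpcr_gene=gpcr,
                ec50=strong,
            )
        )
        npp_genes.append(npp)
        gpcr_genes.append(gpcr)
        return npp, gpcr

    for k in range(cfg.n_broadcaster):
        truth["broadcasters"].append(
            plant_couple(
                f"bcast{k + 1}", cfg.broadcaster_npp_breadth,
                cfg.broadcaster_gpcr_breadth,
            )
        )
    for k in range(cfg.n_integrative):
        truth["integrative"].append(
            plant_couple(
                f"integ{k + 1}", cfg.integrative_npp_breadth,
                cfg.integrative_gpcr_breadth,
            )
        )

    # enriched co-expression: non-cognate gene pairs sharing a neuron set
    for k in range(cfg.n_enriched_pairs):
        overlap = rng.choice(n, size=cfg.enriched_overlap, replace=False)
        npp, gpcr = f"npp_coex{k + 1}", f"gpcr_coex{k + 1}"
        add_gene(npp, overlap)
        add_gene(gpcr, overlap)
        npp_genes.append(npp)
        gpcr_genes.append(gpcr)
        truth["enriched_pairs"].append((npp, gpcr))

    # autocrine loop: one cognate couple co-expressed in exactly m neurons
    if cfg.n_autocrine_neurons > 0:
        loop_neurons = rng.choice(n, size=cfg.n_autocrine_neurons, replace=False)
        npp, gpcr = "npp_auto", "gpcr_auto"
        add_gene(npp, loop_neurons)
        add_gene(gpcr, loop_neurons)
        entries.append(
            InteractionEntry(
                peptide_id="npp_auto_pep1", npp_gene=npp, gpcr_gene=gpcr,
                ec50=strong,
            )
        )
        npp_genes.append(npp)
        gpcr_genes.append(gpcr)
        truth["autocrine"] = {
            "couple": (npp, gpcr),
            "neurons": sorted(names[i] for i in loop_neurons),
        }

    expr = ExpressionMatrix(
        genes=genes, roster=roster, X=np.vstack(rows), threshold_level=4
    )

    truth["npp_genes"] = list(npp_genes)
    truth["gpcr_genes"] = list(gpcr_genes)

    if cfg.rich_club_h > 0:
        expr, entries, truth = plant_rich_club(
            expr, entries, truth,
            h=cfg.rich_club_h,
            wiring_density=cfg.rich_club_density,
            n_couples=cfg.rich_club_couples,
            rng=rng,
        )
    return expr, entries, ann, truth


def planted_block_network(
    sizes: list[int],
    P: np.ndarray,
    seed: int,
    n_periphery: int = 0,
):
    """Directed block-model adjacency with an optional diffuse periphery.

    ``P[a, b]`` is the edge probability from block ``a`` to block ``b``.
    Periphery neurons, appended after the blocks, have no shared incoming
    pattern: each draws its own random per-block incoming rate, emulating
    the loose cloud of variably-connected neurons around the cores.
    Returns ``(AggregateNetwork, true_labels)`` with labels 0..len(sizes)-1
    for blocks and -1 for periphery.
    """
    from .build import AggregateNetwork

    rng = np.random.default_rng(seed)
    P = np.asarray(P, dtype=float)
    labels = np.concatenate(
        [np.repeat(np.arange(len(sizes)), sizes), -np.ones(n_periphery, int)]
    )
    n = len(labels)
    prob = np.zeros((n, n))
    block = labels >= 0
    prob[np.ix_(block, block)] = P[labels[block]][:, labels[block]]
    if n_periphery:
        # each periphery neuron has its own overall incoming/outgoing rate,
        # spreading the cloud along a density axis instead of a tight island
        per = ~block
        r_in = rng.uniform(0.05, 0.7, size=n_periphery)
        r_out = rng.uniform(0.05, 0.7, size=n_periphery)
        prob[:, per] = r_in[None, :]
        prob[per, :] = r_out[:, None]
        prob[np.ix_(per, per)] = np.minimum(r_out[:, None], r_in[None, :])
    W = (rng.random((n, n)) < prob).astype(int)
    np.fill_diagonal(W, 0)
    return (
        AggregateNetwork(
            model="long", W=W, roster=synthetic_roster(n)
        ),
        labels,
    )


def plant_rich_club(
    expr: ExpressionMatrix,
    entries: list[InteractionEntry],
    truth: dict,
    h: int,
    wiring_density: float = 1.0,
    n_couples: int = 3,
    rng: np.random.Generator | int = 0,
) -> tuple[ExpressionMatrix, list[InteractionEntry], dict]:
    """Overwire ``h`` designated neurons into a dense peptidergic core.

    Adds ``n_couples`` dedicated cognate couples whose ligand and receptor
    are expressed only within the hub set; each hub joins a couple's sender
    and receiver sets independently with probability q, solved so the
    expected hub-to-hub edge coverage equals ``wiring_density``. With
    density 1 every couple covers the whole hub set, producing a complete
    digraph among hubs.
    """
    if h == 0:
        return expr, entries, truth
    n = len(expr.roster)
    if h >= n:
        raise ValueError(f"rich-club size {h} must be below n_neurons={n}")
    if not 0 < wiring_density <= 1:
        raise ValueError("wiring_density must be in (0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    hubs = np.sort(rng.choice(n, size=h, replace=False))
    if wiring_density == 1.0:
        q = 1.0
    else:
        q = float(np.sqrt(1 - (1 - wiring_density) ** (1 / n_couples)))
    genes = list(expr.genes)
    X = expr.X
    new_rows = []
    entries = list(entries)
    couples = []
    for k in range(n_couples):
        send = hubs[rng.random(h) < q] if q < 1 else hubs
        recv = hubs[rng.random(h) < q] if q < 1 else hubs
        npp, gpcr = f"npp_rc{k + 1}", f"gpcr_rc{k + 1}"
        for g, idx in ((npp, send), (gpcr, recv)):
            row = np.zeros(n, dtype=bool)
            row[idx] = True
            genes.append(g)
            new_rows.append(row)
        entries.append(
            InteractionEntry(
                peptide_id=f"{npp}_pep1", npp_gene=npp, gpcr_gene=gpcr,
                ec50=1e-9,
            )
        )
        couples.append((npp, gpcr))
    X = np.vstack([X] + new_rows) if new_rows else X
    expr = ExpressionMatrix(
        genes=genes, roster=expr.roster, X=X,
        threshold_level=expr.threshold_level,
    )
    truth = dict(truth)
    truth["rich_club_hubs"] = sorted(expr.roster.names[i] for i in hubs)
    truth["rich_club_couples"] = couples
    truth.setdefault("npp_genes", [])
    truth.setdefault("gpcr_genes", [])
    for npp, gpcr in couples:
        if npp not in truth["npp_genes"]:
            truth["npp_genes"].append(npp)
        if gpcr not in truth["gpcr_genes"]:
            truth["gpcr_genes"].append(gpcr)
    return expr, entries, truth
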