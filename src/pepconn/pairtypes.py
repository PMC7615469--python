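"""Per-couple network topology classes and diffusion-range requirements.

A couple's network shape is driven by how broadly its two genes are
expressed. With a breadth cutoff of 50 neurons (out of 302):

* ``local`` — both ligand and receptor restricted (<= 50 neurons each);
* ``pervasive`` — both broad (> 50);
* ``broadcaster`` — broad receptor, restricted ligand (few senders reach
  many receivers);
* ``integrative`` — broad ligand, restricted receptor (many senders
  converge on few receivers).

Breadth is measured on raw expression (the unfiltered long-range network),
since it describes where the genes are made, not which edges survive a
diffusion model.

The diffusion-range analysis asks, for couples whose ligand and receptor
are mutually exclusive partners, how far a peptide must travel for every
receptor-bearing neuron to hear its ligand (receiver view) or for every
ligand-bearing neuron to reach a receptor (sender view). Ranges are
ordered: contact within a nerve-ring stratum < contact within a thin
bundle < short (same bundle) < mid (same body region) < long.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .build import SpatialIndex
from .core import ExpressionMatrix, GeneCouple, InteractionEntry, couples_at_threshold

TOPOLOGY_CLASSES = ("local", "pervasive", "broadcaster", "integrative")
BREADTH_CUTOFF = 50

RANGE_CLASSES = (
    "contact_stratum", "contact_thin_bundle", "short", "mid", "long",
    "unreachable",
)


@dataclass(frozen=True)
class TopologyClass:
    value: str
    n_npp_neurons: int
    n_gpcr_neurons: int


def classify_topology(
    expr: ExpressionMatrix, couple: GeneCouple, cutoff: int = BREADTH_CUTOFF
) -> TopologyClass:
    """Classify a couple by ligand/receptor expression breadth."""
    n_npp = expr.n_expressing(couple.npp_gene)
    n_gpcr = expr.n_expressing(couple.gpcr_gene)
    broad_npp, broad_gpcr = n_npp > cutoff, n_gpcr > cutoff
    if broad_npp and broad_gpcr:
        value = "pervasive"
    elif broad_gpcr:
        value = "broadcaster"
    elif broad_npp:
        value = "integrative"
    else:
        value = "local"
    return TopologyClass(value=value, n_npp_neurons=n_npp, n_gpcr_neurons=n_gpcr)


def exclusive_couples(
    entries: list[InteractionEntry], ec50_max: float
) -> list[GeneCouple]:
    """Couples whose ligand and receptor are each other's only partner.

    Exclusivity is evaluated on the gene-level couple set at the active
    EC50 threshold: the receptor gene has exactly one ligand gene and that
    ligand activates exactly one receptor gene.
    """
    couples = couples_at_threshold(entries, ec50_max)
    n_ligands: dict[str, int] = {}
    n_receptors: dict[str, int] = {}
    for c in couples:
        n_ligands[c.gpcr_gene] = n_ligands.get(c.gpcr_gene, 0) + 1
        n_receptors[c.npp_gene] = n_receptors.get(c.npp_gene, 0) + 1
    return [
        c for c in couples
        if n_ligands[c.gpcr_gene] == 1 and n_receptors[c.npp_gene] == 1
    ]


def _range_masks(index: SpatialIndex) -> list[tuple[str, np.ndarray]]:
    """(class, allowed-pair mask) in increasing diffusion order.

    Sub-contact classes reuse the contact machinery: stratum contact is the
    shared-stratum component, thin-bundle contact the shared thin bundle
    component; both respect pharynx separation via the contact mask.
    """
    return [
        ("contact_stratum", index.stratum_mask()),
        ("contact_thin_bundle", index.thin_bundle_mask()),
        ("short", index.mask("short")),
        ("mid", index.mask("mid")),
        ("long", index.mask("long")),
    ]


def minimal_range(
    expr: ExpressionMatrix,
    couple: GeneCouple,
    index: SpatialIndex,
    direction: str = "receiver_view",
) -> dict[str, str]:
    """Smallest diffusion class letting each focal neuron reach a partner.

    ``receiver_view`` asks for each receptor-expressing neuron the minimal
    class under which some ligand-expressing neuron can signal to it;
    ``sender_view`` is the converse for ligand-expressing neurons.
    """
    if direction not in ("receiver_view", "sender_view"):
        raise ValueError("direction must be 'receiver_view' or 'sender_view'")
    roster = expr.roster
    if direction == "receiver_view":
        focal = expr.row(couple.gpcr_gene)
        partner = expr.row(couple.npp_gene)
    else:
        focal = expr.row(couple.npp_gene)
        partner = expr.row(couple.gpcr_gene)
    out: dict[str, str] = {}
    focal_idx = np.nonzero(focal)[0]
    if not partner.any():
        return {roster.names[i]: "unreachable" for i in focal_idx}
    for cls, mask in _range_masks(index):
        # reachability is symmetric in sender/receiver for these masks
        reach = mask[:, focal_idx] if direction == "receiver_view" else mask[focal_idx, :].T
        hit = (reach & partner[:, None]).any(axis=0)
        for i, ok in zip(focal_idx, hit):
            name = roster.names[i]
            if ok and name not in out:
                out[name] = cls
    for i in focal_idx:
        out.setdefault(roster.names[i], "unreachable")
    return out


def range_summary(
    matrices: dict[str, dict[str, str]]
) -> dict[str, object]:
    """Per-gene flags and totals for ranges beyond contact and beyond short.

    ``matrices`` maps a focal gene to its neuron -> minimal-class row (the
    output of :func:`minimal_range`).
    """
    beyond_contact = {}
    beyond_short = {}
    order = {c: i for i, c in enumerate(RANGE_CLASSES)}
    for gene, row in matrices.items():
        ranks = [order[c] for c in row.values()]
        beyond_contact[gene] = any(
            r > order["contact_thin_bundle"] for r in ranks
        )
        beyond_short[gene] = any(r > order["short"] for r in ranks)
    return {
        "beyond_contact": beyond_contact,
        "beyond_short": beyond_short,
        "n_beyond_contact": sum(beyond_contact.values()),
        "n_beyond_short": sum(beyond_short.values()),
        "n_genes": len(matrices),
    }
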