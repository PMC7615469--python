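"""Build per-couple signaling networks and the aggregate connectome.

A single ligand-receptor gene couple induces a directed network: neuron i
signals to neuron j when i expresses the precursor gene and j expresses the
receptor gene, A(i, j) = NPP(i) * GPCR(j). Four diffusion models then
restrict which (i, j) pairs are anatomically plausible:

* ``long`` — no restriction; peptides may reach any neuron.
* ``mid`` — sender and receiver processes must lie in the same body region
  (head, midbody, tail), with the pharynx counted as part of the head.
* ``short`` — processes must share a bundle; the pharynx is treated as a
  separate system whose neurons connect only to each other.
* ``contact`` — processes must share a nerve-ring stratum or a thin
  (non-nerve-ring) bundle, i.e. be in physical contact.

Self-connections always pass every model (same neuron, same location); they
are kept during construction and zeroed only when topology metrics are
computed. The aggregate network sums the binary per-couple adjacencies, so
an edge weight counts the distinct ligand-receptor channels between a
neuron pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionMatrix, GeneCouple, NeuronAnnotation, WiredNetwork, SPATIAL_MODELS, REGIONS
from .io import NERVE_RING_BUNDLE
from .roster import NeuronRoster


class SpatialIndex:
    """Vectorized allowed-pair masks for the four diffusion models.

    Built once from per-neuron annotations; ``mask(model)`` returns the
    boolean roster x roster matrix of anatomically permitted sender ->
    receiver pairs (diagonal always True).
    """

    def __init__(
        self, ann: dict[str, NeuronAnnotation], roster: NeuronRoster
    ) -> None:
        missing = sorted(set(roster.names) - set(ann))
        if missing:
            raise ValueError(f"annotations missing for neurons: {missing[:10]}")
        self.roster = roster
        n = len(roster)
        bundles = sorted({b for a in ann.values() for b in a.bundles})
        b_idx = {b: k for k, b in enumerate(bundles)}
        B = np.zeros((n, len(bundles)), dtype=bool)
        S = np.zeros((n, 4), dtype=bool)  # strata 1..4
        region = np.zeros(n, dtype=int)
        in_ph = np.zeros(n, dtype=bool)
        for i, name in enumerate(roster.names):
            a = ann[name]
            for b in a.bundles:
                B[i, b_idx[b]] = True
            for s in a.strata:
                S[i, s - 1] = True
            region[i] = REGIONS.index(a.region)
            in_ph[i] = a.in_pharynx
        thin = np.array([b != NERVE_RING_BUNDLE for b in bundles])
        self._masks: dict[str, np.ndarray] = {}
        self._masks["long"] = np.ones((n, n), dtype=bool)
        self._masks["mid"] = region[:, None] == region[None, :]
        same_ph = in_ph[:, None] == in_ph[None, :]
        share_bundle = B @ B.T
        self._masks["short"] = share_bundle & same_ph
        share_thin = (B[:, thin] @ B[:, thin].T) & same_ph
        share_stratum = (S @ S.T) & same_ph
        self._masks["contact"] = share_thin | share_stratum
        self._share_thin = share_thin
        self._share_stratum = share_stratum
        for m in (*self._masks.values(), share_thin, share_stratum):
            np.fill_diagonal(m, True)

    def mask(self, model: str) -> np.ndarray:
        if model not in SPATIAL_MODELS:
            raise ValueError(f"unknown model {model!r}; expected {SPATIAL_MODELS}")
        return self._masks[model]

    def stratum_mask(self) -> np.ndarray:
        """Pairs in physical contact through a shared nerve-ring stratum."""
        return self._share_stratum

    def thin_bundle_mask(self) -> np.ndarray:
        """Pairs in physical contact through a shared thin process bundle."""
        return self._share_thin


def spatial_predicate(
    i: str, j: str, model: str, index: SpatialIndex
) -> bool:
    """Whether neuron ``i`` may signal to neuron ``j`` under ``model``."""
    idx = index.roster.index()
    try:
        a, b = idx[i], idx[j]
    except KeyError as e:
        raise ValueError(f"neuron {e.args[0]!r} not annotated") from None
    return bool(index.mask(model)[a, b])


@dataclass
class PairNetwork:
    """Binary directed network of one gene couple under one diffusion model."""

    couple: GeneCouple
    model: str
    A: np.ndarray
    roster: NeuronRoster

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=bool)
        n = len(self.roster)
        if self.A.shape != (n, n):
            raise ValueError(f"pair network must be {n}x{n}")
        if self.model not in SPATIAL_MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    def n_components(self) -> int:
        """Weakly connected components over neurons with >= 1 incident edge.

        Isolated (non-participating) neurons are ignored, so a couple whose
        genes are expressed nowhere has zero components.
        """
        import networkx as nx

        A = self.A.copy()
        np.fill_diagonal(A, False)
        deg = A.sum(0) + A.sum(1)
        # self-loop-only neurons still participate
        deg = deg + np.diag(self.A)
        keep = np.nonzero(deg > 0)[0]
        if keep.size == 0:
            return 0
        G = nx.from_numpy_array(
            self.A[np.ix_(keep, keep)], create_using=nx.DiGraph
        )
        return nx.number_weakly_connected_components(G)


def build_pair_network(
    expr: ExpressionMatrix, couple: GeneCouple
) -> PairNetwork:
    """Unfiltered (long-range) network of one couple: NPP(i) AND GPCR(j)."""
    send = expr.row(couple.npp_gene)
    recv = expr.row(couple.gpcr_gene)
    A = np.outer(send, recv)
    return PairNetwork(couple=couple, model="long", A=A, roster=expr.roster)


def apply_spatial_filter(
    net: PairNetwork, model: str, index: SpatialIndex
) -> PairNetwork:
    """Restrict a long-range pair network to a diffusion model's mask."""
    A = net.A & index.mask(model)
    return PairNetwork(couple=net.couple, model=model, A=A, roster=net.roster)


@dataclass
class AggregateNetwork:
    """Weighted sum of per-couple networks under a shared diffusion model."""

    model: str
    W: np.ndarray
    couples: list[GeneCouple] = field(default_factory=list)
    roster: NeuronRoster | None = None

    def binary(self, zero_diagonal: bool = True) -> np.ndarray:
        B = self.W > 0
        if zero_diagonal:
            B = B.copy()
            np.fill_diagonal(B, False)
        return B


def aggregate(nets: list[PairNetwork], model: str) -> AggregateNetwork:
    """Sum binary per-couple networks into the weighted connectome."""
    if not nets:
        return AggregateNetwork(model=model, W=np.zeros((0, 0), dtype=int))
    models = {n.model for n in nets}
    if models != {model}:
        raise ValueError(f"mixed models {sorted(models)}, expected {model!r}")
    W = np.zeros_like(nets[0].A, dtype=int)
    for n in nets:
        W += n.A
    return AggregateNetwork(
        model=model, W=W, couples=[n.couple for n in nets],
        roster=nets[0].roster,
    )


def edge_weight_distribution(
    agg: AggregateNetwork,
) -> tuple[dict[int, int], list[tuple[str, str]]]:
    """Histogram of off-diagonal edge weights, plus the heaviest edge(s)."""
    W = agg.W.copy()
    np.fill_diagonal(W, 0)
    vals = W[W > 0]
    hist = {int(w): int(c) for w, c in zip(*np.unique(vals, return_counts=True))}
    if not hist:
        return {}, []
    wmax = max(hist)
    names = agg.roster.names if agg.roster is not None else None
    ii, jj = np.nonzero(W == wmax)
    argmax = [
        (names[i], names[j]) if names else (int(i), int(j))
        for i, j in zip(ii, jj)
    ]
    return hist, argmax


def overlap_with_wired(
    agg: AggregateNetwork, wired: WiredNetwork
) -> dict[str, int]:
    """Directed off-diagonal co-occurrence counts with a wired connectome."""
    P = agg.binary()
    S = wired.binary()
    return {
        "both": int((P & S).sum()),
        "pept_only": int((P & ~S).sum()),
        "wired_only": int((~P & S).sum()),
    }
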