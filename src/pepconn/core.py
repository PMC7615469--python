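"""Core data types: expression matrices, ligand-receptor interactions,
per-neuron anatomy, and wired reference connectomes.

All adjacency-shaped data is indexed against the canonical
:class:`~pepconn.roster.NeuronRoster` order. Expression is strictly binary
(a gene is called expressed in a neuron or not); ligand-receptor entries
carry in vitro EC50 potencies in molar units and are reduced to gene-level
couples by thresholding on EC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roster import NeuronRoster

SPATIAL_MODELS = ("long", "mid", "short", "contact")
REGIONS = ("head", "midbody", "tail")


@dataclass
class ExpressionMatrix:
    """Binary gene x neuron expression calls over the fixed roster.

    ``X[g, i]`` is True when gene ``genes[g]`` is called expressed in neuron
    ``roster.names[i]``. ``threshold_level`` is a provenance tag for the
    stringency of the upstream expression calls (1-4, 4 most stringent); it
    is carried through reports but never interpreted.
    """

    genes: list[str]
    roster: NeuronRoster
    X: np.ndarray
    threshold_level: int = 4

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=bool)
        if self.X.shape != (len(self.genes), len(self.roster)):
            raise ValueError(
                f"expression matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.roster)} neurons"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        """Boolean expression vector of ``gene`` over the roster."""
        try:
            return self.X[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def n_expressing(self, gene: str) -> int:
        return int(self.row(gene).sum())


@dataclass(frozen=True)
class InteractionEntry:
    """One peptide-receptor activation measured in vitro."""

    peptide_id: str
    npp_gene: str
    gpcr_gene: str
    ec50: float  # molar

    def __post_init__(self) -> None:
        if not self.npp_gene or not self.gpcr_gene:
            raise ValueError("npp_gene and gpcr_gene must be non-empty")
        if not (self.ec50 > 0):
            raise ValueError(f"EC50 must be positive, got {self.ec50}")


@dataclass(frozen=True, order=True)
class GeneCouple:
    """A precursor-gene / receptor-gene pair active at the current threshold."""

    npp_gene: str
    gpcr_gene: str
    min_ec50: float = field(compare=False, default=float("nan"))

    @property
    def key(self) -> tuple[str, str]:
        return (self.npp_gene, self.gpcr_gene)

    def __str__(self) -> str:
        return f"{self.npp_gene}->{self.gpcr_gene}"


def couples_at_threshold(
    entries: list[InteractionEntry], ec50_max: float
) -> list[GeneCouple]:
    """Reduce peptide-level entries to unique gene couples at an EC50 cutoff.

    A couple is retained when at least one peptide-level entry for the gene
    pair has EC50 <= ``ec50_max`` (molar); its ``min_ec50`` is the minimum
    over all contributing entries. Output is sorted by (npp_gene, gpcr_gene).
    """
    if not (ec50_max > 0):
        raise ValueError("ec50_max must be positive")
    best: dict[tuple[str, str], float] = {}
    for e in entries:
        if e.ec50 <= ec50_max:
            k = (e.npp_gene, e.gpcr_gene)
            if k not in best or e.ec50 < best[k]:
                best[k] = e.ec50
    return [
        GeneCouple(npp_gene=n, gpcr_gene=g, min_ec50=best[(n, g)])
        for n, g in sorted(best)
    ]


@dataclass
class NeuronAnnotation:
    """Anatomical annotation of one neuron.

    ``bundles`` are the process bundles the neuron's axons/dendrites run in;
    ``region`` is the body region of its processes (head, midbody or tail,
    with the pharynx counted as head); ``strata`` are the nerve-ring layers
    (subset of 1-4) its nerve-ring process occupies, empty when the neuron
    has no nerve-ring process; ``in_pharynx`` marks membership in the
    pharyngeal nervous system.
    """

    neuron: str
    bundles: frozenset[str]
    region: str
    strata: frozenset[int] = frozenset()
    in_pharynx: bool = False

    def __post_init__(self) -> None:
        self.bundles = frozenset(self.bundles)
        self.strata = frozenset(int(s) for s in self.strata)
        if self.region not in REGIONS:
            raise ValueError(
                f"{self.neuron}: region {self.region!r} not in {REGIONS}"
            )
        if not self.strata <= {1, 2, 3, 4}:
            raise ValueError(f"{self.neuron}: strata must be within 1..4")
        if not self.bundles:
            raise ValueError(f"{self.neuron}: at least one bundle required")


@dataclass
class WiredNetwork:
    """A wired reference connectome (synaptic, gap junction or monoamine)."""

    name: str
    A: np.ndarray  # nonnegative integers, roster x roster
    directed: bool
    roster: NeuronRoster

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        n = len(self.roster)
        if self.A.shape != (n, n):
            raise ValueError(f"wired matrix must be {n}x{n}")
        if (self.A < 0).any():
            raise ValueError("wired weights must be nonnegative")
        if not self.directed and not np.array_equal(self.A, self.A.T):
            raise ValueError(f"{self.name}: undirected network must be symmetric")

    def binary(self) -> np.ndarray:
        """Binarized adjacency with the diagonal zeroed."""
        B = self.A > 0
        np.fill_diagonal(B, False)
        return B
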