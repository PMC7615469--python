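"""Directed-network statistics and rich-club analysis.

All functions operate on binary directed adjacency matrices with the
diagonal zeroed (use :func:`zero_diagonal` first; most entry points check).

The rich-club computation follows the standard recipe for directed graphs:
for each degree level k, keep the nodes with total degree (in + out) > k
and measure the density Phi(k) of the induced subgraph,
Phi(k) = M_k / (N_k (N_k - 1)). Phi is normalized against an ensemble of
degree-preserving randomizations of the network (pairwise edge swaps:
(A->B), (C->D) becomes (A->D), (C->B), rejecting swaps that would create a
self-loop or duplicate an existing edge). The rich-club regime starts at
the smallest k where the normalized coefficient exceeds 1 by at least one
standard deviation of the null, and the rich club is the set of nodes whose
total degree exceeds that onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def zero_diagonal(A: np.ndarray) -> np.ndarray:
    """Copy of ``A`` as boolean with self-connections removed."""
    A = np.asarray(A, dtype=bool).copy()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    np.fill_diagonal(A, False)
    return A


@dataclass
class DegreeTable:
    """Per-node in/out/total degree of a binary directed network."""

    k_in: np.ndarray
    k_out: np.ndarray
    names: tuple[str, ...] | None = None

    @property
    def k(self) -> np.ndarray:
        return self.k_in + self.k_out

    def __len__(self) -> int:
        return len(self.k_in)


@dataclass
class NetworkMetrics:
    N: int
    K: int
    density: float
    transitivity: float
    reciprocity: float
    reciprocal_edges: int
    defined: bool = True  # False when K == 0 (reciprocity undefined)


def degrees(A: np.ndarray, names: tuple[str, ...] | None = None) -> DegreeTable:
    A = zero_diagonal(A)
    return DegreeTable(
        k_in=A.sum(axis=0).astype(int), k_out=A.sum(axis=1).astype(int),
        names=names,
    )


def density(A: np.ndarray) -> float:
    """Fraction of present directed connections, K / (N^2 - N)."""
    A = zero_diagonal(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return float(A.sum() / (n * n - n))


def transitivity(A: np.ndarray) -> float:
    """Directed transitivity: ratio of closed triangles to triples.

    Triangles around node i count every ordered closed triple through i in
    the symmetrized sense, t_i = (1/2) sum_{j,h} (A_ij + A_ji)(A_ih + A_hi)
    (A_jh + A_hj); triples are k_i(k_i - 1) - 2 * (reciprocal pairs at i),
    with k_i the total degree.
    """
    A = zero_diagonal(A).astype(float)
    U = A + A.T
    t = np.diag(U @ U @ U) / 2.0
    k_tot = A.sum(0) + A.sum(1)
    recip = (A * A.T).sum(axis=1)
    denom = (k_tot * (k_tot - 1) - 2 * recip).sum()
    if denom == 0:
        return 0.0
    return float(t.sum() / denom)


def reciprocity(A: np.ndarray) -> tuple[float, int, bool]:
    """Fraction of edges that are reciprocated.

    Returns ``(r, n_reciprocal_edges, defined)``; ``defined`` is False for
    an empty network, in which case r is NaN.
    """
    A = zero_diagonal(A)
    K = int(A.sum())
    e_recip = int((A & A.T).sum())
    if K == 0:
        return float("nan"), 0, False
    return e_recip / K, e_recip, True


def network_metrics(A: np.ndarray) -> NetworkMetrics:
    A = zero_diagonal(A)
    n = A.shape[0]
    K = int(A.sum())
    r, e_recip, defined = reciprocity(A)
    return NetworkMetrics(
        N=n, K=K, density=density(A), transitivity=transitivity(A),
        reciprocity=r, reciprocal_edges=e_recip, defined=defined,
    )


def degree_preserving_nulls(
    A: np.ndarray,
    n: int,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[list[np.ndarray], dict]:
    """Randomize a directed network by degree-preserving edge swaps.

    Each null attempts ``swaps_per_edge * K`` swaps; a proposed swap
    (A->B),(C->D) -> (A->D),(C->B) is rejected (and counts toward the
    attempt budget) when it would create a self-loop or an edge that
    already exists. In- and out-degree sequences are preserved exactly.

    Returns the list of null adjacencies and a diagnostics dict with the
    realized swap tally per null.
    """
    if n < 1:
        raise ValueError("need at least one null")
    A = zero_diagonal(A)
    N = A.shape[0]
    rng = np.random.default_rng(seed)
    u0, v0 = np.nonzero(A)
    K = len(u0)
    nulls: list[np.ndarray] = []
    realized: list[int] = []
    if K < 2:
        warnings.warn("network too small to swap; returning copies")
        return [A.copy() for _ in range(n)], {"realized_swaps": [0] * n}
    attempts = swaps_per_edge * K
    for _ in range(n):
        u = u0.tolist()
        v = v0.tolist()
        adj = bytearray(A.reshape(-1).astype(np.uint8).tobytes())
        e1s = rng.integers(0, K, size=attempts).tolist()
        e2s = rng.integers(0, K, size=attempts).tolist()
        done = 0
        for e1, e2 in zip(e1s, e2s):
            if e1 == e2:
                continue
            a, b = u[e1], v[e1]
            c, d = u[e2], v[e2]
            if a == d or c == b:
                continue
            if adj[a * N + d] or adj[c * N + b]:
                continue
            adj[a * N + b] = 0
            adj[c * N + d] = 0
            adj[a * N + d] = 1
            adj[c * N + b] = 1
            v[e1] = d
            v[e2] = b
            done += 1
        nulls.append(
            np.frombuffer(bytes(adj), dtype=np.uint8).reshape(N, N).astype(bool)
        )
        realized.append(done)
    if min(realized) == 0:
        warnings.warn("a null realized no swaps (network too dense or small)")
    return nulls, {"realized_swaps": realized}


@dataclass
class RichClubCurve:
    k: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray
    phi_rand_sd: np.ndarray
    phi_norm: np.ndarray
    onset_k: int | None
    members: tuple = ()
    n_null: int = 0
    swaps_per_edge: int = 10
    seed: int | None = None
    sigma_basis: str = "normalized"
    member_indices: np.ndarray = field(default_factory=lambda: np.array([], int))


def _phi_curve(A: np.ndarray, k_tot: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Phi(k) for the induced subgraphs of nodes with total degree > k."""
    order = np.argsort(k_tot, kind="stable")
    As = A[np.ix_(order, order)]
    ks_sorted = k_tot[order]
    phi = np.full(len(ks), np.nan)
    for i, k in enumerate(ks):
        start = np.searchsorted(ks_sorted, k, side="right")
        nk = len(ks_sorted) - start
        if nk < 2:
            continue
        mk = As[start:, start:].sum()
        phi[i] = mk / (nk * (nk - 1))
    return phi


def rich_club(
    A: np.ndarray,
    nulls: list[np.ndarray],
    *,
    names: tuple[str, ...] | None = None,
    sigma_basis: str = "normalized",
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> RichClubCurve:
    """Rich-club curve, normalization against nulls, onset and membership.

    ``sigma_basis`` selects how the one-sigma onset band is measured:
    ``"normalized"`` (default) uses SD(Phi_rand)/mean(Phi_rand) at each k,
    i.e. the spread of the null curve on the normalized scale; ``"raw"``
    uses SD(Phi_rand) directly.
    """
    if sigma_basis not in ("normalized", "raw"):
        raise ValueError("sigma_basis must be 'normalized' or 'raw'")
    A = zero_diagonal(A)
    k_tot = A.sum(0) + A.sum(1)
    kmax = int(k_tot.max(initial=0))
    ks = np.arange(1, max(kmax, 2))
    phi = _phi_curve(A, k_tot, ks)
    rand = np.vstack([
        _phi_curve(zero_diagonal(Z), k_tot, ks) for Z in nulls
    ]) if nulls else np.full((1, len(ks)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rand, axis=0)
        sd = np.nanstd(rand, axis=0, ddof=0)
        phi_norm = np.where(mean > 0, phi / mean, np.nan)
        sigma = np.where(mean > 0, sd / mean, np.nan) if sigma_basis == "normalized" else sd
    ok = ~np.isnan(phi_norm) & ~np.isnan(sigma)
    # sigma == 0 only in degenerate ensembles (e.g. a degree sequence with a
    # unique realization); requiring strict excess there keeps Phi_norm == 1
    # from opening a vacuous club
    above = ok & np.where(
        sigma > 0, phi_norm >= 1 + sigma, phi_norm > 1 + sigma
    )
    onset = int(ks[above][0]) if above.any() else None
    if onset is None:
        idx = np.array([], dtype=int)
    else:
        idx = np.nonzero(k_tot > onset)[0]
    members = tuple(names[i] for i in idx) if names else tuple(int(i) for i in idx)
    return RichClubCurve(
        k=ks, phi=phi, phi_rand_mean=mean, phi_rand_sd=sd, phi_norm=phi_norm,
        onset_k=onset, members=members, n_null=len(nulls),
        swaps_per_edge=swaps_per_edge, seed=seed, sigma_basis=sigma_basis,
        member_indices=idx,
    )


def subnetwork_density(A: np.ndarray, nodes) -> float:
    """Density of the induced subgraph on ``nodes`` (diagonal excluded)."""
    nodes = np.asarray(nodes)
    if len(nodes) < 2:
        raise ValueError("subnetwork density needs at least 2 nodes")
    A = zero_diagonal(A)
    return density(A[np.ix_(nodes, nodes)])


def degree_correlation(d1: DegreeTable, d2: DegreeTable) -> tuple[float, float]:
    """Pearson correlation of total degrees with two-sided p-value."""
    if len(d1) != len(d2):
        raise ValueError("degree tables cover different rosters")
    x, y = d1.k.astype(float), d2.k.astype(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a degree sequence")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
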