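"""Directed-network statistics against exhaustive-enumeration oracles, and
the degree-preserving null / rich-club machinery."""

import numpy as np
import pytest

import pepconn as pc
from conftest import random_digraph


# ---- independent brute-force oracles (loops over nodes/pairs/triples) ----

def oracle_degrees(A):
    n = len(A)
    k_in = [sum(A[i][j] for i in range(n) if i != j) for j in range(n)]
    k_out = [sum(A[i][j] for j in range(n) if i != j) for i in range(n)]
    return k_in, k_out


def oracle_density(A):
    n = len(A)
    K = sum(A[i][j] for i in range(n) for j in range(n) if i != j)
    return K / (n * n - n)


def oracle_reciprocity(A):
    n = len(A)
    K = sum(A[i][j] for i in range(n) for j in range(n) if i != j)
    rec = sum(
        A[i][j] and A[j][i] for i in range(n) for j in range(n) if i != j
    )
    return (rec / K if K else float("nan")), rec


def oracle_transitivity(A):
    n = len(A)
    num = 0.0
    den = 0.0
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (A[i][j] + A[j][i]) * (A[i][h] + A[h][i]) * (
                    A[j][h] + A[h][j]
                )
        num += t / 2.0
        k_tot = sum(A[i][j] for j in range(n)) + sum(A[j][i] for j in range(n))
        rec_i = sum(A[i][j] * A[j][i] for j in range(n))
        den += k_tot * (k_tot - 1) - 2 * rec_i
    return num / den if den else 0.0


def adj(n, edges):
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = True
    return A


class TestMetricOracles:
    @pytest.mark.parametrize("seed", range(40))
    def test_all_metrics_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        A = random_digraph(n, rng.uniform(0.05, 0.6), rng)
        L = A.astype(int).tolist()
        dt = pc.degrees(A)
        k_in, k_out = oracle_degrees(L)
        assert dt.k_in.tolist() == k_in
        assert dt.k_out.tolist() == k_out
        assert pc.density(A) == pytest.approx(oracle_density(L))
        r, rec, defined = pc.reciprocity(A)
        r_o, rec_o = oracle_reciprocity(L)
        assert rec == rec_o
        if defined:
            assert r == pytest.approx(r_o)
        assert pc.transitivity(A) == pytest.approx(oracle_transitivity(L))

    def test_degree_sums_equal_edge_count(self, rng):
        A = random_digraph(20, 0.3, rng)
        dt = pc.degrees(A)
        assert dt.k_in.sum() == dt.k_out.sum() == A.sum()


class TestExamples:
    def test_empty_graph_all_zero_degrees(self):
        dt = pc.degrees(np.zeros((4, 4), bool))
        assert not dt.k.any()

    def test_single_edge_degrees(self):
        A = adj(3, [(0, 1)])
        dt = pc.degrees(A)
        assert dt.k_out[0] == 1 and dt.k_in[0] == 0
        assert dt.k_in[1] == 1 and dt.k_out[1] == 0

    def test_complete_digraph_density_one(self):
        A = ~np.eye(5, dtype=bool)
        assert pc.density(A) == 1.0
        assert pc.density(np.zeros((5, 5), bool)) == 0.0

    def test_density_rejects_tiny_graph(self):
        with pytest.raises(ValueError):
            pc.density(np.zeros((1, 1), bool))

    def test_dag_reciprocity_zero(self):
        A = adj(4, [(0, 1), (1, 2), (0, 3)])
        r, rec, defined = pc.reciprocity(A)
        assert defined and r == 0.0 and rec == 0

    def test_reciprocity_two_thirds(self):
        A = adj(3, [(0, 1), (1, 0), (0, 2)])
        r, rec, _ = pc.reciprocity(A)
        assert r == pytest.approx(2 / 3) and rec == 2

    def test_empty_reciprocity_flagged_undefined(self):
        r, rec, defined = pc.reciprocity(np.zeros((3, 3), bool))
        assert not defined and np.isnan(r)

    def test_triangle_free_transitivity_zero(self):
        A = adj(4, [(0, 1), (1, 2)])
        assert pc.transitivity(A) == 0.0

    def test_fully_reciprocated_k4_transitivity_one(self):
        A = ~np.eye(4, dtype=bool)
        assert pc.transitivity(A) == pytest.approx(1.0)


class TestNulls:
    def test_defining_swap_move(self):
        # {A->B, C->D} can only become {A->D, C->B}
        A = adj(4, [(0, 1), (2, 3)])
        configs = set()
        for seed in range(6):
            nulls, diag = pc.degree_preserving_nulls(
                A, n=1, swaps_per_edge=5, seed=seed
            )
            edges = frozenset(zip(*map(tuple, np.nonzero(nulls[0]))))
            assert edges in (
                frozenset({(0, 1), (2, 3)}), frozenset({(0, 3), (2, 1)}),
            )
            configs.add(edges)
        assert len(configs) == 2  # the swap actually happens

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degree_sequences_and_edge_count_preserved(self, seed):
        rng = np.random.default_rng(seed)
        A = random_digraph(30, 0.15, rng)
        nulls, diag = pc.degree_preserving_nulls(
            A, n=20, swaps_per_edge=10, seed=seed
        )
        d0 = pc.degrees(A)
        for Z in nulls:
            assert not np.diag(Z).any()
            dz = pc.degrees(Z)
            assert np.array_equal(dz.k_in, d0.k_in)
            assert np.array_equal(dz.k_out, d0.k_out)
            assert Z.sum() == A.sum()
        assert min(diag["realized_swaps"]) > 0

    def test_nulls_randomize_transitivity_but_not_density(self):
        # swaps leave density untouched while scrambling triangle structure
        expr, entries, _, _ = pc.generate(
            pc.SynthConfig(
                n_neurons=50, n_npp=8, n_gpcr=8, seed=4,
                breadth_log_mean=1.5, breadth_log_sigma=0.4,
            )
        )
        couples = pc.couples_at_threshold(entries, 1e-6)
        nets = [pc.build_pair_network(expr, c) for c in couples]
        A = pc.aggregate(nets, "long").binary()
        nulls, _ = pc.degree_preserving_nulls(A, n=30, swaps_per_edge=10, seed=1)
        t0 = pc.transitivity(A)
        t_null = np.array([pc.transitivity(Z) for Z in nulls])
        d_null = [pc.density(Z) for Z in nulls]
        assert all(d == pc.density(A) for d in d_null)
        assert t_null.std() > 0  # the ensemble is a genuine distribution
        assert np.mean(t_null != t0) > 0.9  # and it moved off the original

    def test_too_small_graph_warns_and_copies(self):
        A = adj(3, [(0, 1)])
        with pytest.warns(UserWarning, match="too small"):
            nulls, diag = pc.degree_preserving_nulls(A, n=3, seed=0)
        assert all(np.array_equal(Z, A) for Z in nulls)


class TestRichClub:
    def test_complete_digraph_phi_one_everywhere(self):
        A = ~np.eye(8, dtype=bool)
        rc = pc.rich_club(A, [A.copy() for _ in range(5)])
        defined = ~np.isnan(rc.phi)
        assert defined.any()
        assert np.allclose(rc.phi[defined], 1.0)

    def test_star_digraph_has_no_rich_club(self):
        # hub 0 reciprocally tied to each leaf; leaves unconnected
        n = 12
        edges = [(0, i) for i in range(1, n)] + [(i, 0) for i in range(1, n)]
        A = adj(n, edges)
        nulls, _ = pc.degree_preserving_nulls(A, n=30, swaps_per_edge=10, seed=3)
        rc = pc.rich_club(A, nulls)
        assert len(rc.members) == 0

    def test_homogeneous_graph_phi_norm_flat_in_bulk(self):
        # an ER digraph carries no rich-club signal where N_k is sizeable
        devs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            A = random_digraph(60, 0.15, rng)
            k_tot = A.sum(0) + A.sum(1)
            nulls, _ = pc.degree_preserving_nulls(
                A, n=25, swaps_per_edge=10, seed=seed + 100
            )
            rc = pc.rich_club(A, nulls)
            Nk = np.array([(k_tot > k).sum() for k in rc.k])
            sel = (Nk >= 20) & ~np.isnan(rc.phi_norm)
            devs.append(np.max(np.abs(rc.phi_norm[sel] - 1)))
        assert np.median(devs) < 0.1
        assert max(devs) < 0.25

    def test_deterministic_given_seed(self, rng):
        A = random_digraph(40, 0.2, rng)
        curves = []
        for _ in range(2):
            nulls, _ = pc.degree_preserving_nulls(
                A, n=10, swaps_per_edge=10, seed=7
            )
            curves.append(pc.rich_club(A, nulls, seed=7))
        a, b = curves
        assert np.array_equal(a.phi, b.phi, equal_nan=True)
        assert np.array_equal(a.phi_norm, b.phi_norm, equal_nan=True)
        assert a.onset_k == b.onset_k and a.members == b.members

    def test_membership_rule_is_degree_above_onset(self, rng):
        A = random_digraph(40, 0.3, rng)
        nulls, _ = pc.degree_preserving_nulls(A, n=15, seed=2)
        rc = pc.rich_club(A, nulls)
        if rc.onset_k is not None:
            k_tot = A.sum(0) + A.sum(1)
            assert set(rc.member_indices) == set(np.nonzero(k_tot > rc.onset_k)[0])


class TestSubnetworkDensity:
    def test_clique_and_independent_set(self):
        A = np.zeros((6, 6), bool)
        A[np.ix_([0, 1, 2], [0, 1, 2])] = True
        np.fill_diagonal(A, False)
        assert pc.subnetwork_density(A, [0, 1, 2]) == 1.0
        assert pc.subnetwork_density(A, [3, 4, 5]) == 0.0

    def test_needs_two_nodes(self):
        with pytest.raises(ValueError):
            pc.subnetwork_density(np.zeros((4, 4), bool), [1])


class TestDegreeCorrelation:
    def test_identity_and_reversal(self, rng):
        A = random_digraph(25, 0.3, rng)
        d = pc.degrees(A)
        r, p = pc.degree_correlation(d, d)
        assert r == pytest.approx(1.0)
        flipped = pc.DegreeTable(k_in=-d.k_in + 50, k_out=-d.k_out + 50)
        r2, _ = pc.degree_correlation(d, flipped)
        assert r2 == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        d1 = pc.DegreeTable(k_in=np.arange(5), k_out=np.zeros(5, int))
        d2 = pc.DegreeTable(k_in=np.ones(5, int), k_out=np.ones(5, int))
        with pytest.raises(ValueError, match="variance"):
            pc.degree_correlation(d1, d2)
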