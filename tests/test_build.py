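"""Pair-network construction, spatial filtering, and aggregation."""

import numpy as np
import pytest

import pepconn as pc
from pepconn.core import GeneCouple, NeuronAnnotation


def expr_from(roster, table):
    """Expression matrix from {gene: [neuron names]}."""
    idx = roster.index()
    X = np.zeros((len(table), len(roster)), dtype=bool)
    genes = list(table)
    for g, neurons in table.items():
        for n in neurons:
            X[genes.index(g), idx[n]] = True
    return pc.ExpressionMatrix(genes=genes, roster=roster, X=X)


@pytest.fixture(scope="module")
def toy():
    """Six neurons: two head (nerve ring), one pharyngeal, one ventral-cord
    pair spanning head, one tail."""
    r = pc.synthetic_roster(6)
    a, b, c, d, e, f = r.names
    ann = {
        a: NeuronAnnotation(a, {"nerve_ring"}, "head", strata={1, 2}),
        b: NeuronAnnotation(b, {"nerve_ring"}, "head", strata={2}),
        c: NeuronAnnotation(c, {"pharynx"}, "head", in_pharynx=True),
        d: NeuronAnnotation(d, {"nerve_ring", "ventral_cord"}, "head", strata={4}),
        e: NeuronAnnotation(e, {"ventral_cord"}, "head"),
        f: NeuronAnnotation(f, {"tail_bundle"}, "tail"),
    }
    return r, ann, pc.SpatialIndex(ann, r)


class TestPairNetwork:
    def test_npp_expressed_nowhere_gives_empty(self, toy):
        r, _, _ = toy
        expr = expr_from(r, {"npp": [], "gpcr": list(r.names)})
        net = pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
        assert not net.A.any()

    def test_shared_neuron_gives_self_loop(self, toy):
        r, _, _ = toy
        a = r.names[0]
        expr = expr_from(r, {"npp": [a], "gpcr": [a]})
        net = pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
        assert net.A.sum() == 1 and net.A[0, 0]

    def test_outer_product_oracle(self, toy):
        r, _, _ = toy
        a, b, c = r.names[:3]
        expr = expr_from(r, {"npp": [a, b], "gpcr": [b, c]})
        net = pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
        idx = r.index()
        expected = {(a, b), (a, c), (b, b), (b, c)}
        got = {
            (r.names[i], r.names[j]) for i, j in zip(*np.nonzero(net.A))
        }
        assert got == expected
        # exhaustive check against the defining formula
        for i in range(len(r)):
            for j in range(len(r)):
                assert net.A[i, j] == (
                    expr.row("npp")[i] and expr.row("gpcr")[j]
                )

    def test_missing_gene_error_names_gene(self, toy):
        r, _, _ = toy
        expr = expr_from(r, {"npp": [r.names[0]]})
        with pytest.raises(KeyError, match="gpcr"):
            pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))


class TestSpatialPredicate:
    def test_head_vs_tail(self, toy):
        r, _, idx = toy
        head, tail = r.names[0], r.names[5]
        assert pc.spatial_predicate(head, tail, "long", idx)
        assert not pc.spatial_predicate(head, tail, "mid", idx)

    def test_pharynx_separated_under_short_but_not_mid(self, toy):
        r, _, idx = toy
        ring, pharyngeal = r.names[0], r.names[2]
        assert not pc.spatial_predicate(ring, pharyngeal, "short", idx)
        assert pc.spatial_predicate(ring, pharyngeal, "mid", idx)
        # pharyngeal neurons still talk to each other at short range
        assert pc.spatial_predicate(pharyngeal, pharyngeal, "short", idx)

    def test_shared_thin_bundle_passes_all_models(self, toy):
        r, _, idx = toy
        d, e = r.names[3], r.names[4]  # share ventral_cord
        for model in ("contact", "short", "mid", "long"):
            assert pc.spatial_predicate(d, e, model, idx)

    def test_stratum_contact(self, toy):
        r, _, idx = toy
        a, b, d = r.names[0], r.names[1], r.names[3]
        assert pc.spatial_predicate(a, b, "contact", idx)  # share stratum 2
        assert not pc.spatial_predicate(b, d, "contact", idx)  # strata 2 vs 4
        assert pc.spatial_predicate(b, d, "short", idx)  # share nerve ring

    def test_nesting_exhaustive_on_synthetic_anatomy(self):
        cfg = pc.SynthConfig(n_neurons=100, n_npp=5, n_gpcr=5, seed=2)
        expr, _, ann, _ = pc.generate(cfg)
        idx = pc.SpatialIndex(ann, expr.roster)
        contact = idx.mask("contact")
        short = idx.mask("short")
        mid = idx.mask("mid")
        long_ = idx.mask("long")
        assert (contact <= short).all()
        assert (short <= mid).all()
        assert (mid <= long_).all()


class TestSpatialFilter:
    def test_long_model_is_identity(self, toy):
        r, _, idx = toy
        expr = expr_from(r, {"npp": list(r.names[:3]), "gpcr": list(r.names[2:])})
        net = pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
        assert np.array_equal(
            pc.apply_spatial_filter(net, "long", idx).A, net.A
        )

    @pytest.mark.parametrize("model", ["contact", "short", "mid"])
    def test_matches_brute_force_refilter(self, model):
        cfg = pc.SynthConfig(n_neurons=40, n_npp=4, n_gpcr=4, seed=5)
        expr, entries, ann, _ = pc.generate(cfg)
        idx = pc.SpatialIndex(ann, expr.roster)
        couples = pc.couples_at_threshold(entries, 1e-6)
        names = expr.roster.names
        for c in couples[:3]:
            net = pc.build_pair_network(expr, c)
            filt = pc.apply_spatial_filter(net, model, idx)
            for i in range(len(names)):
                for j in range(len(names)):
                    if i == j:
                        expected = net.A[i, j]  # self-loops always pass
                    else:
                        expected = net.A[i, j] and pc.spatial_predicate(
                            names[i], names[j], model, idx
                        )
                    assert filt.A[i, j] == expected

    def test_mid_filter_keeps_only_same_region(self, toy):
        r, _, idx = toy
        head, tail = r.names[0], r.names[5]
        expr = expr_from(r, {"npp": [head, tail], "gpcr": [head, tail]})
        net = pc.apply_spatial_filter(
            pc.build_pair_network(expr, GeneCouple("npp", "gpcr")), "mid", idx
        )
        got = {(i, j) for i, j in zip(*np.nonzero(net.A))}
        assert got == {(0, 0), (5, 5)}  # cross-region edges removed


class TestAggregate:
    def test_two_identical_nets_sum_to_two(self, toy):
        r, _, _ = toy
        expr = expr_from(r, {"npp": [r.names[0]], "gpcr": [r.names[1]]})
        nets = [
            pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
            for _ in range(2)
        ]
        agg = pc.aggregate(nets, "long")
        assert agg.W[0, 1] == 2 and agg.W.sum() == 2

    def test_empty_list_gives_zero_matrix(self):
        agg = pc.aggregate([], "short")
        assert agg.W.size == 0

    def test_mixed_models_rejected(self, toy):
        r, _, idx = toy
        expr = expr_from(r, {"npp": [r.names[0]], "gpcr": [r.names[1]]})
        n1 = pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
        n2 = pc.apply_spatial_filter(n1, "mid", idx)
        with pytest.raises(ValueError, match="mixed models"):
            pc.aggregate([n1, n2], "long")

    def test_weight_conservation(self, small_dataset):
        expr, entries, ann, _ = small_dataset
        couples = pc.couples_at_threshold(entries, 500e-9)
        nets = [pc.build_pair_network(expr, c) for c in couples]
        agg = pc.aggregate(nets, "long")
        assert agg.W.sum() == sum(n.A.sum() for n in nets)
        assert agg.W.max() <= len(couples)

    def test_density_monotone_across_models(self, small_dataset):
        expr, entries, ann, _ = small_dataset
        idx = pc.SpatialIndex(ann, expr.roster)
        couples = pc.couples_at_threshold(entries, 500e-9)
        long_nets = [pc.build_pair_network(expr, c) for c in couples]
        dens = {}
        for model in ("contact", "short", "mid", "long"):
            nets = [pc.apply_spatial_filter(n, model, idx) for n in long_nets]
            dens[model] = pc.density(pc.aggregate(nets, model).binary())
        assert dens["contact"] <= dens["short"] <= dens["mid"] <= dens["long"]


class TestEdgeWeights:
    def test_zero_matrix_empty_histogram(self):
        r = pc.synthetic_roster(5)
        agg = pc.AggregateNetwork(model="long", W=np.zeros((5, 5), int), roster=r)
        hist, argmax = pc.edge_weight_distribution(agg)
        assert hist == {} and argmax == []

    def test_k_identical_couples_single_bin(self, toy):
        r, _, _ = toy
        expr = expr_from(r, {"npp": [r.names[0]], "gpcr": [r.names[1]]})
        nets = [
            pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
            for _ in range(4)
        ]
        hist, argmax = pc.edge_weight_distribution(pc.aggregate(nets, "long"))
        assert hist == {4: 1}
        assert argmax == [(r.names[0], r.names[1])]

    def test_self_loops_excluded(self, toy):
        r, _, _ = toy
        a = r.names[0]
        expr = expr_from(r, {"npp": [a], "gpcr": [a]})
        net = pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
        hist, _ = pc.edge_weight_distribution(pc.aggregate([net], "long"))
        assert hist == {}


class TestOverlapWithWired:
    def test_identical_and_disjoint(self, rng):
        r = pc.synthetic_roster(10)
        A = (rng.random((10, 10)) < 0.3)
        np.fill_diagonal(A, False)
        agg = pc.AggregateNetwork(model="short", W=A.astype(int), roster=r)
        wired = pc.WiredNetwork("synaptic", A.astype(int), True, r)
        res = pc.overlap_with_wired(agg, wired)
        assert res == {"both": int(A.sum()), "pept_only": 0, "wired_only": 0}
        other = pc.WiredNetwork("synaptic", (~A).astype(int) * 1, True, r)
        res2 = pc.overlap_with_wired(agg, other)
        assert res2["both"] == 0


class TestComponents:
    def test_isolated_neurons_ignored(self, toy):
        r, _, _ = toy
        expr = expr_from(r, {"npp": [r.names[0]], "gpcr": [r.names[1], r.names[3]]})
        net = pc.build_pair_network(expr, GeneCouple("npp", "gpcr"))
        assert net.n_components() == 1

    def test_two_components_after_filter(self, toy):
        r, _, idx = toy
        head, tail = r.names[0], r.names[5]
        expr = expr_from(r, {"npp": [head, tail], "gpcr": [head, tail]})
        net = pc.apply_spatial_filter(
            pc.build_pair_network(expr, GeneCouple("npp", "gpcr")), "mid", idx
        )
        assert net.n_components() == 2  # head self-loop + tail self-loop
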