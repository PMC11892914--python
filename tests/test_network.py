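"""SparCC recovery, network construction, Louvain, representatives, keystones."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutbrain.network import (
    CooccurrenceNetwork,
    build_cooccurrence_network,
    centrality_difference,
    louvain_partition,
    representative_species,
    sparcc_correlations,
)
from gutbrain.otu_processing import OtuTable
from gutbrain.synthetic_data import generate_compositional_counts


def _net_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, abs_weight=abs(w))
    return CooccurrenceNetwork(graph=g)


class TestSparcc:
    def test_planted_correlation_recovered(self):
        corr = np.eye(20)
        corr[0, 1] = corr[1, 0] = 0.8
        otu = generate_compositional_counts(corr, 0.0, 200, 50_000, seed=11)
        est = sparcc_correlations(otu, seed=1)
        assert est.iloc[0, 1] == pytest.approx(0.8, abs=0.15)

    def test_null_estimates_concentrate_near_zero(self):
        otu = generate_compositional_counts(np.eye(20), 0.0, 200, 50_000, seed=12)
        est = sparcc_correlations(otu, seed=2).to_numpy()
        off = est[np.triu_indices(20, 1)]
        # estimator sd at n=200 is ~1/sqrt(n); the bulk must sit near zero
        assert np.abs(off).mean() < 0.1
        assert off.std() < 0.12

    def test_too_few_taxa_rejected(self, small_otu):
        with pytest.raises(ValueError, match="4 taxa"):
            sparcc_correlations(small_otu.counts.iloc[:3])

    def test_sample_order_invariance(self):
        otu = generate_compositional_counts(np.eye(8), 0.0, 40, 5_000, seed=3)
        a = sparcc_correlations(otu.counts, seed=5)
        b = sparcc_correlations(otu.counts.iloc[:, ::-1], seed=5)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_depth_rescaling_stability(self):
        corr = np.eye(15)
        corr[2, 3] = corr[3, 2] = 0.7
        lo = generate_compositional_counts(corr, 0.0, 150, 20_000, seed=9)
        hi = generate_compositional_counts(corr, 0.0, 150, 40_000, seed=9)
        r_lo = sparcc_correlations(lo, seed=4)
        r_hi = sparcc_correlations(hi, seed=4)
        assert np.abs(r_lo.values - r_hi.values).max() < 0.05

    def test_output_symmetric_unit_diagonal(self):
        otu = generate_compositional_counts(np.eye(6), 0.0, 30, 2_000, seed=6)
        est = sparcc_correlations(otu, seed=0)
        np.testing.assert_allclose(est.values, est.values.T)
        np.testing.assert_allclose(np.diag(est.values), 1.0)
        assert (np.abs(est.values) <= 1.0).all()


class TestBuildNetwork:
    def _table(self):
        counts = pd.DataFrame(
            {"s1": [5, 6, 50], "s2": [5, 6, 50]}, index=["A", "B", "C"]
        )
        return OtuTable(
            counts,
            pd.Series(["a", "b", "c"], index=counts.index),
            pd.Series(["F", "F", "B"], index=counts.index),
        )

    def test_edge_threshold_and_sign(self):
        corr = pd.DataFrame(
            [[1, -0.5, 0.1], [-0.5, 1, 0.2], [0.1, 0.2, 1]],
            index=["A", "B", "C"], columns=["A", "B", "C"],
        )
        net = build_cooccurrence_network(corr, self._table(), node_min_total=5)
        edges = net.edge_list()
        assert len(edges) == 1
        assert edges.iloc[0]["sign"] == "negative"
        assert edges.iloc[0]["strength"] == pytest.approx(0.5)

    def test_node_total_strictly_greater(self):
        corr = pd.DataFrame(np.eye(3), index=["A", "B", "C"], columns=["A", "B", "C"])
        net = build_cooccurrence_network(corr, self._table(), node_min_total=10)
        assert set(net.graph.nodes) == {"B", "C"}  # A total exactly 10 excluded

    def test_subthreshold_network_edgeless(self):
        corr = pd.DataFrame(np.eye(3) * 1.0, index=["A", "B", "C"],
                            columns=["A", "B", "C"])
        net = build_cooccurrence_network(corr, self._table(), node_min_total=5)
        assert net.graph.number_of_edges() == 0
        assert net.graph.number_of_nodes() == 3


class TestLouvain:
    def test_two_disjoint_cliques(self):
        edges = [(f"a{i}", f"a{j}", 1.0) for i in range(5) for j in range(i + 1, 5)]
        edges += [(f"b{i}", f"b{j}", 1.0) for i in range(5) for j in range(i + 1, 5)]
        net = _net_from_edges(edges)
        mapping, q = louvain_partition(net, seed=0)
        assert len(set(mapping.values())) == 2
        assert q == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        edges = [(f"n{i}", f"n{j}", 1.0) for i in range(5) for j in range(i + 1, 5)]
        mapping, q = louvain_partition(_net_from_edges(edges), seed=0)
        assert len(set(mapping.values())) == 1
        assert q == pytest.approx(0.0)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            louvain_partition(_net_from_edges([], nodes=["a", "b"]))

    def test_partition_beats_singletons(self, rng):
        g = nx.gnm_random_graph(20, 40, seed=3)
        net = CooccurrenceNetwork(graph=g)
        for u, v in g.edges:
            g[u][v]["weight"] = g[u][v]["abs_weight"] = 1.0
        _, q = louvain_partition(net, seed=0)
        singletons = [{n} for n in g.nodes]
        q0 = nx.community.modularity(g, singletons, weight="abs_weight")
        assert q >= q0


class TestRepresentatives:
    def test_single_community_max_degree(self):
        edges = [("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0), ("a", "d", 1.0)]
        net = _net_from_edges(edges)
        net.community = {n: 0 for n in net.graph.nodes}
        reps = representative_species(net)
        assert list(reps.values()) == ["a"]

    def test_community_outside_global_top_k_unrepresented(self):
        # one 4-clique (high degrees) and one separate edge pair (low degree)
        edges = [(f"h{i}", f"h{j}", 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [("x", "y", 1.0)]
        net = _net_from_edges(edges)
        louvain_partition(net, seed=0)
        reps = representative_species(net, top_k=4)
        assert reps[net.community["h0"]] == "h0"
        assert reps[net.community["x"]] is None

    def test_degree_tie_breaks_lexicographically(self):
        net = _net_from_edges([("beta", "alpha", 1.0)])
        louvain_partition(net, seed=0)
        reps = representative_species(net)
        assert set(reps.values()) == {"alpha"}


class TestCentralityDifference:
    def test_identical_networks_no_outliers(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0)]
        d = centrality_difference(_net_from_edges(edges), _net_from_edges(edges))
        assert (d["delta"] == 0).all()
        assert not d["outlier"].any()

    def test_node_missing_from_case_network(self):
        c = _net_from_edges([("a", "b", 1.0), ("a", "c", 1.0)])  # a: degree 2/2
        case = _net_from_edges([("b", "c", 1.0)])
        d = centrality_difference(c, case)
        assert d.loc["a", "delta"] == pytest.approx(1.0)

    def test_tukey_fences_flag_extremes(self):
        # deltas: eight zeros, +0.6, -0.6 -> IQR = 0, only extremes flagged
        base = [(f"z{i}", f"z{(i+1)%8}", 1.0) for i in range(8)]
        c = _net_from_edges(base + [("p", "q", 1.0)])
        case = _net_from_edges(base)
        # p,q have centrality 1/9 in control, 0 in case; zeros elsewhere
        d = centrality_difference(c, case)
        flagged = set(d.index[d["outlier"]])
        assert flagged == {"p", "q"}

    def test_antisymmetry(self, rng):
        g1 = _net_from_edges([("a", "b", 0.5), ("b", "c", -0.4)])
        g2 = _net_from_edges([("a", "c", 0.9), ("c", "d", 0.6)])
        d12 = centrality_difference(g1, g2)
        d21 = centrality_difference(g2, g1)
        np.testing.assert_allclose(d12["delta"], -d21["delta"])

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            centrality_difference(_net_from_edges([]), _net_from_edges([]))
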