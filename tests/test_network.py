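"""Similarity Index, orthology bands, network construction and MCL."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import adjusted_rand, naive_degrees

from mtevol.network import (
    build_network,
    classify_similarity,
    mcl_cluster,
    node_connectivity,
    similarity_index,
)


class TestSimilarityIndex:
    @pytest.mark.parametrize(
        "Lt,Lp,S,expected",
        [
            (100, 100, 1.0, 0.0),  # log2(1)
            (100, 200, 64.0, 5.0),  # log2(0.5 * 64)
            (35, 350, 30.0, math.log2(3.0)),  # short weak hit, below 2.5
        ],
    )
    def test_printed_formula(self, Lt, Lp, S, expected):
        assert similarity_index(Lt, Lp, S) == pytest.approx(expected, abs=1e-12)

    def test_short_weak_hit_falls_below_retention(self):
        assert similarity_index(35, 350, 30.0) < 2.5

    def test_nonpositive_score_rejected(self):
        with pytest.raises(ValueError):
            similarity_index(100, 100, 0.0)
        with pytest.raises(ValueError):
            similarity_index(0, 100, 5.0)

    @given(
        Lt=st.integers(1, 2000),
        Lp=st.integers(1, 2000),
        S=st.floats(0.01, 1e4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotonicity(self, Lt, Lp, S):
        base = similarity_index(Lt, Lp, S)
        assert similarity_index(Lt + 1, Lp, S) > base
        assert similarity_index(Lt, Lp + 1, S) < base
        assert similarity_index(Lt, Lp, S * 1.01) > base


class TestBands:
    @pytest.mark.parametrize(
        "SI,band",
        [
            (8.0, "ortholog"),
            (6.0, "paralog"),
            (3.0, "related"),
            (1.0, "discard"),
            (7.5, "paralog"),  # boundary goes to the lower-named band
            (5.0, "related"),
            (2.5, "related"),
            (2.4999999, "discard"),
        ],
    )
    def test_band_assignment(self, SI, band):
        assert classify_similarity(SI) == band

    @given(SI=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_partition_no_gaps(self, SI):
        band = classify_similarity(SI)
        assert band in {"ortholog", "paralog", "related", "discard"}
        # exactly one band by construction of the comparison chain
        memberships = [
            SI > 7.5,
            5.0 < SI <= 7.5,
            2.5 <= SI <= 5.0,
            SI < 2.5,
        ]
        assert sum(memberships) == 1
        assert memberships[["ortholog", "paralog", "related", "discard"].index(band)]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_similarity(math.inf)


def _hits(rows):
    return pd.DataFrame(rows, columns=["family", "target_family", "SI"])


class TestBuildNetwork:
    def test_all_below_threshold_edgeless(self):
        labels = {"A": "unknown", "B": "unknown"}
        net = build_network(_hits([("A", "B", 1.0), ("B", "A", 2.0)]), labels)
        assert net.graph.number_of_edges() == 0
        assert all(d == 0 for d in net.connectivity.values())

    def test_reciprocal_best_edge(self):
        labels = {"A": "unknown", "B": "unknown"}
        net = build_network(_hits([("A", "B", 6.0), ("B", "A", 4.0)]), labels)
        assert net.graph.number_of_edges() == 1
        assert net.graph["A"]["B"]["SI"] == 6.0  # max over directions
        assert net.connectivity == {"A": 1, "B": 1}

    def test_self_hits_dropped(self):
        labels = {"A": "unknown"}
        net = build_network(_hits([("A", "A", 9.0)]), labels)
        assert net.graph.number_of_edges() == 0

    def test_unlabeled_family_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            build_network(_hits([("A", "Z", 6.0)]), {"A": "unknown"})


def _block_network(rng, n_blocks=3, per_block=8, w_in=6.0, w_out=2.5, p_out=0.3):
    """Planted-partition SI graph: dense within blocks, sparse weak between."""
    labels = {}
    truth = {}
    rows = []
    names = []
    for b in range(n_blocks):
        for k in range(per_block):
            name = f"b{b}n{k}"
            names.append(name)
            labels[name] = "unknown"
            truth[name] = b
    for i, a in enumerate(names):
        for c in names[i + 1 :]:
            if truth[a] == truth[c]:
                rows.append((a, c, w_in + rng.normal(0, 0.1)))
            elif rng.random() < p_out:
                rows.append((a, c, w_out + rng.normal(0, 0.05)))
    return build_network(_hits(rows), labels), truth


class TestMCL:
    def test_two_disjoint_triangles(self):
        rows = [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0),
                ("X", "Y", 1.0), ("Y", "Z", 1.0), ("X", "Z", 1.0)]
        labels = {n: "unknown" for n in "ABCXYZ"}
        net = build_network(_hits(rows), labels, min_SI=0.5)
        clusters = mcl_cluster(net)
        assert len(set(clusters.values())) == 2
        assert clusters["A"] == clusters["B"] == clusters["C"]
        assert clusters["X"] == clusters["Y"] == clusters["Z"]
        assert clusters["A"] != clusters["X"]

    def test_isolated_node_own_cluster(self):
        labels = {"A": "unknown", "B": "unknown", "C": "unknown"}
        net = build_network(_hits([("A", "B", 5.0)]), labels)
        clusters = mcl_cluster(net)
        assert clusters["C"] not in {clusters["A"], clusters["B"]}

    def test_every_node_assigned_once(self, rng):
        net, _ = _block_network(rng)
        clusters = mcl_cluster(net)
        assert set(clusters) == set(net.graph.nodes)
        sizes = pd.Series(list(clusters.values())).value_counts()
        assert sizes.sum() == net.graph.number_of_nodes()

    def test_planted_partition_recovery(self):
        aris = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            net, truth = _block_network(rng)
            clusters = mcl_cluster(net)
            nodes = sorted(truth)
            aris.append(
                adjusted_rand(
                    [truth[n] for n in nodes], [clusters[n] for n in nodes]
                )
            )
        assert np.mean(aris) >= 0.9

    def test_relabeling_invariance(self, rng):
        net, truth = _block_network(rng)
        clusters = mcl_cluster(net)
        # rename every node; partition must map across the renaming
        mapping = {n: f"z_{n}" for n in net.graph.nodes}
        import networkx as nx

        renamed_graph = nx.relabel_nodes(net.graph, mapping)
        from mtevol.network import SimilarityNetwork

        renamed = SimilarityNetwork(graph=renamed_graph, min_SI=net.min_SI)
        clusters2 = mcl_cluster(renamed)
        nodes = sorted(net.graph.nodes)
        ari = adjusted_rand(
            [clusters[n] for n in nodes], [clusters2[mapping[n]] for n in nodes]
        )
        assert ari == pytest.approx(1.0)

    def test_bad_parameters_rejected(self, rng):
        net, _ = _block_network(rng)
        with pytest.raises(ValueError):
            mcl_cluster(net, inflation=1.0)
        with pytest.raises(ValueError):
            mcl_cluster(net, expansion=1)


class TestConnectivity:
    def test_star_graph(self):
        rows = [("hub", f"leaf{i}", 6.0) for i in range(5)]
        labels = {"hub": "unknown", **{f"leaf{i}": "unknown" for i in range(5)}}
        net = build_network(_hits(rows), labels)
        table = node_connectivity(net)
        assert table.iloc[0]["node"] == "hub"
        assert table.iloc[0]["degree"] == 5
        assert (table.iloc[1:]["degree"] == 1).all()

    def test_edgeless_all_zero(self):
        labels = {"A": "unknown", "B": "unknown"}
        net = build_network(_hits([]), labels)
        assert (node_connectivity(net)["degree"] == 0).all()

    def test_random_graph_matches_recount(self, rng):
        net, _ = _block_network(rng, n_blocks=2, per_block=10)
        table = node_connectivity(net)
        edges = list(net.graph.edges)
        expected = naive_degrees(edges, list(net.graph.nodes))
        for node, degree in table.itertuples(index=False):
            assert degree == expected[node]
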