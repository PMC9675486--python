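import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from implinet import booleannet, network, scoring, stepminer, synthetic
from implinet.network import (
    SignaturePath,
    build_cluster_graph,
    build_clusters,
    enumerate_paths,
    refine_clusters,
    select_signature,
)

from conftest import step_matrix


def pair_table(rows):
    """Minimal implication table from (gene_a, gene_b, relation) triples."""
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "relation"])
    df["S1"] = 5.0
    df["p1"] = 0.0
    df["S2"] = np.nan
    df["p2"] = np.nan
    df["n_usable"] = 60
    df["passes"] = df["relation"] != "none"
    return df


class TestBuildClusters:
    def test_clique_plus_isolate(self):
        table = pair_table(
            [("A", "B", "equivalent"), ("A", "C", "equivalent"), ("B", "C", "equivalent")]
        )
        clusters = build_clusters(table, genes=["A", "B", "C", "D"])
        assert [c.members for c in clusters] == [["A", "B", "C"], ["D"]]
        assert clusters[0].seed_gene == "A"

    def test_star_splits_low_sharing_leaf(self):
        # B and C are equivalent only to the hub A and share too little with
        # each other; only the first-admitted leaf stays with the hub
        table = pair_table([("A", "B", "equivalent"), ("A", "C", "equivalent")])
        clusters = build_clusters(table, genes=["A", "B", "C"])
        assert [c.members for c in clusters] == [["A", "B"], ["C"]]

    def test_empty_table_gives_singletons(self):
        clusters = build_clusters(pair_table([]), genes=["X", "Y"])
        assert [c.members for c in clusters] == [["X"], ["Y"]]

    def test_partition_property(self, fitted, default_cohort):
        _, _, truth = default_cohort
        informative = list(fitted.ternary.informative_codes().index)
        assigned = [g for c in fitted.clusters for g in c.members]
        assert sorted(assigned) == sorted(informative)

    def test_planted_cluster_recovery(self, fitted, default_cohort):
        _, _, truth = default_cohort
        predicted = {g: c.cluster_id for c in fitted.clusters for g in c.members}
        planted = [g for g, c in truth.gene_to_cluster.items() if c != "background"]
        ari = adjusted_rand_score(
            [truth.gene_to_cluster[g] for g in planted], [predicted[g] for g in planted]
        )
        assert ari >= 0.9


class TestRefineClusters:
    def test_member_dropped_when_not_replicating(self):
        clusters = build_clusters(
            pair_table(
                [("A", "B", "equivalent"), ("A", "C", "equivalent"), ("B", "C", "equivalent")]
            )
        )
        second = pair_table([("A", "B", "equivalent"), ("A", "C", "none"), ("B", "C", "none")])
        refined = refine_clusters(clusters, second)
        assert refined[0].members == ["A", "B"]


class TestClusterGraph:
    def test_opposite_pair_support_one(self):
        m = step_matrix({"A1": [0, 1], "A2": [0, 1], "B1": [1, 0], "B2": [1, 0]})
        table = booleannet.all_pairs(stepminer.ternarize(m))
        clusters = build_clusters(table)
        graph = build_cluster_graph(clusters, table)
        edges = list(graph.graph.edges(data=True))
        assert len(edges) == 1
        assert edges[0][2]["relation"] == "opposite" and edges[0][2]["support"] == 1.0

    def test_no_cross_significance_no_edge(self):
        table = pair_table(
            [("A1", "A2", "equivalent"), ("B1", "B2", "equivalent"), ("A1", "B1", "none"),
             ("A1", "B2", "none"), ("A2", "B1", "none"), ("A2", "B2", "none")]
        )
        graph = build_cluster_graph(build_clusters(table), table)
        assert graph.graph.number_of_edges() == 0

    def test_asymmetric_chain_recovered(self):
        # second block HIGH in states 2+3, third block HIGH only in state 3
        m = step_matrix({"B1": [0, 1, 1], "B2": [0, 1, 1], "C1": [0, 0, 1], "C2": [0, 0, 1]})
        table = booleannet.all_pairs(stepminer.ternarize(m))
        clusters = build_clusters(table)
        graph = build_cluster_graph(clusters, table)
        by_seed = {c.seed_gene: c.cluster_id for c in clusters}
        rel = graph.graph.edges[by_seed["B1"], by_seed["C1"]]["relation"]
        assert rel == "low=>low"  # B low forbids C high, i.e. C high => B high

    def test_isomorphism_under_gene_relabeling(self):
        m = step_matrix({"A1": [0, 1], "A2": [0, 1], "B1": [1, 0], "B2": [1, 0]})
        renamed = m.rename(index={"A1": "X1", "A2": "X2", "B1": "Y1", "B2": "Y2"})
        g1 = build_cluster_graph(
            build_clusters(t1 := booleannet.all_pairs(stepminer.ternarize(m))), t1
        )
        g2 = build_cluster_graph(
            build_clusters(t2 := booleannet.all_pairs(stepminer.ternarize(renamed))), t2
        )
        e1 = [(d["relation"], d["support"]) for _, _, d in g1.graph.edges(data=True)]
        e2 = [(d["relation"], d["support"]) for _, _, d in g2.graph.edges(data=True)]
        assert sorted(e1) == sorted(e2)

    def test_graph_round_trip_dict(self):
        m = step_matrix({"A1": [0, 1], "A2": [0, 1], "B1": [1, 0]})
        table = booleannet.all_pairs(stepminer.ternarize(m))
        graph = build_cluster_graph(build_clusters(table), table)
        assert network.ClusterGraph.from_dict(graph.to_dict()) == graph


class TestSelectSignature:
    @pytest.fixture()
    def toy(self):
        # five 2-gene clusters with distinct patterns over four sample blocks
        m = step_matrix(
            {
                "A1": [0, 0, 1, 1], "A2": [0, 0, 1, 1],
                "B1": [1, 1, 0, 0], "B2": [1, 1, 0, 0],
                "C1": [0, 1, 1, 1], "C2": [0, 1, 1, 1],
                "D1": [1, 0, 0, 0], "D2": [1, 0, 0, 0],
                "E1": [0, 0, 0, 1], "E2": [0, 0, 0, 1],
            },
            n_per_level=10,
        )
        rng = np.random.default_rng(12)
        m = m + rng.normal(0, 0.4, m.shape)  # noise so path AUCs differ
        ternary = stepminer.ternarize(m, min_per_side=2)
        table = booleannet.all_pairs(ternary, min_samples=10)
        clusters = build_clusters(table)
        graph = build_cluster_graph(clusters, table)
        labels = pd.Series(
            ["control"] * 20 + ["case"] * 20, index=m.columns, name="class_label"
        )
        return graph, m, ternary.fits, labels

    def test_ranking_matches_exhaustive_oracle(self, toy):
        graph, m, fits, labels = toy
        ranked = select_signature(graph, m, fits, labels, "case", max_len=3)

        # oracle: enumerate every simple directed path by hand and score it
        nodes = sorted(graph.graph.nodes)
        directions = {c.cluster_id: c.direction for c in graph.clusters}
        oracle = []
        for length in (1, 2, 3):
            for path in itertools.permutations(nodes, length):
                if any(not graph.graph.has_edge(a, b) for a, b in zip(path, path[1:])):
                    continue
                sig = network.make_signature(path, directions)
                scores = scoring.composite_score(sig, m, fits, graph.members_by_id)
                auc = roc_auc_score((labels == "case").astype(int), scores)
                oracle.append((-auc, length, path))
        oracle.sort()
        assert [tuple(s.cluster_ids) for s in ranked] == [p for _, _, p in oracle]
        assert ranked[0].auc == pytest.approx(-oracle[0][0])

    def test_max_len_one_returns_best_single_cluster(self, toy):
        graph, m, fits, labels = toy
        ranked = select_signature(graph, m, fits, labels, "case", max_len=1)
        assert all(len(s.cluster_ids) == 1 for s in ranked)

    def test_planted_separation_reaches_auc_one(self, fitted):
        ranked = fitted.select_signature(case_label="EAC", max_len=2)
        assert ranked[0].auc == 1.0

    def test_weights_signed_by_direction_and_position(self):
        sig = network.make_signature(("C1", "C2"), {"C1": "down", "C2": "up"})
        assert sig.weights == [-1, 2]


class TestSignaturePath:
    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            SignaturePath(cluster_ids=["C1"], weights=[0])

    def test_enumerate_paths_respects_edges(self):
        import networkx as nx

        g = nx.DiGraph([("a", "b"), ("b", "c")])
        paths = enumerate_paths(g, 3)
        assert ("a", "b", "c") in paths and ("c", "b") not in paths
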