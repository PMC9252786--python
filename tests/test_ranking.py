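import itertools

import networkx as nx
import pytest

from drugnet import (
    CapabilityError,
    ScoreMap,
    Subnetwork,
    degree_to_seeds,
    drug_gene_graph,
    gene_graph,
    harmonic_to_seeds,
    keypathwayminer_greedy,
    mst_view,
    multi_steiner,
    network_proximity,
    rank_drugs,
    rank_targets,
    summarize_tasks,
    trustrank,
)


def score_map(scores, seeds=frozenset(), algorithm="degree", tag=""):
    return ScoreMap(scores, algorithm, {}, frozenset(seeds), tag)


class TestRankTargets:
    def test_max_normalization(self, small_interactome):
        r = rank_targets(score_map({"A": 2.0, "B": 1.0}), small_interactome)
        by = dict(zip(r.rows["node_id"], r.rows["normalized_score"]))
        assert by == {"A": 1.0, "B": 0.5}

    def test_exclude_seeds_removes_exactly_the_seed_rows(self, small_interactome):
        sm = score_map({g: 1.0 for g in "ABCDE"}, seeds={"A", "B"})
        with_seeds = rank_targets(sm, small_interactome, include_seeds=True)
        without = rank_targets(sm, small_interactome, include_seeds=False)
        assert set(with_seeds.node_ids()) - set(without.node_ids()) == {"A", "B"}

    def test_top_n_matches_independent_full_sort(self, small_interactome):
        G = gene_graph(small_interactome)
        sm = harmonic_to_seeds(G, {"A"})
        full = rank_targets(sm, small_interactome, include_seeds=True)
        top = rank_targets(sm, small_interactome, top_n=3, include_seeds=True)
        rows = sorted(
            ((n, s) for n, s in sm.scores.items()),
            key=lambda ns: (-ns[1], small_interactome.gene_degree(ns[0]), ns[0]),
        )
        assert top.node_ids() == [n for n, _ in rows[:3]] == full.node_ids()[:3]

    def test_all_zero_scores_warn_but_are_valid(self, small_interactome, caplog):
        with caplog.at_level("WARNING", logger="drugnet"):
            r = rank_targets(score_map({"A": 0.0, "B": 0.0}), small_interactome)
        assert set(r.rows["normalized_score"]) == {0.0}

    def test_subnetwork_ranked_by_interactome_degree(self, small_interactome):
        sub = Subnetwork({"A", "C"}, {("A", "C")} & set(), "kpm")
        r = rank_targets(sub, small_interactome, include_seeds=True)
        # degree(C)=3 > degree(A)=1: tie on score 1 -> degree ascending
        assert r.node_ids() == ["A", "C"]
        assert list(r.rows["degree"]) == [1, 3]

    def test_proximity_cannot_rank_targets(self, small_interactome):
        G = gene_graph(small_interactome)
        res = network_proximity(G, {"A"}, small_interactome,
                                n_permutations=20, min_bin_size=2)
        with pytest.raises(CapabilityError):
            rank_targets(res, small_interactome)


class TestRankDrugs:
    def test_top_drug_has_normalized_score_one(self, small_interactome):
        sm = trustrank(drug_gene_graph(small_interactome), {"A", "B"})
        r = rank_drugs(sm, small_interactome, seeds={"A", "B"})
        assert r.rows["normalized_score"].iloc[0] == pytest.approx(1.0)
        assert set(r.rows["kind"]) == {"drug"}

    def test_aggregation_algorithms_refuse_drug_ranking(self, small_interactome):
        G = gene_graph(small_interactome)
        for result in (multi_steiner(G, {"A", "B"}),
                       keypathwayminer_greedy(G, {"A", "B"}, k=1)):
            with pytest.raises(CapabilityError, match="cannot rank drugs"):
                rank_drugs(result, small_interactome, seeds={"A", "B"})
        from drugnet import betweenness_among_seeds
        with pytest.raises(CapabilityError):
            rank_drugs(betweenness_among_seeds(G, {"A", "D"}),
                       small_interactome, seeds={"A", "D"})

    def test_indirect_drug_excluded_unless_requested(self, small_interactome):
        sm = trustrank(drug_gene_graph(small_interactome), {"A", "B"})
        # dY targets only D, dZ only E: both indirect for seeds {A,B}
        incl = rank_drugs(sm, small_interactome, include_indirect=True, seeds={"A", "B"})
        excl = rank_drugs(sm, small_interactome, include_indirect=False, seeds={"A", "B"})
        assert "dY" in incl.node_ids() and "dY" not in excl.node_ids()
        assert excl.node_ids() == ["dX"]

    def test_unapproved_toggle_changes_only_unapproved_rows(self, small_interactome):
        sm = trustrank(drug_gene_graph(small_interactome), {"A", "B"})
        incl = rank_drugs(sm, small_interactome, include_unapproved=True, seeds={"A", "B"})
        excl = rank_drugs(sm, small_interactome, include_unapproved=False, seeds={"A", "B"})
        removed = set(incl.node_ids()) - set(excl.node_ids())
        assert all(not small_interactome.drugs[d].approved for d in removed)
        assert removed == {"dY"}

    def test_drug_degree_is_dgi_degree(self, small_interactome):
        sm = trustrank(drug_gene_graph(small_interactome), {"A"})
        r = rank_drugs(sm, small_interactome, seeds={"A"})
        deg = dict(zip(r.rows["node_id"], r.rows["degree"]))
        assert deg["dX"] == 2 and deg["dY"] == 1

    def test_proximity_normalization_best_is_one(self, small_interactome):
        G = gene_graph(small_interactome)
        res = network_proximity(G, {"A", "B"}, small_interactome,
                                n_permutations=30, min_bin_size=2)
        r = rank_drugs(res, small_interactome, seeds={"A", "B"})
        assert r.rows["normalized_score"].iloc[0] == pytest.approx(1.0)
        assert list(r.rows["raw_score"]) == sorted(r.rows["raw_score"])  # ascending z

    def test_filter_monotonicity_never_adds_rows(self, small_interactome):
        sm = trustrank(drug_gene_graph(small_interactome), {"A", "B"})
        base = rank_drugs(sm, small_interactome, seeds={"A", "B"})
        for unapp, indir in itertools.product([True, False], repeat=2):
            r = rank_drugs(sm, small_interactome, include_unapproved=unapp,
                           include_indirect=indir, seeds={"A", "B"})
            assert set(r.node_ids()) <= set(base.node_ids())

    def test_tsv_shape_matches_drug_table(self, small_interactome, tmp_path):
        sm = trustrank(drug_gene_graph(small_interactome), {"A", "B"})
        r = rank_drugs(sm, small_interactome, seeds={"A", "B"})
        r.write_tsv(tmp_path / "drugs.tsv")
        lines = (tmp_path / "drugs.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["name", "approved", "atc_l", "cancerx",
                                        "score", "degree"]
        assert lines[1].split("\t")[4] == "1"  # top row scores exactly 1


class TestNormalizationIdempotence:
    def test_normalizing_twice_equals_once(self, small_interactome):
        sm = score_map({"A": 4.0, "B": 1.0, "C": 0.5})
        once = rank_targets(sm, small_interactome, include_seeds=True)
        renorm = score_map(dict(zip(once.rows["node_id"], once.rows["normalized_score"])))
        twice = rank_targets(renorm, small_interactome, include_seeds=True)
        assert list(once.rows["normalized_score"]) == list(twice.rows["normalized_score"])
        assert once.rows["normalized_score"].iloc[0] in (0.0, 1.0)


class TestSummarize:
    def test_identical_results_count_two(self, small_interactome):
        G = gene_graph(small_interactome)
        r = rank_targets(degree_to_seeds(G, {"A"}), small_interactome, include_seeds=True)
        summary = summarize_tasks([r, r], small_interactome)
        assert set(summary.counts.values()) == {2}

    def test_disjoint_results_count_one(self, small_interactome):
        a = Subnetwork({"A", "B"}, set(), "kpm", interactome_tag=small_interactome.tag)
        b = Subnetwork({"D", "E"}, set(), "kpm", interactome_tag=small_interactome.tag)
        summary = summarize_tasks([a, b], small_interactome)
        assert set(summary.counts.values()) == {1}
        assert set(summary.counts) == {"A", "B", "D", "E"}
        assert summary.graph.has_edge("A", "B")  # induced interactome edge
        assert not summary.graph.has_edge("B", "D")

    def test_three_tasks_match_hand_tally(self, small_interactome):
        tag = small_interactome.tag
        tasks = [Subnetwork(nodes, set(), "kpm", interactome_tag=tag)
                 for nodes in ({"A", "B"}, {"B", "C"}, {"B", "C", "D"})]
        for perm in itertools.permutations(tasks):
            summary = summarize_tasks(list(perm), small_interactome)
            assert summary.counts == {"A": 1, "B": 3, "C": 2, "D": 1}

    def test_mismatched_interactomes_rejected(self, small_interactome):
        a = Subnetwork({"A"}, set(), "kpm", interactome_tag="tag1")
        b = Subnetwork({"B"}, set(), "kpm", interactome_tag="tag2")
        with pytest.raises(ValueError, match="different interactomes"):
            summarize_tasks([a, b], small_interactome)

    def test_needs_two_results(self, small_interactome):
        a = Subnetwork({"A"}, set(), "kpm", interactome_tag=small_interactome.tag)
        with pytest.raises(ValueError):
            summarize_tasks([a], small_interactome)


class TestMstView:
    def test_connected_subset_gives_spanning_tree(self, small_interactome):
        G = gene_graph(small_interactome)
        sub = mst_view(G, {"B", "C", "E"})
        assert sub.nodes == {"B", "C", "E"}
        assert len(sub.edges) == 2

    def test_two_nodes_at_distance_three(self, small_interactome):
        G = gene_graph(small_interactome)
        sub = mst_view(G, {"A", "D"})
        assert len(sub.edges) == 3
        assert {"B", "C"} <= sub.nodes  # connectors on the path

    def test_connector_cost_not_beaten_by_exhaustive_alternatives(self):
        import itertools as it
        import numpy as np
        from conftest import random_gene_graph

        rng = np.random.default_rng(11)
        for _ in range(10):
            G = random_gene_graph(rng, n_max=10, connected=True)
            subset = set(np.random.default_rng(1).choice(
                sorted(G.nodes), size=min(4, len(G)), replace=False).tolist())
            view = mst_view(G, subset)
            got = sum(G[u][v]["cost"] for u, v in view.edges)
            # exhaustive: best spanning tree of the metric closure
            dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="cost"))
            best = min(
                sum(dist[u][v] for u, v in tree)
                for tree in it.combinations(it.combinations(sorted(subset), 2),
                                            len(subset) - 1)
                if nx.is_connected(nx.Graph(list(tree)))
                and len(nx.Graph(list(tree)).nodes) == len(subset)
            )
            assert got <= best + 1e-9

    def test_empty_subset_rejected(self, small_interactome):
        with pytest.raises(ValueError):
            mst_view(gene_graph(small_interactome), set())
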