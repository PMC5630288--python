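"""Subnetwork induction, LCC, modularity, spectral partitioning, overlay."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mirnet import (
    DegSelection,
    SpectralGraphPartitioner,
    induce_subnetwork,
    largest_connected_component,
    modularity,
    overlay_targets,
    spectral_partition,
)
from mirnet.interactome import InteractionRecord, build_consolidated_interactome

from .oracles import recount_modularity, union_find_lcc


def make_degs(up=(), down=()):
    return DegSelection(frozenset(up), frozenset(down), 1.5, 0.05)


def sbm_graph(rng, sizes=(50, 50, 50, 50), p_in=0.30, p_out=0.01):
    """Stochastic block model with lexicographically sortable node names."""
    labels = {}
    g = nx.Graph()
    pos = 0
    names = []
    for b, size in enumerate(sizes):
        for i in range(size):
            name = f"N{pos + i:04d}"
            labels[name] = b
            names.append(name)
        pos += size
    g.add_nodes_from(names)
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            p = p_in if labels[u] == labels[v] else p_out
            if rng.random() < p:
                g.add_edge(u, v)
    return g, labels


class TestInduceSubnetwork:
    def test_hand_example_with_bfs_oracle(self):
        records = [
            InteractionRecord(a, b, "db")
            for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("E", "F")]
        ]
        ci = build_consolidated_interactome(records)
        degs = make_degs(up=("A", "B", "E"), down=("C", "F"))
        result = induce_subnetwork(ci, degs)
        assert result.induced_edges == {("A", "B"), ("B", "C"), ("E", "F")}
        # BFS oracle for the LCC
        oracle_nodes, oracle_edges = union_find_lcc(
            result.induced_nodes, result.induced_edges
        )
        assert result.lcc_nodes == oracle_nodes == {"A", "B", "C"}
        assert result.lcc_edges == oracle_edges
        assert result.n_components == 2

    def test_degs_disjoint_from_ci_gives_empty_result(self, small_ci, caplog):
        with caplog.at_level("WARNING"):
            result = induce_subnetwork(small_ci, make_degs(up=("X", "Y")))
        assert not result.induced_edges and not result.lcc_nodes
        assert "empty" in caplog.text

    def test_all_nodes_de_recovers_full_ci(self, small_ci):
        degs = make_degs(up=tuple(small_ci.nodes))
        result = induce_subnetwork(small_ci, degs)
        assert result.induced_edges == small_ci.edges
        assert result.induced_nodes == small_ci.nodes

    def test_isolated_degs_reported_separately(self, small_ci):
        # D interacts only with C; C not selected → D has no DEG-DEG edge
        degs = make_degs(up=("A", "B", "D"))
        result = induce_subnetwork(small_ci, degs)
        assert result.induced_edges == {("A", "B")}
        assert result.isolated_degs == {"D"}


class TestLargestConnectedComponent:
    def test_two_components_enumerated(self):
        nodes = {"A", "B", "C", "D", "E"}
        edges = {("A", "B"), ("B", "C"), ("D", "E")}
        lcc_nodes, lcc_edges = largest_connected_component(nodes, edges)
        assert lcc_nodes == {"A", "B", "C"}
        assert lcc_edges == {("A", "B"), ("B", "C")}

    def test_isolated_single_node(self):
        assert largest_connected_component({"Z"}, set()) == ({"Z"}, set())
        assert largest_connected_component(set(), set()) == (set(), set())

    def test_tie_broken_by_smallest_member(self):
        lcc_nodes, _ = largest_connected_component(
            {"A", "B", "C", "D"}, {("C", "D"), ("A", "B")}
        )
        assert lcc_nodes == {"A", "B"}

    def test_agrees_with_union_find_on_random_graphs(self):
        """200 random graphs (n ≤ 50): exact agreement with union-find."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            p = float(rng.uniform(0, 0.15))
            nodes = [f"N{i:02d}" for i in range(n)]
            edges = {
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < p
            }
            got = largest_connected_component(nodes, edges)
            expected = union_find_lcc(nodes, edges)
            assert got == expected


class TestModularity:
    def test_single_module_is_zero(self):
        g = nx.complete_graph(5)
        assert modularity(g, {n: 0 for n in g}) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        """Hand evaluation: m=6, each e_c=3, d_c=6 ⇒ Q = 2·(0.5 − 0.25) = 0.5."""
        g = nx.Graph(
            [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]
        )
        assignment = {n: 0 if n in "ABC" else 1 for n in g}
        assert modularity(g, assignment) == pytest.approx(0.5)

    def test_empty_graph_defined_as_zero(self):
        g = nx.Graph()
        g.add_nodes_from("AB")
        assert modularity(g, {"A": 0, "B": 1}) == 0.0

    def test_random_partition_matches_recount_and_networkx(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(40, 0.15, seed=11)
        assignment = {n: int(rng.integers(0, 4)) for n in g}
        q = modularity(g, assignment)
        assert q == pytest.approx(
            recount_modularity(g.nodes, g.edges, assignment), abs=1e-12
        )
        communities = [
            {n for n in g if assignment[n] == c} for c in set(assignment.values())
        ]
        q_nx = nx.community.modularity(g, [c for c in communities if c])
        assert q == pytest.approx(q_nx, abs=1e-12)

    def test_uncovered_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            modularity(g, {0: 0, 1: 0})


class TestSpectralPartition:
    def test_two_cliques_with_bridge_recovered_exactly(self):
        """Planted structure: two 10-cliques joined by one bridge edge."""
        g = nx.Graph()
        left = [f"A{i:02d}" for i in range(10)]
        right = [f"B{i:02d}" for i in range(10)]
        for grp in (left, right):
            g.add_edges_from(
                (grp[i], grp[j]) for i in range(10) for j in range(i + 1, 10)
            )
        g.add_edge(left[0], right[0])
        part = spectral_partition(g, min_module_size=3, seed=0)
        assert part.n_modules == 2
        assert {part.assignment[n] for n in left} != {part.assignment[n] for n in right}
        assert len({part.assignment[n] for n in left}) == 1
        assert len({part.assignment[n] for n in right}) == 1
        assert part.modularity == pytest.approx(
            recount_modularity(g.nodes, g.edges, part.assignment), abs=1e-12
        )

    def test_single_clique_stays_whole(self):
        g = nx.complete_graph(12)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
        part = spectral_partition(g, min_module_size=3, seed=0)
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0)

    def test_size_floor_prevents_split(self):
        g = nx.path_graph(2)
        g = nx.relabel_nodes(g, {0: "A", 1: "B"})
        part = spectral_partition(g, min_module_size=3, seed=0)
        assert part.n_modules == 1

    def test_assignment_is_contiguous_disjoint_cover(self):
        rng = np.random.default_rng(2)
        g, _ = sbm_graph(rng, sizes=(30, 30), p_in=0.4, p_out=0.02)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        part = spectral_partition(g, min_module_size=5, seed=0)
        assert set(part.assignment) == set(g.nodes)
        assert sorted(set(part.assignment.values())) == list(range(part.n_modules))
        assert part.modularity == pytest.approx(
            modularity(g, part.assignment), abs=1e-12
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        g, _ = sbm_graph(rng, sizes=(40, 40), p_in=0.3, p_out=0.02)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        p1 = spectral_partition(g, min_module_size=5, seed=9)
        p2 = spectral_partition(g, min_module_size=5, seed=9)
        assert p1.assignment == p2.assignment
        assert p1.modularity == p2.modularity

    def test_planted_sbm_recovery(self):
        """SBM (4×50, p_in=0.30, p_out=0.01): ARI ≥ 0.9 in ≥ 9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            g, labels = sbm_graph(rng)
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            part = spectral_partition(g, min_module_size=5, seed=seed)
            nodes = sorted(g.nodes)
            ari = adjusted_rand_score(
                [labels[n] for n in nodes], [part.assignment[n] for n in nodes]
            )
            hits += ari >= 0.9
        assert hits >= 9

    def test_recovery_degrades_as_blocks_blur(self):
        """Mean ARI decreases on the grid p_out ∈ {0.01, 0.10, 0.30 (=p_in)}."""
        mean_aris = []
        for p_out in (0.01, 0.10, 0.30):
            aris = []
            for seed in range(3):
                rng = np.random.default_rng(2000 + seed)
                g, labels = sbm_graph(rng, sizes=(40, 40, 40), p_out=p_out)
                g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
                part = spectral_partition(g, min_module_size=5, seed=seed)
                nodes = sorted(g.nodes)
                aris.append(
                    adjusted_rand_score(
                        [labels[n] for n in nodes],
                        [part.assignment[n] for n in nodes],
                    )
                )
            mean_aris.append(np.mean(aris))
        assert mean_aris[0] > mean_aris[1] > mean_aris[2]


class TestSpectralGraphPartitionerEstimator:
    def test_sklearn_api(self):
        g = nx.complete_graph(6)
        adj = nx.to_scipy_sparse_array(g, format="csr")
        est = SpectralGraphPartitioner(min_module_size=2, random_state=0)
        labels = est.fit_predict(adj)
        assert labels.shape == (6,)
        params = est.get_params()
        assert params == {"min_module_size": 2, "random_state": 0}
        est.set_params(min_module_size=3)
        assert est.min_module_size == 3

    def test_rejects_asymmetric_input(self):
        a = np.zeros((3, 3))
        a[0, 1] = 1
        with pytest.raises(ValueError):
            SpectralGraphPartitioner().fit(a)


class TestOverlayTargets:
    def test_union_intersected_with_nodes(self):
        ann = overlay_targets(
            {"A", "B", "D"}, {"alg1": {"A", "B"}, "alg2": {"B", "C"}}
        )
        assert ann.predicted_targets == {"A", "B"}
        assert ann.per_algorithm == {"alg1": {"A", "B"}, "alg2": {"B"}}

    def test_node_in_all_lists_flagged_once(self):
        ann = overlay_targets({"A"}, {"a1": {"A"}, "a2": {"A"}, "a3": {"A"}})
        assert ann.predicted_targets == {"A"}

    def test_no_overlap_warns(self, caplog):
        with caplog.at_level("WARNING"):
            ann = overlay_targets({"A"}, {"a1": {"X"}})
        assert not ann.predicted_targets
        assert "no predicted targets" in caplog.text

    def test_vote_threshold(self):
        ann = overlay_targets(
            {"A", "B"}, {"a1": {"A", "B"}, "a2": {"A"}}, vote_threshold=2
        )
        assert ann.predicted_targets == {"A"}
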