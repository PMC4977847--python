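"""Graph construction, iterated weighting, bridges and module decomposition."""

import networkx as nx
import numpy as np
import pytest

from mirx.netcore import (GeneNetwork, build_graph, decompose_modules,
                          pagerank_weights, select_bridges)


def union_find_components(nodes, edges):
    """Independent component counter (union-find)."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(n) for n in nodes})


class TestBuildGraph:
    def test_dedup_and_self_loop_drop(self):
        net = build_graph([("a", "b"), ("b", "a"), ("c", "c")])
        assert net.n_nodes == 3
        assert net.n_edges == 1

    def test_path_degrees(self):
        net = build_graph([("a", "b"), ("b", "c")])
        assert net.degree("b") == 2
        assert net.degree("a") == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_graph([])

    def test_adjacency_symmetric_zero_diagonal(self):
        net = build_graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        A = net.adjacency()
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert A.sum() == 2 * net.n_edges


class TestPagerankWeights:
    def test_single_isolated_node_keeps_weight_one(self):
        g = nx.Graph()
        g.add_node("solo")
        w = pagerank_weights(GeneNetwork(g))
        assert w.weights.tolist() == [1.0]
        assert w.iteration_count == 0

    def test_triangle_symmetry(self):
        net = build_graph([("a", "b"), ("b", "c"), ("a", "c")])
        w = pagerank_weights(net, tol=1e-12)
        assert np.allclose(w.weights, 1.0)

    def test_star_plus_chord_matches_eigenvector_oracle(self):
        edges = [("c", "a"), ("c", "b"), ("c", "d"), ("c", "e"), ("a", "b")]
        net = build_graph(edges)
        w = pagerank_weights(net, tol=1e-13, max_iter=100000)
        vals, vecs = np.linalg.eigh(net.adjacency())
        perron = np.abs(vecs[:, np.argmax(vals)])
        perron *= net.n_nodes / perron.sum()
        assert np.max(np.abs(w.weights - perron)) < 1e-6

    def test_total_weight_conserved_each_iteration(self):
        net = build_graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        for k in range(1, 6):
            w = pagerank_weights(net, tol=0.0, max_iter=k)
            assert w.weights.sum() == pytest.approx(net.n_nodes)

    def test_convergence_flagging(self):
        net = build_graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        w = pagerank_weights(net, tol=1e-12, max_iter=2)
        assert not w.converged
        w = pagerank_weights(net, tol=0.005)
        assert w.converged and w.final_perturbation < 0.005

    def test_damped_mode_matches_networkx(self):
        rng = np.random.default_rng(17)
        nodes = [f"n{i}" for i in range(40)]
        edges = [(nodes[i], nodes[j]) for i in range(40) for j in range(i)
                 if rng.random() < 0.12]
        net = build_graph(edges)
        w = pagerank_weights(net, mode="damped", tol=1e-10, max_iter=10000)
        ref = nx.pagerank(net.graph, alpha=0.85, tol=1e-12, max_iter=1000)
        mine = w.weights / w.weights.sum()
        theirs = np.array([ref[n] for n in w.nodes])
        assert np.max(np.abs(mine - theirs)) < 1e-8

    def test_isolated_node_weight_zero_in_adjacency_mode(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("iso")
        w = pagerank_weights(GeneNetwork(g), tol=1e-9)
        assert w.as_dict()["iso"] == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pagerank_weights(build_graph([("a", "b")]), mode="bogus")


class TestSelectBridges:
    def fake_weights(self, pairs):
        nodes, ws = zip(*pairs)
        from mirx.netcore import WeightVector
        return WeightVector(nodes=tuple(nodes), weights=np.array(ws, float),
                            degrees=np.zeros(len(nodes)), mode="adjacency",
                            iteration_count=1, final_perturbation=0.0,
                            converged=True)

    def test_top_k(self):
        w = self.fake_weights([("a", 5), ("b", 4), ("c", 3), ("d", 2),
                               ("e", 1)])
        assert select_bridges(w, 2) == ["a", "b"]

    def test_k_equals_n_returns_all_sorted(self):
        w = self.fake_weights([("a", 1), ("b", 3), ("c", 2)])
        assert select_bridges(w, 3) == ["b", "c", "a"]

    def test_k_too_large_rejected(self):
        w = self.fake_weights([("a", 1)])
        with pytest.raises(ValueError):
            select_bridges(w, 2)

    def test_weight_tie_broken_by_degree_then_id(self):
        from mirx.netcore import WeightVector
        w = WeightVector(nodes=("a", "b", "c"),
                         weights=np.array([1.0, 1.0, 1.0]),
                         degrees=np.array([1.0, 5.0, 5.0]), mode="adjacency",
                         iteration_count=1, final_perturbation=0.0,
                         converged=True)
        assert select_bridges(w, 2) == ["b", "c"]


class TestDecompose:
    def barbell(self):
        edges = []
        left = [f"L{i}" for i in range(5)]
        right = [f"R{i}" for i in range(5)]
        for grp in (left, right):
            edges += [(a, b) for i, a in enumerate(grp) for b in grp[i + 1:]]
        edges += [("L0", "hub"), ("R0", "hub")]
        return build_graph(edges), left, right

    def test_barbell_splits_into_two_modules(self):
        net, left, right = self.barbell()
        decomp = decompose_modules(net, ["hub"])
        assert len(decomp.modules) == 2
        members = {m.member_genes for m in decomp.modules}
        assert members == {frozenset(left), frozenset(right)}
        assert all(m.central_bridges == frozenset({"hub"})
                   for m in decomp.modules)

    def test_no_bridges_one_module(self):
        net, *_ = self.barbell()
        decomp = decompose_modules(net, [])
        assert len(decomp.modules) == 1
        assert decomp.modules[0].member_genes == frozenset(net.nodes)

    def test_unknown_bridge_rejected(self):
        net, *_ = self.barbell()
        with pytest.raises(ValueError):
            decompose_modules(net, ["nope"])

    def test_small_components_reported_as_residue(self):
        net = build_graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "x"),
                           ("x", "p"), ("p", "q")])
        decomp = decompose_modules(net, ["x"], min_size=3)
        assert [set(m.member_genes) for m in decomp.modules] == \
            [{"a", "b", "c"}]
        assert decomp.residue == [frozenset({"p", "q"})]

    def test_partition_of_non_bridge_nodes(self):
        rng = np.random.default_rng(23)
        nodes = [f"n{i}" for i in range(50)]
        edges = [(nodes[i], nodes[j]) for i in range(50) for j in range(i)
                 if rng.random() < 0.06]
        net = build_graph(edges + [(nodes[0], nodes[1])])
        bridges = nodes[:5]
        decomp = decompose_modules(net, bridges, min_size=3)
        seen = [g for m in decomp.modules for g in m.member_genes] + \
            [g for c in decomp.residue for g in c]
        assert sorted(seen) == sorted(set(net.nodes) - set(bridges))

    def test_component_counts_match_union_find_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(10, 60))
            nodes = [f"n{i}" for i in range(n)]
            edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i)
                     if rng.random() < 0.05]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            decomp = decompose_modules(GeneNetwork(g), [], min_size=1)
            assert len(decomp.modules) == union_find_components(nodes, edges)
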