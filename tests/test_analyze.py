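"""Bipartite projection and topology statistics against brute-force oracles."""

import random
from itertools import combinations

import pytest

from hetnetkit.analyze import (
    degree_opacity,
    largest_component,
    ne_ratio,
    similarity_projection,
    topology_report,
)
from hetnetkit.core import EdgeTypeError, HetNet

from .conftest import random_hetnet


def bipartite_net(rng, n_dis, n_gene, n_edges):
    net = HetNet()
    diseases = [f"D{i:03d}" for i in range(n_dis)]
    genes = [f"G{i:03d}" for i in range(n_gene)]
    for d in diseases:
        net.add_node(d, "phenotype")
    for g in genes:
        net.add_node(g, "gene")
    pairs = rng.sample([(d, g) for d in diseases for g in genes],
                       min(n_edges, n_dis * n_gene))
    for d, g in pairs:
        net.add_edge(d, g, "phenotype-gene")
    return net, diseases, {d: {g for dd, g in pairs if dd == d} for d in diseases}


class TestSimilarityProjection:
    def test_three_shared_genes_at_threshold_three(self):
        # "more than 2 shared genes" == min_shared 3
        net = HetNet()
        for d in ("D1", "D2"):
            net.add_node(d, "phenotype")
        for i in range(3):
            g = f"G{i}"
            net.add_node(g, "gene")
            net.add_edge("D1", g, "phenotype-gene")
            net.add_edge("D2", g, "phenotype-gene")
        sim = similarity_projection(net, "phenotype", "gene", min_shared=3)
        assert sim.weight("D1", "D2") == 3

    def test_single_node_no_edges(self):
        net = HetNet()
        net.add_node("D1", "phenotype")
        sim = similarity_projection(net, "phenotype", "gene")
        assert sim.n_nodes == 1 and sim.n_edges == 0

    def test_unlinked_kinds_rejected(self):
        with pytest.raises(EdgeTypeError):
            similarity_projection(HetNet(), "drug", "tissue")

    def test_matches_all_pairs_intersection_oracle(self):
        rng = random.Random(23)
        net, diseases, nbrs = bipartite_net(rng, 20, 60, 150)
        for t in (1, 2, 3):
            sim = similarity_projection(net, "phenotype", "gene", min_shared=t)
            expected = {
                (a, b): len(nbrs[a] & nbrs[b])
                for a, b in combinations(diseases, 2)
                if len(nbrs[a] & nbrs[b]) >= t
            }
            got = {(min(a, b), max(a, b)): w
                   for a, b, w in sim.graph.edges(data="weight")}
            assert got == expected

    def test_threshold_monotone_and_symmetric(self):
        rng = random.Random(6)
        net, _, _ = bipartite_net(rng, 15, 40, 120)
        prev = None
        for t in (1, 2, 3, 4):
            sim = similarity_projection(net, "phenotype", "gene", min_shared=t)
            edges = {frozenset((a, b)) for a, b in sim.graph.edges()}
            if prev is not None:
                assert edges <= prev
            prev = edges
            for a, b in sim.graph.edges():
                assert sim.weight(a, b) == sim.weight(b, a)

    def test_no_self_edges(self):
        rng = random.Random(2)
        net, _, _ = bipartite_net(rng, 10, 20, 60)
        sim = similarity_projection(net, "phenotype", "gene")
        assert all(a != b for a, b in sim.graph.edges())


class TestNeRatio:
    def test_disease_gene_worked_example(self):
        # 1547 nodes over 2010 edges prints as 0.77
        assert ne_ratio(1547, 2010) == 0.77

    def test_half_up_rounding(self):
        assert ne_ratio(125, 1000) == 0.13  # 0.125 rounds half-up

    def test_no_edges_is_absent(self):
        assert ne_ratio(10, 0) is None


class TestTopologyReport:
    def test_counts_and_ratio(self):
        rng = random.Random(1)
        net, _, _ = bipartite_net(rng, 20, 80, 150)
        rep = topology_report(net)
        assert rep.n_nodes == 100 and rep.n_edges == 150
        assert rep.ne_ratio == ne_ratio(100, 150)

    def test_empty_network(self):
        rep = topology_report(HetNet())
        assert rep.n_nodes == 0 and rep.ne_ratio is None
        assert rep.component_sizes == []

    def test_degree_sum_identity(self):
        net = random_hetnet(random.Random(14), n_edges=60)
        rep = topology_report(net)
        assert sum(d * c for d, c in rep.degree_distribution.items()) \
            == 2 * rep.n_edges_simple

    def test_component_sizes_sum_to_node_count(self):
        net = random_hetnet(random.Random(15), n_edges=30)
        rep = topology_report(net)
        assert sum(rep.component_sizes) == rep.n_nodes

    def test_matches_dense_bfs_oracle(self):
        rng = random.Random(77)
        net = random_hetnet(random.Random(77), n_per_kind=6, n_edges=35)
        rep = topology_report(net)
        # independent oracle: adjacency dict + hand BFS
        adj: dict[str, set[str]] = {n: set() for n in net.nodes()}
        for u, v, _, _ in net.edges():
            if u != v:
                adj[u].add(v)
                adj[v].add(u)
        # components
        seen, comps = set(), []
        for n in adj:
            if n in seen:
                continue
            comp, stack = set(), [n]
            while stack:
                x = stack.pop()
                if x not in comp:
                    comp.add(x)
                    stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(comp)
        assert sorted((len(c) for c in comps), reverse=True) == rep.component_sizes
        # degree distribution
        deg_dist: dict[int, int] = {}
        for n in adj:
            d = len(adj[n])
            deg_dist[d] = deg_dist.get(d, 0) + 1
        assert deg_dist == rep.degree_distribution
        # path-length histogram of the largest component via BFS per node
        lcc = max(comps, key=len)
        hist: dict[int, int] = {}
        for src in lcc:
            dist = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for x in frontier:
                    for y in adj[x]:
                        if y not in dist:
                            dist[y] = dist[x] + 1
                            nxt.append(y)
                frontier = nxt
            for dst, h in dist.items():
                if src < dst:
                    hist[h] = hist.get(h, 0) + 1
        assert hist == rep.lcc_path_length_distribution

    def test_neighborhood_connectivity_oracle(self):
        net = random_hetnet(random.Random(5), n_per_kind=5, n_edges=25)
        rep = topology_report(net)
        adj: dict[str, set[str]] = {n: set() for n in net.nodes()}
        for u, v, _, _ in net.edges():
            if u != v:
                adj[u].add(v)
                adj[v].add(u)
        by_deg: dict[int, list[float]] = {}
        for n, nbrs in adj.items():
            if nbrs:
                mean_nbr = sum(len(adj[m]) for m in nbrs) / len(nbrs)
                by_deg.setdefault(len(nbrs), []).append(mean_nbr)
        expected = {d: sum(v) / len(v) for d, v in by_deg.items()}
        assert expected.keys() == rep.neighborhood_connectivity.keys()
        for d in expected:
            assert rep.neighborhood_connectivity[d] == pytest.approx(expected[d])


class TestLargestComponent:
    def test_picks_biggest(self):
        net = HetNet()
        for i in range(5):
            net.add_node(f"G{i}", "gene")
        net.add_edge("G0", "G1", "gene-gene")
        net.add_edge("G1", "G2", "gene-gene")
        net.add_edge("G3", "G4", "gene-gene")
        lcc = largest_component(net)
        assert set(lcc.nodes()) == {"G0", "G1", "G2"}

    def test_connected_identity(self):
        net = HetNet()
        net.add_node("A", "gene")
        net.add_node("B", "gene")
        net.add_edge("A", "B", "gene-gene")
        assert set(largest_component(net).nodes()) == {"A", "B"}

    def test_empty_in_empty_out(self):
        assert largest_component(HetNet()).n_nodes == 0

    def test_size_matches_union_find_oracle(self):
        net = random_hetnet(random.Random(44), n_edges=30)
        parent = {n: n for n in net.nodes()}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v, _, _ in net.edges():
            parent[find(u)] = find(v)
        sizes: dict[str, int] = {}
        for n in parent:
            r = find(n)
            sizes[r] = sizes.get(r, 0) + 1
        assert largest_component(net).n_nodes == max(sizes.values())

    def test_tie_broken_by_smallest_member(self):
        net = HetNet()
        for n in ("A", "B", "C", "D"):
            net.add_node(n, "gene")
        net.add_edge("C", "D", "gene-gene")
        net.add_edge("A", "B", "gene-gene")
        assert set(largest_component(net).nodes()) == {"A", "B"}


class TestDegreeOpacity:
    def test_proportional_to_degree(self):
        net = HetNet()
        net.add_node("X1", "drug")
        net.add_node("X2", "drug")
        for i, d in enumerate(("D1", "D2", "D3", "D4", "D5", "D6")):
            net.add_node(d, "phenotype")
            net.add_edge("X2", d, "drug-phenotype")
            if i < 3:
                net.add_edge("X1", d, "drug-phenotype")
        op = degree_opacity(net, "drug")
        assert op == {"X1": 0.5, "X2": 1.0}

    def test_all_equal_degrees_all_one(self):
        net = HetNet()
        net.add_node("X1", "drug")
        net.add_node("X2", "drug")
        net.add_node("D1", "phenotype")
        net.add_edge("X1", "D1", "drug-phenotype")
        net.add_edge("X2", "D1", "drug-phenotype")
        assert degree_opacity(net, "drug") == {"X1": 1.0, "X2": 1.0}

    def test_absent_kind_empty(self):
        assert degree_opacity(HetNet(), "drug") == {}

    def test_matches_direct_recomputation(self):
        net = random_hetnet(random.Random(9), n_edges=50)
        op = degree_opacity(net, "gene")
        adj: dict[str, set[str]] = {n: set() for n in net.nodes()}
        for u, v, _, _ in net.edges():
            if u != v:
                adj[u].add(v)
                adj[v].add(u)
        peak = max(len(adj[g]) for g in net.nodes("gene"))
        for g in net.nodes("gene"):
            expected = len(adj[g]) / peak if peak else 0.0
            assert op[g] == pytest.approx(expected)
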