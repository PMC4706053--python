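"""Seed-and-expand construction and disease-degree filtering."""

import random

import pytest

from hetnetkit.construct import (
    BuildRequest,
    ResourceStore,
    build,
    subnetwork_by_min_disease_degree,
)
from hetnetkit.core import HetNet, MissingNodeError


def small_store() -> ResourceStore:
    store = ResourceStore()
    store.register_node("phenotype", "D1")
    store.register_node("phenotype", "D2")
    store.add_edge("phenotype-gene", "D1", "G1")
    store.add_edge("phenotype-gene", "D2", "G9")
    store.add_edge("gene-gene", "G1", "G2")
    store.add_edge("gene-gene", "G2", "G3")
    store.add_edge("drug-gene", "X1", "G1")
    return store


class TestBuild:
    def test_only_incident_edges_join(self):
        net = build(small_store(), BuildRequest.make("phenotype", ["D1"],
                                                     tier1=["phenotype-gene"]))
        assert set(net.nodes()) == {"D1", "G1"}
        assert net.n_edges == 1

    def test_tier2_adds_first_degree_ppi(self):
        net = build(small_store(), BuildRequest.make(
            "phenotype", ["D1"], tier1=["phenotype-gene"], tier2=["gene-gene"]))
        # G2 is G1's interaction partner; G3 is two hops out and stays absent
        assert "G2" in net and "G3" not in net
        assert net.has_edge("G1", "G2", "gene-gene")

    def test_isolated_seed_retained(self):
        store = small_store()
        store.register_node("phenotype", "D_LONELY")
        net = build(store, BuildRequest.make("phenotype", ["D_LONELY"],
                                             tier1=["phenotype-gene"]))
        assert set(net.nodes()) == {"D_LONELY"} and net.n_edges == 0

    def test_unknown_seed_raises(self):
        with pytest.raises(MissingNodeError):
            build(small_store(), BuildRequest.make("phenotype", ["NOPE"]))

    def test_seed_kind_restricted(self):
        with pytest.raises(ValueError):
            BuildRequest.make("tissue", ["BTO:1"])

    def test_closure_connects_tier2_additions(self):
        store = ResourceStore()
        store.add_edge("phenotype-gene", "D1", "G1")
        store.add_edge("phenotype-gene", "D1", "G2")
        store.add_edge("gene-gene", "G1", "G3")
        store.add_edge("gene-gene", "G2", "G4")
        store.add_edge("gene-gene", "G3", "G4")  # between tier2 additions
        req = BuildRequest.make("phenotype", ["D1"],
                                tier1=["phenotype-gene"], tier2=["gene-gene"])
        with_closure = build(store, req, close_within=True)
        without = build(store, req, close_within=False)
        assert with_closure.has_edge("G3", "G4", "gene-gene")
        assert not without.has_edge("G3", "G4", "gene-gene")

    def test_closure_invariant(self):
        net = build(small_store(), BuildRequest.make(
            "phenotype", ["D1", "D2"], tier1=["phenotype-gene", "drug-gene"],
            tier2=["gene-gene"]))
        nodes = set(net.nodes())
        for u, v, _, _ in net.edges():
            assert u in nodes and v in nodes


def random_store(rng: random.Random) -> ResourceStore:
    store = ResourceStore()
    diseases = [f"D{i}" for i in range(6)]
    genes = [f"G{i}" for i in range(15)]
    drugs = [f"X{i}" for i in range(4)]
    for d in diseases:
        store.register_node("phenotype", d)
    for _ in range(18):
        store.add_edge("phenotype-gene", rng.choice(diseases), rng.choice(genes))
    for _ in range(15):
        store.add_edge("gene-gene", rng.choice(genes), rng.choice(genes))
    for _ in range(8):
        store.add_edge("drug-gene", rng.choice(drugs), rng.choice(genes))
    for _ in range(6):
        store.add_edge("drug-phenotype", rng.choice(drugs), rng.choice(diseases))
    return store


def oracle_build(store, seeds, tier1, tier2):
    """Two-phase incidence oracle over raw edge lists, plus final closure."""
    nodes = set(seeds)
    for kinds in (tier1, tier2):
        snapshot = set(nodes)
        for k in kinds:
            for s, t, _ in store.edges.get(k, ()):
                if s in snapshot or t in snapshot:
                    nodes.update((s, t))
    edges = set()
    for k in tier1 | tier2:
        for s, t, _ in store.edges.get(k, ()):
            if s in nodes and t in nodes:
                # keep only edges reachable by the phase rule or closure —
                # closure admits all present-endpoint edges, so this is exact
                edges.add((min(s, t), max(s, t), k))
    return nodes, edges


class TestBuildOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_two_phase_breadth_oracle(self, seed):
        rng = random.Random(seed)
        store = random_store(rng)
        seeds = set(rng.sample(sorted(store.nodes["phenotype"]), 2))
        tier1 = frozenset({"phenotype-gene", "drug-phenotype"})
        tier2 = frozenset({"gene-gene", "drug-gene"})
        net = build(store, BuildRequest.make("phenotype", seeds, tier1, tier2))
        exp_nodes, exp_edges = oracle_build(store, seeds, tier1, tier2)
        assert set(net.nodes()) == exp_nodes
        assert {(u, v, k) for u, v, k, _ in net.edges()} == exp_edges

    def test_monotone_in_requested_kinds(self):
        rng = random.Random(3)
        store = random_store(rng)
        seeds = sorted(store.nodes["phenotype"])[:2]
        small = build(store, BuildRequest.make("phenotype", seeds,
                                               tier1=["phenotype-gene"]))
        large = build(store, BuildRequest.make(
            "phenotype", seeds, tier1=["phenotype-gene", "drug-phenotype"],
            tier2=["gene-gene"]))
        assert set(small.nodes()) <= set(large.nodes())
        small_edges = {(u, v, k) for u, v, k, _ in small.edges()}
        large_edges = {(u, v, k) for u, v, k, _ in large.edges()}
        assert small_edges <= large_edges

    def test_deterministic(self):
        store = random_store(random.Random(12))
        req = BuildRequest.make("phenotype", sorted(store.nodes["phenotype"])[:3],
                                tier1=["phenotype-gene"], tier2=["gene-gene"])
        a, b = build(store, req), build(store, req)
        assert sorted(a.edges()) == sorted(b.edges())
        assert sorted(a.nodes()) == sorted(b.nodes())


class TestMinDiseaseDegree:
    def _net(self):
        net = HetNet()
        for d in ("D1", "D2"):
            net.add_node(d, "phenotype")
        for g in ("Gshared", "Gprivate"):
            net.add_node(g, "gene")
        net.add_edge("D1", "Gshared", "phenotype-gene")
        net.add_edge("D2", "Gshared", "phenotype-gene")
        net.add_edge("D1", "Gprivate", "phenotype-gene")
        net.add_edge("Gshared", "Gprivate", "gene-gene")
        return net

    def test_multi_disease_genes_survive(self):
        sub = subnetwork_by_min_disease_degree(self._net(), 2)
        assert set(sub.nodes()) == {"Gshared", "D1", "D2"}

    def test_k1_keeps_all_disease_linked_genes(self):
        sub = subnetwork_by_min_disease_degree(self._net(), 1)
        assert set(sub.nodes()) == {"D1", "D2", "Gshared", "Gprivate"}
        assert sub.has_edge("Gshared", "Gprivate", "gene-gene")

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            subnetwork_by_min_disease_degree(self._net(), 0)

    def test_matches_distinct_disease_count_oracle(self):
        rng = random.Random(31)
        net = HetNet()
        diseases = [f"D{i}" for i in range(8)]
        genes = [f"G{i}" for i in range(20)]
        for d in diseases:
            net.add_node(d, "phenotype")
        for g in genes:
            net.add_node(g, "gene")
        pairs = set()
        for _ in range(45):
            pairs.add((rng.choice(diseases), rng.choice(genes)))
        for d, g in pairs:
            net.add_edge(d, g, "phenotype-gene")
        k = 2
        expected_genes = {
            g for g in genes
            if sum(1 for d, gg in pairs if gg == g) and
            len({d for d, gg in pairs if gg == g}) >= k
        }
        sub = subnetwork_by_min_disease_degree(net, k)
        assert {n for n in sub.nodes("gene")} == expected_genes
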