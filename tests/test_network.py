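"""Median-joining network construction and rho-statistic dating."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fescuecp import median_joining, rho_age, synthetic
from fescuecp.errors import FescueError, InputError
from fescuecp.network import scale_age


def hap_frame(rows, index=None):
    index = index or [f"h{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=index)


class TestMedianJoining:
    def test_single_haplotype_is_one_node_no_edges(self):
        net = median_joining(hap_frame([[0, 1, 0]], index=["only"]))
        assert list(net.graph.nodes) == ["only"]
        assert net.graph.number_of_edges() == 0

    def test_triplet_reconstructs_unsampled_ancestor(self):
        net = median_joining(
            hap_frame([[1, 0, 0], [0, 1, 0], [0, 0, 1]], index=list("abc"))
        )
        assert net.median_nodes == ["mv1"]
        mv = net.graph.nodes["mv1"]
        assert mv["haplotype"] == (0, 0, 0)
        edges = sorted(
            (u, v, d["mutations"]) for u, v, d in net.graph.edges(data=True)
        )
        assert edges == [("a", "mv1", 1), ("b", "mv1", 1), ("c", "mv1", 1)]

    def test_sampled_star_center_needs_no_median_vectors(self):
        star = synthetic.simulate_star_genealogy(8, 4.0, seed=2)
        net = median_joining(star)
        assert net.median_nodes == []
        # network is exactly the star around the ancestor
        assert net.graph.number_of_edges() == len(net.graph.nodes) - 1
        degrees = dict(net.graph.degree())
        assert degrees["ancestor"] == len(net.graph.nodes) - 1

    def test_identical_haplotypes_collapse_with_multiplicity(self):
        net = median_joining(
            hap_frame([[0, 0], [0, 0], [1, 1]], index=["a", "b", "c"])
        )
        node = net.node_of_taxon("b")
        assert net.graph.nodes[node]["multiplicity"] == 2
        assert set(net.graph.nodes[node]["taxa"]) == {"a", "b"}

    @pytest.mark.parametrize("seed", range(10))
    def test_network_is_union_of_all_msts_of_its_nodes(self, seed):
        """At epsilon 0 the network equals the union of every MST over its
        final node set (checked exhaustively via the cycle property: an edge
        belongs to some MST iff its endpoints are disconnected using only
        strictly shorter links). Random <=7-haplotype inputs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        rows = np.unique(rng.integers(0, 2, size=(n, 8)), axis=0)
        m = hap_frame(rows.tolist())
        net = median_joining(m, epsilon=0)
        haps = {x: tuple(net.graph.nodes[x]["haplotype"]) for x in net.graph.nodes}
        expected = _union_of_msts(haps)
        got = {frozenset((u, v)) for u, v in net.graph.edges}
        assert got == expected

    def test_msts_of_observed_input_contained_when_no_medians_added(self):
        """When the construction introduces no median vectors, every MST of
        the observed haplotypes is contained edge-for-edge (enumerated by
        brute force over all spanning trees)."""
        star = synthetic.simulate_star_genealogy(5, 3.0, seed=6)
        net = median_joining(star)
        assert net.median_nodes == []
        haps = {x: tuple(net.graph.nodes[x]["haplotype"]) for x in net.graph.nodes}
        observed = list(haps.values())
        label = {h: x for x, h in haps.items()}
        net_edges = {frozenset((u, v)) for u, v in net.graph.edges}
        for u_hap, v_hap in _all_mst_edges(observed):
            assert frozenset((label[u_hap], label[v_hap])) in net_edges

    def test_weight_scaling_leaves_topology_and_rho_unchanged(self):
        star = synthetic.simulate_star_genealogy(10, 5.0, seed=4)
        net1 = median_joining(star, weight=10.0)
        net2 = median_joining(star, weight=70.0)
        e1 = {frozenset((u, v)) for u, v in net1.graph.edges}
        e2 = {frozenset((u, v)) for u, v in net2.graph.edges}
        assert e1 == e2
        tips = [t for t in star.index if t != "ancestor"]
        r1 = rho_age(net1, "ancestor", tips).rho
        r2 = rho_age(net2, "ancestor", tips).rho
        assert r1 == r2

    def test_constant_characters_are_ignored(self):
        m1 = hap_frame([[0, 1, 1], [0, 0, 1], [0, 1, 0]])
        m2 = hap_frame([[1, 1], [0, 1], [1, 0]])
        n1 = median_joining(m1)
        n2 = median_joining(m2)
        assert nx.is_isomorphic(n1.graph, n2.graph)


def _union_of_msts(haps: dict) -> set[frozenset]:
    """Independent oracle: edge (u, v) lies in some MST of the complete
    Hamming-distance graph iff u and v are not connected by strictly
    shorter links (cycle property)."""
    labels = list(haps)
    d = {
        frozenset((a, b)): sum(x != y for x, y in zip(haps[a], haps[b]))
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    out = set()
    for pair, w in d.items():
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from(tuple(p) for p, wp in d.items() if wp < w)
        u, v = tuple(pair)
        if not nx.has_path(g, u, v):
            out.add(pair)
    return out


def _all_mst_edges(haplotypes):
    """Oracle: enumerate every spanning tree by brute force and collect the
    edges of all minimum-weight ones (Hamming distances)."""
    n = len(haplotypes)
    dist = {
        (i, j): sum(a != b for a, b in zip(haplotypes[i], haplotypes[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    pairs = list(dist)
    best = None
    mst_edges = set()
    for combo in itertools.combinations(pairs, n - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() != n or not nx.is_connected(g):
            continue
        w = sum(dist[e] for e in combo)
        if best is None or w < best:
            best = w
            mst_edges = set()
        if w == best:
            for i, j in combo:
                mst_edges.add((haplotypes[i], haplotypes[j]))
    return mst_edges


class TestRhoAge:
    def test_star_with_forced_counts_matches_closed_form(self):
        d, n = 6, 4
        star = synthetic.simulate_star_genealogy(
            n, 0.0, seed=1, forced_counts=[d] * n
        )
        net = median_joining(star)
        tips = [t for t in star.index if t != "ancestor"]
        est = rho_age(net, "ancestor", tips)
        assert est.rho == d
        assert est.sd_rho == pytest.approx(np.sqrt(d / n))

    def test_rho_zero_iff_descendants_identical_to_ancestor(self):
        star = synthetic.simulate_star_genealogy(
            3, 0.0, seed=1, forced_counts=[0, 0, 2]
        )
        net = median_joining(star)
        est_same = rho_age(net, "ancestor", ["tip1", "tip2"])
        assert est_same.rho == 0
        est_mixed = rho_age(net, "ancestor", ["tip1", "tip2", "tip3"])
        assert est_mixed.rho > 0

    def test_age_scales_linearly_with_mutation_rate(self):
        est1 = scale_age(10.0, 1.0, mutation_rate=20180)
        est2 = scale_age(10.0, 1.0, mutation_rate=40360)
        assert est2.age_years == 2 * est1.age_years
        assert est2.sd_years == 2 * est1.sd_years

    @pytest.mark.parametrize(
        "rho,sd,age_my,sd_my",
        [
            (32.29, 3.04, 0.65, 0.061),
            (47.6, 5.0, 0.96, 0.10),
            (163.71, 11.87, 3.30, 0.24),
            (179.6, 12.52, 3.62, 0.25),
        ],
    )
    def test_published_age_arithmetic(self, rho, sd, age_my, sd_my):
        est = scale_age(rho, sd, mutation_rate=20180)
        assert est.age_my_rounded == pytest.approx(age_my)
        assert est.sd_my_rounded == pytest.approx(sd_my)

    def test_unknown_ancestor_and_empty_descendants_raise(self):
        star = synthetic.simulate_star_genealogy(3, 1.0, seed=5)
        net = median_joining(star)
        with pytest.raises(InputError):
            rho_age(net, "nope", ["tip1"])
        with pytest.raises(InputError):
            rho_age(net, "ancestor", [])

    def test_unreachable_descendant_raises(self):
        g = nx.Graph()
        g.add_node("a", haplotype=(0,), is_median=False, taxa=["a"], multiplicity=1)
        g.add_node("b", haplotype=(1,), is_median=False, taxa=["b"], multiplicity=1)
        from fescuecp.network import HaplotypeNetwork

        net = HaplotypeNetwork(graph=g)
        with pytest.raises(FescueError):
            rho_age(net, "a", ["b"])

    def test_recovery_on_simulated_stars(self):
        lam, hits = 12.0, 0
        for seed in range(25):
            star = synthetic.simulate_star_genealogy(60, lam, seed=seed)
            net = median_joining(star)
            tips = [t for t in star.index if t != "ancestor"]
            est = rho_age(net, "ancestor", tips)
            if abs(est.rho - lam) <= 3 * est.sd_rho:
                hits += 1
        assert hits >= 24
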