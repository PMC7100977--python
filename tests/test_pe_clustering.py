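"""Fragment graph, clique cover and breakpoint-region geometry."""

import itertools

import networkx as nx
import numpy as np
import pytest

from svrecombine.insert_model import build_insert_model
from svrecombine.pe_clustering import (
    build_fragment_graph, compute_breakpoints, distance_penalty, edge_weight,
    greedy_clique_cover, orientation_compatible, PECluster,
)

from conftest import mk_fragment


class TestOrientationCompatibility:
    def test_orientation_mismatch(self):
        a = mk_fragment("a", orient="FR")
        b = mk_fragment("b", orient="RF")
        assert orientation_compatible(a, b) == 0

    def test_fr_long_vs_fr_short(self):
        a = mk_fragment("a", il_class="long")
        b = mk_fragment("b", il_class="short")
        assert orientation_compatible(a, b) == 0

    def test_same_chromosome_set_required(self):
        a = mk_fragment("a", orient="RR", chrom="chr1", chrom_right="chr5")
        b = mk_fragment("b", orient="RR", chrom="chr1", chrom_right="chr5")
        c = mk_fragment("c", orient="RR", chrom="chr1", chrom_right="chr7")
        assert orientation_compatible(a, b) == 1
        assert orientation_compatible(a, c) == 0


class TestDistancePenalty:
    @pytest.mark.parametrize("l,expected", [
        (0, 1.0), (500, 1.0), (601, 0.0), (550, 0.5),
    ])
    def test_piecewise_values(self, l, expected):
        assert distance_penalty(l, 500, 600) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_penalty(-1, 500, 600)

    def test_degenerate_step_function(self):
        assert distance_penalty(500, 500, 500) == 1.0
        assert distance_penalty(501, 500, 500) == 0.0

    def test_non_increasing(self):
        grid = np.linspace(0, 700, 200)
        vals = [distance_penalty(l, 500, 600) for l in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestEdgeWeight:
    def test_theta_zero_kills_weight(self, gaussian_model):
        a = mk_fragment("a", orient="FR")
        b = mk_fragment("b", orient="RF", left_tip=1000)
        assert edge_weight(a, b, gaussian_model).w_ij == 0.0

    def test_identical_fragments(self, gaussian_model):
        a = mk_fragment("a")
        b = mk_fragment("b")
        prof = edge_weight(a, b, gaussian_model)
        assert prof.w_ij == gaussian_model.delta_probability(0)

    def test_symmetry_over_random_pairs(self, gaussian_model):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = mk_fragment("a", left_tip=int(rng.integers(0, 2000)),
                            insert_length=int(rng.integers(600, 1200)),
                            orient=rng.choice(["FR", "RF", "FF", "RR"]))
            b = mk_fragment("b", left_tip=int(rng.integers(0, 2000)),
                            insert_length=int(rng.integers(600, 1200)),
                            orient=rng.choice(["FR", "RF", "FF", "RR"]))
            assert edge_weight(a, b, gaussian_model).w_ij == \
                edge_weight(b, a, gaussian_model).w_ij

    def test_non_increasing_in_distance(self, gaussian_model):
        a = mk_fragment("a", left_tip=0)
        last = None
        for l in range(0, int(gaussian_model.p_mi) + 50, 25):
            b = mk_fragment("b", left_tip=l)
            w = edge_weight(a, b, gaussian_model).w_ij
            if last is not None:
                assert w <= last
            last = w


class TestFragmentGraph:
    def test_two_close_fragments_connect(self, gaussian_model):
        a = mk_fragment("a", left_tip=1000)
        b = mk_fragment("b", left_tip=1010)
        g = build_fragment_graph([a, b], gaussian_model)
        assert g.has_edge("a", "b")

    def test_beyond_pmi_never_connects(self, gaussian_model):
        a = mk_fragment("a", left_tip=1000)
        b = mk_fragment("b", left_tip=1000 + int(gaussian_model.p_mi) + 1)
        g = build_fragment_graph([a, b], gaussian_model)
        assert not g.has_edge("a", "b")
        assert nx.number_connected_components(g) == 2

    def test_matches_all_pairs_brute_force(self, gaussian_model):
        rng = np.random.default_rng(13)
        frags = [mk_fragment(f"f{i:02d}", left_tip=int(rng.integers(0, 3000)),
                             insert_length=int(rng.integers(700, 1100)),
                             right_tip=int(rng.integers(4000, 5000)),
                             orient=rng.choice(["FR", "RF", "FF"]))
                 for i in range(50)]
        g = build_fragment_graph(frags, gaussian_model)
        brute = nx.Graph()
        brute.add_nodes_from(f.fragment_id for f in frags)
        for a, b in itertools.combinations(frags, 2):
            if edge_weight(a, b, gaussian_model).w_ij > 0:
                brute.add_edge(a.fragment_id, b.fragment_id)
        assert set(map(frozenset, nx.connected_components(g))) == \
            set(map(frozenset, nx.connected_components(brute)))
        assert set(map(frozenset, g.edges())) == set(map(frozenset, brute.edges()))


# ---------------------------------------------------------------------------
# Greedy clique cover vs brute-force enumeration
# ---------------------------------------------------------------------------

def brute_force_cover(adj_sets: dict, min_size: int):
    """Exhaustive maximal-clique enumeration + the same greedy rule.

    Cliques found by subset enumeration over bitmasks; the cover repeatedly
    takes the largest clique (ties: smallest left coordinate = node index,
    then lexicographic ids), strikes its members from the rest.
    """
    nodes = sorted(adj_sets)
    idx = {n: i for i, n in enumerate(nodes)}
    bits = {n: sum(1 << idx[m] for m in adj_sets[n]) for n in nodes}
    n = len(nodes)
    cliques = []
    for s in range(1, 1 << n):
        members = [nodes[i] for i in range(n) if s >> i & 1]
        if any((bits[m] | (1 << idx[m])) & s != s for m in members):
            continue
        # maximality: no outside node adjacent to all members
        if any((bits[o] & s) == s for o in nodes if not s >> idx[o] & 1):
            continue
        cliques.append(set(members))
    cover = []
    live = cliques
    while True:
        live = [c for c in live if len(c) >= min_size]
        if not live:
            break
        best = min(live, key=lambda c: (-len(c), min(int(m[1:]) for m in c),
                                        tuple(sorted(c))))
        cover.append(frozenset(best))
        live = [c - best for c in live if c is not best]
    return cover


def random_fragment_graph(seed: int, max_nodes: int = 12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.Graph()
    for i in range(n):
        f = mk_fragment(f"n{i:02d}", left_tip=i)
        g.add_node(f.fragment_id, fragment=f)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(f"n{i:02d}", f"n{j:02d}")
    return g


def check_cover_matches_oracle(seed: int, min_size: int = 2) -> None:
    g = random_fragment_graph(seed)
    got = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        got.extend(frozenset(c.members)
                   for c in greedy_clique_cover(sub, min_size, sigma3=500))
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    expected = []
    for comp in nx.connected_components(g):
        expected.extend(brute_force_cover({n: adj[n] & comp for n in comp}, min_size))
    assert sorted(got, key=sorted) == sorted(map(frozenset, expected), key=sorted), \
        f"cover mismatch at seed {seed}"


class TestGreedyCliqueCover:
    def test_triangle_single_cluster(self):
        g = random_fragment_graph(0)
        g.clear_edges()
        for a, b in [("n00", "n01"), ("n01", "n02"), ("n00", "n02")]:
            if g.has_node(a) and g.has_node(b):
                g.add_edge(a, b)
        sub = g.subgraph(["n00", "n01", "n02"])
        clusters = greedy_clique_cover(sub, min_size=2, sigma3=500)
        assert [set(c.members) for c in clusters] == [{"n00", "n01", "n02"}]

    def test_path_drops_singleton(self):
        g = nx.Graph()
        for i in range(3):
            g.add_node(f"n{i:02d}", fragment=mk_fragment(f"n{i:02d}", left_tip=i))
        g.add_edge("n00", "n01")
        g.add_edge("n01", "n02")
        clusters = greedy_clique_cover(g, min_size=2, sigma3=500)
        # maximal cliques {a,b} and {b,c}; first emitted leaves a singleton
        assert [set(c.members) for c in clusters] == [{"n00", "n01"}]

    def test_emitted_clusters_are_disjoint_cliques(self):
        for seed in range(20):
            g = random_fragment_graph(seed)
            for comp in nx.connected_components(g):
                sub = g.subgraph(comp)
                clusters = greedy_clique_cover(sub, min_size=2, sigma3=500)
                seen = set()
                for c in clusters:
                    assert not (set(c.members) & seen)
                    seen |= set(c.members)
                    for a, b in itertools.combinations(c.members, 2):
                        assert sub.has_edge(a, b)

    @pytest.mark.parametrize("batch", range(5))
    def test_matches_brute_force_enumerator(self, batch):
        for seed in range(batch * 8, batch * 8 + 8):
            check_cover_matches_oracle(seed)


class TestBreakpointRegions:
    def _cluster(self, tips_left, tips_right, signature="FR_long"):
        frags = []
        for i, (tl, tr) in enumerate(zip(tips_left, tips_right)):
            frags.append(mk_fragment(f"m{i}", left_tip=tl, right_tip=tr,
                                     orient=signature.split("_")[0],
                                     il_class="long" if "_long" in signature else "na"))
        return PECluster(signature=signature,
                         members=tuple(f.fragment_id for f in frags),
                         fragments=frags)

    def test_margin_is_sigma3_minus_tip_spread(self):
        c = self._cluster([1000, 1100], [2000, 2060])
        left, right = compute_breakpoints(c, sigma3=500)
        assert left.inner == 1100 and left.hi - left.lo == 400      # 500 - 100
        assert right.inner == 2000 and right.lo == 2000 - 440       # 500 - 60

    def test_single_fragment_margin_equals_sigma3(self):
        c = self._cluster([1000], [2000])
        left, right = compute_breakpoints(c, sigma3=500)
        assert left.hi - left.lo == 500
        assert right.lo == 2000 - 500 and right.hi == 2001

    def test_excess_spread_floors_margin(self):
        c = self._cluster([1000, 1600], [2500, 2520])
        left, _ = compute_breakpoints(c, sigma3=500, margin_floor=10)
        assert left.hi - left.lo == 10           # 500 - 600 < 0 -> floor

    @pytest.mark.parametrize("spread", [0, 50, 250, 499, 500, 700])
    def test_margin_bounds(self, spread):
        c = self._cluster([1000, 1000 + spread], [3000, 3000])
        left, right = compute_breakpoints(c, sigma3=500, margin_floor=10)
        assert 10 <= left.hi - left.lo <= 500
        assert 10 <= right.inner - right.lo <= 500

    def test_region_direction_follows_read_orientation(self):
        fr = self._cluster([1000], [2000], "FR_long")
        l, r = compute_breakpoints(fr, sigma3=500)
        assert (l.lo, l.orient) == (1000, "F") and l.hi > l.inner
        assert (r.hi, r.orient) == (2001, "R") and r.lo < r.inner
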