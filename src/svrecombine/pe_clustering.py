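"""Clustering of discordant fragments into breakpoint-supporting cliques.

Each discordant fragment is a node; two fragments are connected when they
could plausibly support the same variant. The connection score is

    w_ij = theta_ij * P(delta = delta_ij) * T(l_ij)

where theta_ij indicates compatible orientation/chromosomes (and, for FR
pairs, agreement on long-vs-short insert class), P(delta) is the empirical
mass of the observed insert-length difference, and T penalizes the distance
between the two left alignments linearly between sigma3 (no penalty) and
p_mi (full penalty). Connected components are decomposed into maximal
cliques and covered greedily, largest clique first; accepted cliques become
clusters with breakpoint regions derived from member read tips with margin
sigma3 - (x_r - x_l), floored at a configurable minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .insert_model import FragmentAlignment, InsertLengthModel


@dataclass(frozen=True)
class FragmentPairProfile:
    delta_ij: float
    l_ij: float
    theta_ij: int
    w_ij: float


@dataclass
class BreakpointRegion:
    """Interval estimated to contain one true breakpoint.

    ``inner`` is the tip-derived point estimate; the margin extends the
    region in the direction the supporting reads face: forward-side regions
    span [tip, tip+margin), reverse-side regions [tip-margin, tip+1) (the +1
    keeps the tip itself, a legal breakpoint position, inside the half-open
    interval).
    """

    chrom: str
    lo: int
    hi: int
    inner: int
    orient: str = "F"        # orientation of the supporting reads
    precise: bool = False    # True once refined by a split-read junction

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"empty breakpoint region [{self.lo}, {self.hi})")


@dataclass
class PECluster:
    signature: str                       # FR_long, FR_short, RF, FF, RR, UM
    members: tuple[str, ...]             # fragment ids, sorted
    fragments: list[FragmentAlignment] = field(repr=False)
    bp_left: Optional[BreakpointRegion] = None
    bp_right: Optional[BreakpointRegion] = None

    @property
    def size(self) -> int:
        return len(self.members)

    def sort_key(self):
        return (self.bp_left.chrom, self.bp_left.lo, self.bp_left.inner, self.members)


def orientation_compatible(f_i: FragmentAlignment, f_j: FragmentAlignment) -> int:
    """theta_ij: 1 iff the fragments could support the same variant."""
    if f_i.orient != f_j.orient:
        return 0
    if {f_i.chrom_left, f_i.chrom_right} != {f_j.chrom_left, f_j.chrom_right}:
        return 0
    if f_i.orient == "FR" and f_i.il_class != f_j.il_class:
        return 0
    if f_i.orient == "UM" and f_i.left_reverse != f_j.left_reverse:
        return 0
    return 1


def distance_penalty(l: float, sigma3: float, p_mi: float) -> float:
    """T(L): 1 up to sigma3, 0 beyond p_mi, linear ramp between."""
    if l < 0:
        raise ValueError("distance must be >= 0")
    if sigma3 > p_mi:
        raise ValueError("sigma3 must be <= p_mi")
    if l <= sigma3:
        return 1.0
    if l > p_mi:
        return 0.0
    if p_mi == sigma3:
        return 0.0
    return 1.0 - (l - sigma3) / (p_mi - sigma3)


def edge_weight(f_i: FragmentAlignment, f_j: FragmentAlignment,
                model: InsertLengthModel) -> FragmentPairProfile:
    theta = orientation_compatible(f_i, f_j)
    if f_i.insert_length is not None and f_j.insert_length is not None:
        delta = abs(f_i.insert_length - f_j.insert_length)
    else:
        # interchromosomal / one-mate-unmapped pairs carry no insert length;
        # proximity alone decides
        delta = 0.0
    l = abs(f_i.left_tip - f_j.left_tip) if f_i.chrom_left == f_j.chrom_left else model.p_mi + 1
    if theta == 0:
        return FragmentPairProfile(delta, l, 0, 0.0)
    w = model.delta_probability(delta) * distance_penalty(l, model.sigma3, model.p_mi)
    return FragmentPairProfile(delta, l, theta, w)


def build_fragment_graph(fragments: Sequence[FragmentAlignment],
                         model: InsertLengthModel,
                         weight_threshold: float = 0.0) -> nx.Graph:
    """Graph over fragments with edges wherever w_ij exceeds the threshold.

    Candidate pairs are restricted to fragments whose left tips lie within
    p_mi of each other — lossless, since T (and hence w) is zero beyond it.
    """
    frags = sorted(fragments, key=lambda f: (f.chrom_left, f.left_tip, f.fragment_id))
    g = nx.Graph()
    for f in frags:
        g.add_node(f.fragment_id, fragment=f)
    window = model.p_mi
    for i, fi in enumerate(frags):
        for fj in frags[i + 1:]:
            if fj.chrom_left != fi.chrom_left or fj.left_tip - fi.left_tip > window:
                break
            prof = edge_weight(fi, fj, model)
            if prof.w_ij > weight_threshold:
                g.add_edge(fi.fragment_id, fj.fragment_id, weight=prof.w_ij)
    return g


def greedy_clique_cover(component: nx.Graph, min_size: int, sigma3: float,
                        margin_floor: int = 10) -> list[PECluster]:
    """Cover one connected component with disjoint maximal cliques.

    All maximal cliques are enumerated; the largest remaining clique is
    processed into a cluster, its members are struck from every other
    clique, and the loop repeats until only cliques below ``min_size``
    remain. Ties on size break to the smallest leftmost breakpoint
    coordinate, then to lexicographic member ids, keeping the cover
    deterministic.
    """
    cliques = [frozenset(c) for c in nx.find_cliques(component)]
    frag_of = {n: component.nodes[n]["fragment"] for n in component.nodes}

    def key(c: frozenset):
        ids = tuple(sorted(c))
        left = min(frag_of[n].left_tip for n in c)
        return (-len(c), left, ids)

    clusters: list[PECluster] = []
    live = [set(c) for c in cliques]
    while True:
        live = [c for c in live if len(c) >= min_size]
        if not live:
            break
        best = min(live, key=lambda c: key(frozenset(c)))
        members = tuple(sorted(best))
        frags = [frag_of[m] for m in members]
        cluster = PECluster(signature=frags[0].signature, members=members, fragments=frags)
        compute_breakpoints(cluster, sigma3, margin_floor)
        clusters.append(cluster)
        live = [c - best for c in live if c is not best]
    return clusters


def _region(chrom: str, tips: list[int], orient: str, sigma3: float,
            margin_floor: int) -> BreakpointRegion:
    x_l, x_r = min(tips), max(tips)
    margin = sigma3 - (x_r - x_l)
    margin = int(min(max(margin, margin_floor), sigma3))
    if orient == "F":
        inner = x_r
        return BreakpointRegion(chrom, inner, inner + margin, inner, "F")
    inner = x_l
    return BreakpointRegion(chrom, max(inner - margin, 0), inner + 1, inner, "R")


#: per-signature read orientation of (left side, right side)
_SIDE_ORIENT = {
    "FR_long": ("F", "R"), "FR_short": ("F", "R"), "FR": ("F", "R"),
    "RF": ("R", "F"), "FF": ("F", "F"), "RR": ("R", "R"),
}


def compute_breakpoints(cluster: PECluster, sigma3: float,
                        margin_floor: int = 10) -> tuple[BreakpointRegion, Optional[BreakpointRegion]]:
    """Attach breakpoint regions (margin sigma3 - (x_r - x_l), floored)."""
    frags = cluster.fragments
    if not frags:
        raise ValueError("empty cluster")
    if cluster.signature == "UM":
        orient = "R" if frags[0].left_reverse else "F"
        cluster.bp_left = _region(frags[0].chrom_left, [f.left_tip for f in frags],
                                  orient, sigma3, margin_floor)
        cluster.bp_right = None
        return cluster.bp_left, None
    o_left, o_right = _SIDE_ORIENT[cluster.signature]
    cluster.bp_left = _region(frags[0].chrom_left, [f.left_tip for f in frags],
                              o_left, sigma3, margin_floor)
    cluster.bp_right = _region(frags[0].chrom_right, [f.right_tip for f in frags],
                               o_right, sigma3, margin_floor)
    return cluster.bp_left, cluster.bp_right


def cluster_breakpoints(cluster: PECluster, sigma3: float,
                        margin_floor: int = 10):
    """Alias kept for symmetry with the operation vocabulary."""
    return compute_breakpoints(cluster, sigma3, margin_floor)


def cluster_fragments(fragments: Iterable[FragmentAlignment], model: InsertLengthModel,
                      min_size: int, margin_floor: int = 10,
                      weight_threshold: float = 0.0) -> list[PECluster]:
    """Full PE-clustering stage: graph, components, greedy clique cover."""
    g = build_fragment_graph(list(fragments), model, weight_threshold)
    clusters: list[PECluster] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        clusters.extend(greedy_clique_cover(sub, min_size, model.sigma3, margin_floor))
    clusters.sort(key=lambda c: c.sort_key())
    return clusters
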