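"""Recombination of PE clusters into integrated variants.

A single discordant cluster is compatible with several variant
interpretations; the composite signature of *overlapping* clusters pins the
type down. Clusters are processed in coordinate order: each is compared to
the growing variants first, then to the still-unmatched clusters; overlap of
breakpoint regions plus a signature rule decides the pairing:

* FF + RR overlapping on both sides                  -> inversion (INV)
* FF + RR overlapping on exactly one side            -> inverted copy-paste insertion
* FR + RF overlapping on exactly one side            -> copy-paste insertion (INS):
  the shared breakpoint is the paste locus x1, the mate-defined breakpoints
  the source edges x2 < x3
* INS + an FR deletion cluster flanking x2 and x3    -> cut-paste insertion (INS_C)
* two one-mate-unmapped clusters, opposite strands   -> de novo insertion (DN_INS)

Whatever remains unmatched falls back to its single-cluster meaning: a long
FR cluster is a deletion, an RF cluster a tandem duplication, a short FR
cluster a de novo insertion, and a lone FF or RR cluster an untyped breakend.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .pe_clustering import BreakpointRegion, PECluster

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "TD", "INV", "INS", "INS_C", "INS_C_P", "INS_C_I", "DN_INS", "BND",
            "DEL_INS", "TD_I")


def regions_overlap(a: BreakpointRegion, b: BreakpointRegion) -> bool:
    """Strict half-open interval intersection on the same chromosome."""
    return a.chrom == b.chrom and a.lo < b.hi and b.lo < a.hi


@dataclass
class IntegratedVariant:
    sv_type: str
    breakpoints: list[BreakpointRegion]
    member_clusters: list[PECluster] = field(default_factory=list)
    variant_map: set[str] = field(default_factory=set)
    support: str = "PE"                    # PE | SR | mixed
    group_id: Optional[str] = None
    inverted: bool = False
    shared: bool = False                   # flagged by resolve_ambiguous_sharing
    probtype: Optional[str] = None         # probable type once demoted to BND

    def span(self) -> tuple[str, int, int]:
        """Chromosome and inner span between the two defining breakpoints."""
        b1, b2 = self.breakpoints[0], self.breakpoints[1]
        lo, hi = sorted((b1.inner, b2.inner))
        return b1.chrom, lo, hi

    def sort_key(self):
        b = self.breakpoints[0]
        return (b.chrom, b.inner, self.sv_type)


def _merge_regions(a: BreakpointRegion, b: BreakpointRegion) -> BreakpointRegion:
    lo, hi = min(a.lo, b.lo), max(a.hi, b.hi)
    inner = (a.inner + b.inner) // 2
    precise = a.precise or b.precise
    if precise:
        p = a if a.precise else b
        return BreakpointRegion(a.chrom, p.lo, p.hi, p.inner, p.orient, True)
    return BreakpointRegion(a.chrom, lo, hi, inner, a.orient, False)


def _regions(c: PECluster) -> list[BreakpointRegion]:
    return [r for r in (c.bp_left, c.bp_right) if r is not None]


def _overlap_pairs(u: PECluster, c: PECluster):
    pairs = []
    for ru, rc in itertools.product(_regions(u), _regions(c)):
        if regions_overlap(ru, rc):
            pairs.append((ru, rc))
    return pairs


def _pair_score(pairs) -> int:
    return sum(abs(ru.inner - rc.inner) for ru, rc in pairs)


def _other_region(c: PECluster, used: BreakpointRegion) -> BreakpointRegion:
    regs = _regions(c)
    return regs[1] if regs[0] is used else regs[0]


def _three_breakpoints(shared: BreakpointRegion, b_a: BreakpointRegion,
                       b_b: BreakpointRegion) -> list[BreakpointRegion]:
    x2, x3 = sorted((b_a, b_b), key=lambda r: (r.chrom, r.inner))
    return [shared, x2, x3]


def try_pair(u: PECluster, c: PECluster) -> Optional[IntegratedVariant]:
    """Attempt to combine two unmatched clusters into one variant."""
    sigs = {u.signature, c.signature}
    pairs = _overlap_pairs(u, c)
    if not pairs:
        return None

    def new(sv, bps, inverted=False):
        v = IntegratedVariant(sv_type=sv, breakpoints=bps,
                              member_clusters=[u, c], inverted=inverted)
        v.variant_map = set(u.members) | set(c.members)
        return v

    if sigs == {"FF", "RR"}:
        ll = regions_overlap(u.bp_left, c.bp_left)
        rr = regions_overlap(u.bp_right, c.bp_right)
        if ll and rr:
            bpl = _merge_regions(u.bp_left, c.bp_left)
            bpr = _merge_regions(u.bp_right, c.bp_right)
            return new("INV", [bpl, bpr])
        if len(pairs) == 1:
            ru, rc = pairs[0]
            shared = _merge_regions(ru, rc)
            return new("INS", _three_breakpoints(shared, _other_region(u, ru),
                                                 _other_region(c, rc)), inverted=True)
        return None

    if ("RF" in sigs) and sigs & {"FR_long", "FR_short", "FR"}:
        if len(pairs) != 1:
            return None           # both-side overlap (crossover regime): leave unmatched
        ru, rc = pairs[0]
        shared = _merge_regions(ru, rc)
        return new("INS", _three_breakpoints(shared, _other_region(u, ru),
                                             _other_region(c, rc)))

    if sigs == {"UM"} and u.fragments[0].left_reverse != c.fragments[0].left_reverse:
        shared = _merge_regions(pairs[0][0], pairs[0][1])
        b = BreakpointRegion(shared.chrom, shared.lo, shared.hi, shared.inner, "R")
        return new("DN_INS", [shared, b])

    return None


def try_extend(v: IntegratedVariant, c: PECluster) -> Optional[IntegratedVariant]:
    """Attempt to extend an existing variant with one more cluster.

    The only extension pattern among PE signatures is the flanking FR
    deletion cluster that upgrades a copy-paste insertion to a cut-paste
    (its breakpoint regions bracket the source edges x2 and x3).
    """
    if v.sv_type != "INS" or len(v.breakpoints) != 3:
        return None
    if c.signature not in ("FR_long", "FR", "FR_short"):
        return None
    x1, x2, x3 = v.breakpoints
    if regions_overlap(c.bp_left, x2) and regions_overlap(c.bp_right, x3):
        v.sv_type = "INS_C_I" if v.inverted else "INS_C"
        v.breakpoints = [x1, _merge_regions(x2, c.bp_left), _merge_regions(x3, c.bp_right)]
        v.member_clusters.append(c)
        v.variant_map |= set(c.members)
        return v
    return None


def finalize_unmatched(cluster: PECluster) -> Optional[IntegratedVariant]:
    """Single-cluster fallback typing after exhaustive comparison."""
    sig = cluster.signature
    sv = {"FR_long": "DEL", "RF": "TD", "FR_short": "DN_INS",
          "FF": "BND", "RR": "BND", "FR": "DEL"}.get(sig)
    if sv is None:
        log.info("dropping lone %s cluster (%d fragments): no emittable signature",
                 sig, cluster.size)
        return None
    v = IntegratedVariant(sv_type=sv, breakpoints=_regions(cluster),
                          member_clusters=[cluster],
                          variant_map=set(cluster.members))
    if sv == "BND":
        v.probtype = "unknown"
    return v


def merge_compatible_clusters(clusters: Iterable[PECluster]) -> list[PECluster]:
    """Pool same-signature clusters whose breakpoint regions coincide.

    The discrete edge weight can split the fragments of one breakpoint pair
    into several cliques (e.g. when insert-length differences straddle the
    histogram support); such cliques describe the same variant and are
    pooled back into one cluster before signature matching.
    """
    merged: list[PECluster] = []
    for c in sorted(clusters, key=lambda c: c.sort_key()):
        home = None
        for m in merged:
            if m.signature != c.signature:
                continue
            if (m.bp_right is None) != (c.bp_right is None):
                continue
            if m.bp_right is None:
                if (m.fragments[0].left_reverse == c.fragments[0].left_reverse
                        and regions_overlap(m.bp_left, c.bp_left)):
                    home = m
                    break
            elif (regions_overlap(m.bp_left, c.bp_left)
                    and regions_overlap(m.bp_right, c.bp_right)):
                home = m
                break
        if home is None:
            merged.append(c)
        else:
            home.members = tuple(sorted(set(home.members) | set(c.members)))
            home.fragments = home.fragments + c.fragments
            home.bp_left = _merge_regions(home.bp_left, c.bp_left)
            if home.bp_right is not None:
                home.bp_right = _merge_regions(home.bp_right, c.bp_right)
    return merged


def consolidate(clusters: Iterable[PECluster]) -> list[IntegratedVariant]:
    """Coordinate-ordered recombination of clusters into variants.

    Same-signature clusters with coinciding breakpoints are pooled first;
    each cluster is then matched against existing variants, then against
    the unmatched clusters; among several candidates the smallest total
    breakpoint distance wins. A cluster joins at most one variant.
    """
    ordered = merge_compatible_clusters(clusters)
    variants: list[IntegratedVariant] = []
    unmatched: list[PECluster] = []

    for c in ordered:
        best_v, best_score = None, None
        for v in variants:
            trial = _extension_score(v, c)
            if trial is not None and (best_score is None or trial < best_score):
                best_v, best_score = v, trial
        if best_v is not None:
            try_extend(best_v, c)
            continue

        best_u, best_score, best_variant = None, None, None
        for u in unmatched:
            cand = try_pair(u, c)
            if cand is None:
                continue
            score = _pair_score(_overlap_pairs(u, c))
            if best_score is None or score < best_score:
                best_u, best_score, best_variant = u, score, cand
        if best_u is not None:
            unmatched.remove(best_u)
            variants.append(best_variant)
            continue
        unmatched.append(c)

    for u in unmatched:
        v = finalize_unmatched(u)
        if v is not None:
            variants.append(v)
    variants.sort(key=lambda v: v.sort_key())
    return variants


def _extension_score(v: IntegratedVariant, c: PECluster) -> Optional[int]:
    if v.sv_type != "INS" or len(v.breakpoints) != 3:
        return None
    if c.signature not in ("FR_long", "FR", "FR_short"):
        return None
    _, x2, x3 = v.breakpoints
    if c.bp_left is None or c.bp_right is None:
        return None
    if regions_overlap(c.bp_left, x2) and regions_overlap(c.bp_right, x3):
        return abs(c.bp_left.inner - x2.inner) + abs(c.bp_right.inner - x3.inner)
    return None


def resolve_ambiguous_sharing(variants: list[IntegratedVariant]) -> list[IntegratedVariant]:
    """Flag variants whose variant maps share fragments.

    Nothing is deleted here: two variants claiming the same fragments are
    unlikely to both be real, and the disjointness filter is the stage that
    arbitrates. Demotion-vs-drop at the read-depth stage also keys off this
    flag.
    """
    for i, a in enumerate(variants):
        for b in variants[i + 1:]:
            if a.variant_map & b.variant_map:
                a.shared = True
                b.shared = True
    return variants
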