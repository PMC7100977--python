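"""Split-read extraction, variant corroboration and SR-only variants.

A split read is a single read aligned in two segments (one primary plus one
supplementary alignment), pinning a junction at base resolution. Splits are
first offered to existing PE variants — a signature-compatible split whose
junctions fall inside the variant's breakpoint regions upgrades support to
"mixed" and replaces the imprecise regions with the exact junctions. Splits
that match nothing are clustered among themselves by junction proximity:

* same chromosome, same orientation, unswapped   -> deletion/insertion (DEL_INS)
* same chromosome, same orientation, swapped     -> tandem-dup/insertion (TD_I)
* different chromosomes                          -> insertion candidate
* same chromosome, opposite orientation          -> inversion candidate

A TD_I cluster and a DEL_INS cluster sharing one junction jointly define a
3-breakpoint copy-paste insertion. Inversion candidates only become an INV
when clusters from *both* sides of the inverted segment are present.
Residual DEL_INS / TD_I clusters stay ambiguous and are arbitrated by read
depth downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .consolidation import IntegratedVariant
from .io_formats import ReadRec
from .pe_clustering import BreakpointRegion

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSegment:
    chrom: str
    start: int
    end: int
    is_reverse: bool
    read_offset: int          # offset of this segment's first base in read order

    @property
    def junction_at_read_end(self) -> int:
        return self.start if self.is_reverse else self.end

    @property
    def junction_at_read_start(self) -> int:
        return self.end if self.is_reverse else self.start


@dataclass(frozen=True)
class SplitAlignment:
    fragment_id: str
    head: SplitSegment         # segment covering the start of the read
    tail: SplitSegment
    sv_class: str              # DEL_INS_cand | TD_I_cand | INS_cand | INV_cand
    swapped: bool
    junction_head: int         # ref coordinate adjacent to the split, head side
    junction_tail: int

    @property
    def junctions(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Both junction coordinates, sorted by (chrom, position)."""
        a = (self.head.chrom, self.junction_head)
        b = (self.tail.chrom, self.junction_tail)
        return tuple(sorted((a, b)))

    @property
    def side(self) -> str:
        """Which side of the junction the lower-coordinate segment occupies.

        'L' when that segment ends at the junction (lies to its left), 'R'
        when it starts there. Distinguishes the two faces of an inversion.
        """
        (c_lo, j_lo), _ = self.junctions
        for seg, j in ((self.head, self.junction_head), (self.tail, self.junction_tail)):
            if (seg.chrom, j) == (c_lo, j_lo):
                return "L" if j == seg.end else "R"
        return "L"


def _read_start_offset(rec: ReadRec) -> int:
    return rec.clip_right if rec.is_reverse else rec.clip_left


def _segment(rec: ReadRec) -> SplitSegment:
    return SplitSegment(rec.chrom, rec.start, rec.end, rec.is_reverse,
                        _read_start_offset(rec))


def classify_split(head: SplitSegment, tail: SplitSegment) -> tuple[str, bool]:
    """Class and swap flag from the two read-ordered segments."""
    if head.chrom != tail.chrom:
        return "INS_cand", False
    if head.is_reverse != tail.is_reverse:
        return "INV_cand", False
    if head.is_reverse:
        swapped = head.start < tail.start      # read order runs right-to-left
    else:
        swapped = head.start > tail.start
    return ("TD_I_cand", True) if swapped else ("DEL_INS_cand", False)


def make_split(fragment_id: str, head: SplitSegment, tail: SplitSegment) -> SplitAlignment:
    sv_class, swapped = classify_split(head, tail)
    return SplitAlignment(
        fragment_id=fragment_id, head=head, tail=tail,
        sv_class=sv_class, swapped=swapped,
        junction_head=head.junction_at_read_end,
        junction_tail=tail.junction_at_read_start,
    )


def extract_splits(records: Iterable[ReadRec], mq_sr: int = 10) -> list[SplitAlignment]:
    """Build split alignments from primary + supplementary record pairs.

    Reads with more than two aligned segments (chimeras) are dropped, as are
    splits with either segment below the SR mapping-quality gate.
    """
    groups: dict[tuple[str, int], list[ReadRec]] = {}
    for r in records:
        if r.is_secondary or r.chrom is None:
            continue
        groups.setdefault((r.qname, r.read12), []).append(r)

    splits = []
    for (qname, _), recs in sorted(groups.items()):
        primaries = [r for r in recs if not r.is_supplementary]
        supps = [r for r in recs if r.is_supplementary]
        if len(primaries) != 1 or len(supps) != 1:
            if len(recs) > 2:
                log.debug("dropping %s: %d aligned segments", qname, len(recs))
            continue
        p, s = primaries[0], supps[0]
        if p.mapq < mq_sr or s.mapq < mq_sr:
            continue
        seg_p, seg_s = _segment(p), _segment(s)
        head, tail = sorted((seg_p, seg_s), key=lambda seg: seg.read_offset)
        splits.append(make_split(qname, head, tail))
    return splits


# ---------------------------------------------------------------------------
# Support of existing variants
# ---------------------------------------------------------------------------

_COMPAT = {
    "DEL": {"DEL_INS_cand"},
    "DEL_INS": {"DEL_INS_cand"},
    "TD": {"TD_I_cand"},
    "TD_I": {"TD_I_cand"},
    "INV": {"INV_cand"},
}
_THREE_BP = ("INS", "INS_C", "INS_C_P", "INS_C_I")


def _hits(region: BreakpointRegion, chrom: str, j: int, window: int) -> bool:
    if region.chrom != chrom:
        return False
    if region.precise:
        return abs(j - region.inner) <= window
    return region.lo <= j < region.hi


def _refine(region: BreakpointRegion, j: int) -> None:
    region.lo, region.hi, region.inner, region.precise = j, j + 1, j, True


def support_variant(s: SplitAlignment, v: IntegratedVariant,
                    window: int = 10) -> bool:
    """Offer one split to one variant; on a match the variant is updated.

    Both junctions must land in distinct breakpoint regions with a
    signature-compatible class; matched regions become single-base precise
    and the fragment joins the variant map.
    """
    (c1, j1), (c2, j2) = s.junctions
    if v.sv_type in _THREE_BP:
        if s.sv_class == "INV_cand" and not v.inverted:
            return False
        hit1 = [b for b in v.breakpoints if _hits(b, c1, j1, window)]
        hit2 = [b for b in v.breakpoints if _hits(b, c2, j2, window)]
        pick = next(((a, b) for a in hit1 for b in hit2 if a is not b), None)
        if pick is None:
            return False
        r1, r2 = pick
    else:
        if s.sv_class not in _COMPAT.get(v.sv_type, set()):
            return False
        b1, b2 = v.breakpoints[0], v.breakpoints[1]
        if not (_hits(b1, c1, j1, window) and _hits(b2, c2, j2, window)):
            return False
        r1, r2 = b1, b2
    _refine(r1, j1)
    _refine(r2, j2)
    v.variant_map.add(s.fragment_id)
    if v.support == "PE":
        v.support = "mixed"
    return True


# ---------------------------------------------------------------------------
# SR-only clusters and promotion
# ---------------------------------------------------------------------------

@dataclass
class SRCluster:
    sv_class: str
    chrom1: str
    j1: int
    chrom2: str
    j2: int
    side: str
    members: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_splits(splits: list[SplitAlignment], window: int = 10) -> list[SRCluster]:
    """Group leftover splits of one class by junction proximity."""
    clusters: list[SRCluster] = []
    order = sorted(splits, key=lambda s: (s.sv_class, s.side) + s.junctions)
    for s in order:
        (c1, j1), (c2, j2) = s.junctions
        home = None
        for cl in clusters:
            if (cl.sv_class == s.sv_class and cl.side == s.side
                    and cl.chrom1 == c1 and cl.chrom2 == c2
                    and abs(cl.j1 - j1) <= window and abs(cl.j2 - j2) <= window):
                home = cl
                break
        if home is None:
            home = SRCluster(s.sv_class, c1, j1, c2, j2, s.side)
            clusters.append(home)
        home.members.append(s.fragment_id)
    return clusters


def _precise(chrom: str, j: int, orient: str = "F") -> BreakpointRegion:
    return BreakpointRegion(chrom, j, j + 1, j, orient, True)


def _sr_variant(sv_type: str, bps, members, probtype=None) -> IntegratedVariant:
    v = IntegratedVariant(sv_type=sv_type, breakpoints=list(bps),
                          variant_map=set(members), support="SR")
    v.probtype = probtype
    return v


def cluster_and_promote(splits: list[SplitAlignment], window: int = 10,
                        min_size: int = 1) -> list[IntegratedVariant]:
    """Cluster unmatched splits and recombine the clusters into variants.

    TD_I + DEL_INS clusters sharing one junction become a 3-breakpoint
    copy-paste insertion; INV candidates need both faces of the inversion;
    residual DEL_INS and TD_I clusters are kept for read-depth
    disambiguation; residual inversion and interchromosomal insertion
    candidates are emitted as breakends.
    """
    clusters = [c for c in cluster_splits(splits, window) if c.size >= min_size]
    used: set[int] = set()
    variants: list[IntegratedVariant] = []

    # TD_I + DEL_INS -> 3-breakpoint insertion
    td = [c for c in clusters if c.sv_class == "TD_I_cand"]
    di = [c for c in clusters if c.sv_class == "DEL_INS_cand"]
    for a in td:
        if id(a) in used:
            continue
        for b in di:
            if id(b) in used or a.chrom1 != b.chrom1:
                continue
            match = _shared_junction(a, b, window)
            if match is None:
                continue
            x1, x2, x3 = match
            variants.append(_sr_variant(
                "INS", [_precise(a.chrom1, x1), _precise(a.chrom1, x2),
                        _precise(a.chrom1, x3)],
                a.members + b.members))
            used.add(id(a))
            used.add(id(b))
            break

    # paired inversion faces
    inv = [c for c in clusters if c.sv_class == "INV_cand" and id(c) not in used]
    for i, a in enumerate(inv):
        if id(a) in used:
            continue
        for b in inv[i + 1:]:
            if id(b) in used or a.side == b.side or a.chrom1 != b.chrom1:
                continue
            if abs(a.j1 - b.j1) <= window and abs(a.j2 - b.j2) <= window:
                variants.append(_sr_variant(
                    "INV", [_precise(a.chrom1, min(a.j1, b.j1)),
                            _precise(a.chrom2, max(a.j2, b.j2))],
                    a.members + b.members))
                used.add(id(a))
                used.add(id(b))
                break

    # residuals
    for c in clusters:
        if id(c) in used:
            continue
        bps = [_precise(c.chrom1, c.j1), _precise(c.chrom2, c.j2, "R")]
        if c.sv_class == "DEL_INS_cand":
            variants.append(_sr_variant("DEL_INS", bps, c.members))
        elif c.sv_class == "TD_I_cand":
            variants.append(_sr_variant("TD_I", bps, c.members))
        elif c.sv_class == "INV_cand":
            variants.append(_sr_variant("BND", bps, c.members, probtype="INV"))
        else:
            variants.append(_sr_variant("BND", bps, c.members, probtype="INS"))
    return variants


def _shared_junction(a: SRCluster, b: SRCluster, window: int):
    """Shared junction (paste locus) plus the two source edges, x2 < x3."""
    for ja in (a.j1, a.j2):
        for jb in (b.j1, b.j2):
            if abs(ja - jb) <= window:
                rest_a = a.j2 if ja == a.j1 else a.j1
                rest_b = b.j2 if jb == b.j1 else b.j1
                x2, x3 = sorted((rest_a, rest_b))
                return (min(ja, jb), x2, x3)
    return None


def incorporate_splits(splits: list[SplitAlignment],
                       variants: list[IntegratedVariant],
                       window: int = 10) -> list[IntegratedVariant]:
    """Full SR stage: corroborate existing variants, then promote leftovers."""
    leftover = []
    for s in splits:
        for v in variants:
            if support_variant(s, v, window):
                break
        else:
            leftover.append(s)
    return variants + cluster_and_promote(leftover, window)
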