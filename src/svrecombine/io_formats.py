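"""Reading and writing of the standard formats the caller touches.

Alignments come in as coordinate-sorted SAM/BAM (pysam); region files are
3-column BED (0-based half-open). Output is a sites-only VCF 4.2 plus a BEDPE
companion. Internally every coordinate is 0-based half-open; the only 1-based
conversion happens at VCF emission.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, NamedTuple, Optional, TYPE_CHECKING

import pysam
from intervaltree import IntervalTree

if TYPE_CHECKING:  # pragma: no cover
    from .consolidation import IntegratedVariant

log = logging.getLogger(__name__)


class ReadRec(NamedTuple):
    """Lightweight projection of one alignment record.

    Decouples the pipeline from pysam object lifetimes: a whole lane of
    records can be held in memory as small tuples.
    """

    qname: str
    read12: int                # 1 or 2
    chrom: Optional[str]       # None if unmapped
    start: int                 # 0-based reference start
    end: int                   # 0-based exclusive reference end
    is_reverse: bool
    mapq: int
    is_supplementary: bool
    is_secondary: bool
    has_sa: bool               # carries an SA (supplementary alignment) tag
    mate_unmapped: bool
    clip_left: int             # soft+hard clipped bases before the first M
    clip_right: int

    @property
    def tip(self) -> int:
        """Largest coordinate of a forward alignment, smallest of a reverse."""
        return self.start if self.is_reverse else self.end

    @property
    def tail(self) -> int:
        return self.end if self.is_reverse else self.start

    @property
    def aligned_len(self) -> int:
        return self.end - self.start


def _clips(seg: pysam.AlignedSegment) -> tuple[int, int]:
    cig = seg.cigartuples or []
    left = 0
    right = 0
    for op, ln in cig:
        if op in (4, 5):
            left += ln
        else:
            break
    for op, ln in reversed(cig):
        if op in (4, 5):
            right += ln
        else:
            break
    return left, right


def to_readrec(seg: pysam.AlignedSegment) -> ReadRec:
    cl, cr = _clips(seg) if not seg.is_unmapped else (0, 0)
    return ReadRec(
        qname=seg.query_name,
        read12=2 if seg.is_read2 else 1,
        chrom=None if seg.is_unmapped else seg.reference_name,
        start=-1 if seg.is_unmapped else seg.reference_start,
        end=-1 if seg.is_unmapped else seg.reference_end,
        is_reverse=bool(seg.is_reverse),
        mapq=seg.mapping_quality,
        is_supplementary=bool(seg.is_supplementary),
        is_secondary=bool(seg.is_secondary),
        has_sa=seg.has_tag("SA"),
        mate_unmapped=bool(seg.mate_is_unmapped) if seg.is_paired else False,
        clip_left=cl,
        clip_right=cr,
    )


def reference_lengths(path: str) -> dict[str, int]:
    with pysam.AlignmentFile(path, check_sq=False) as af:
        return dict(zip(af.references, af.lengths))


def read_alignments(path: str) -> Iterator[ReadRec]:
    """Stream every paired record (primary and supplementary) of a SAM/BAM."""
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for seg in af.fetch(until_eof=True):
            if not seg.is_paired:
                log.debug("dropping unpaired record %s", seg.query_name)
                continue
            yield to_readrec(seg)


# ---------------------------------------------------------------------------
# BED handling
# ---------------------------------------------------------------------------

class BedError(ValueError):
    pass


def read_bed(path: str) -> dict[str, IntervalTree]:
    """Parse a 3+ column BED into per-chromosome interval trees.

    Malformed lines raise :class:`BedError` carrying the 1-based line number.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedError(f"{path}:{ln}: expected >=3 tab-separated columns")
            chrom = parts[0]
            try:
                lo, hi = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedError(f"{path}:{ln}: non-integer coordinates") from exc
            if lo < 0 or hi <= lo:
                raise BedError(f"{path}:{ln}: invalid interval [{lo}, {hi})")
            trees.setdefault(chrom, IntervalTree()).addi(lo, hi)
    return trees


def exclude_regions(fragments: Iterable, trees: dict[str, IntervalTree]) -> list:
    """Drop discordant fragments overlapping any excluded interval."""
    if not trees:
        return list(fragments)
    kept = []
    for f in fragments:
        t1 = trees.get(f.chrom_left)
        lo1, hi1 = f.left_span()
        hit = t1 is not None and bool(t1.overlap(lo1, hi1))
        if not hit and f.chrom_right is not None:
            t2 = trees.get(f.chrom_right)
            lo2, hi2 = f.right_span()
            hit = t2 is not None and bool(t2.overlap(lo2, hi2))
        if not hit:
            kept.append(f)
    return kept


# ---------------------------------------------------------------------------
# VCF / BEDPE emission
# ---------------------------------------------------------------------------

_ALT_LINES = ("DEL", "DUP", "INV", "INS")
_INFO_LINES = [
    ('SVTYPE', '1', 'String', 'Type of structural variant'),
    ('END', '1', 'Integer', 'End position of the variant'),
    ('SVLEN', '1', 'Integer', 'Signed length of the variant'),
    ('CIPOS', '2', 'Integer', 'Confidence interval around POS'),
    ('CIEND', '2', 'Integer', 'Confidence interval around END'),
    ('GROUPID', '1', 'String', 'Identifier shared by records of one event'),
    ('PROBTYPE', '1', 'String', 'Probable variant type of a BND event'),
    ('SUPPORT', '1', 'String', 'Evidence class: PE, SR or mixed'),
    ('SU', '1', 'Integer', 'Number of supporting fragments'),
]


def _vcf_header(contigs: dict[str, int], meta: Optional[dict] = None) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    for ident, num, typ, desc in _INFO_LINES:
        h.info.add(ident, num, typ, desc)
    for alt in _ALT_LINES:
        h.add_meta('ALT', items=[('ID', alt), ('Description', f'Symbolic {alt}')])
    for key, val in (meta or {}).items():
        h.add_meta(key, value=str(val))
    return h


def _ci(region) -> tuple[int, int]:
    if getattr(region, "precise", False):
        return (0, 0)
    return (region.lo - region.inner, max(region.hi - 1 - region.inner, 0))


def _sym_record(h, vcf, chrom, b1, b2, svtype, group, v, svlen=None):
    # symbolic records anchor on the base before the event (standard VCF
    # convention; htslib recomputes END as POS + |SVLEN|)
    rec = vcf.new_record(
        contig=chrom,
        start=max(b1.inner - 1, 0),
        stop=max(b2.inner, b1.inner + 1),
        alleles=('N', f'<{svtype}>'),
    )
    rec.info['SVTYPE'] = svtype
    if svlen is None:
        svlen = b2.inner - b1.inner
        if svtype == 'DEL':
            svlen = -svlen
    rec.info['SVLEN'] = svlen
    rec.info['CIPOS'] = _ci(b1)
    rec.info['CIEND'] = _ci(b2)
    rec.info['GROUPID'] = group
    rec.info['SUPPORT'] = v.support
    rec.info['SU'] = len(v.variant_map)
    return rec


def _bnd_record(h, vcf, b1, b2, group, v, probtype=None):
    rec = vcf.new_record(
        contig=b1.chrom,
        start=b1.inner,
        alleles=('N', f'N[{b2.chrom}:{b2.inner + 1}['),
    )
    rec.info['SVTYPE'] = 'BND'
    rec.info['CIPOS'] = _ci(b1)
    rec.info['GROUPID'] = group
    rec.info['SUPPORT'] = v.support
    rec.info['SU'] = len(v.variant_map)
    if probtype:
        rec.info['PROBTYPE'] = probtype
    return rec


_SYMBOLIC = {'DEL': 'DEL', 'TD': 'DUP', 'INV': 'INV', 'DN_INS': 'INS'}


def variant_records(v: "IntegratedVariant", vcf, h, group: str) -> list:
    """Expand one integrated variant into its VCF record(s).

    Three-breakpoint insertions follow the grouped emission convention:
    two BND adjacencies (paste point x1 to each source edge) plus one
    DUP (copy-paste) or DEL (cut-paste) over the source span [x2, x3),
    all unified by GROUPID.
    """
    t = v.sv_type
    if t in _SYMBOLIC:
        b1, b2 = v.breakpoints[0], v.breakpoints[1]
        return [_sym_record(h, vcf, b1.chrom, b1, b2, _SYMBOLIC[t], group, v)]
    if t in ('INS', 'INS_C', 'INS_C_P', 'INS_C_I'):
        x1, x2, x3 = v.breakpoints
        span_type = 'DEL' if t in ('INS_C', 'INS_C_P', 'INS_C_I') else 'DUP'
        recs = [
            _bnd_record(h, vcf, x1, x2, group, v, probtype=t),
            _bnd_record(h, vcf, x1, x3, group, v, probtype=t),
            _sym_record(h, vcf, x2.chrom, x2, x3, span_type, group, v),
        ]
        return recs
    if t == 'BND':
        b1, b2 = v.breakpoints[0], v.breakpoints[1]
        return [_bnd_record(h, vcf, b1, b2, group, v, probtype=v.probtype or 'unknown')]
    raise ValueError(f"unknown sv_type {t!r}")


def write_vcf(variants: Iterable["IntegratedVariant"], contigs: dict[str, int],
              path: str, meta: Optional[dict] = None) -> None:
    """Write final calls as VCF 4.2.

    Variants are ordered by their leading breakpoint; all records of one
    multi-record event are emitted consecutively under a shared GROUPID.
    """
    h = _vcf_header(contigs, meta)
    order = sorted(variants, key=lambda v: (v.breakpoints[0].chrom, v.breakpoints[0].inner))
    with pysam.VariantFile(path, 'w', header=h) as vcf:
        for n, v in enumerate(order, start=1):
            group = v.group_id or f"G{n}"
            v.group_id = group
            for rec in variant_records(v, vcf, h, group):
                vcf.write(rec)


def read_vcf_calls(path: str) -> list[dict]:
    """Parse back an emitted VCF into plain dicts (round-trip checks)."""
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            out.append({
                'chrom': rec.chrom,
                'pos': rec.pos,            # 1-based
                'start': rec.start,        # 0-based
                'stop': rec.info.get('END', rec.stop),
                'alt': rec.alts[0] if rec.alts else None,
                'svtype': rec.info.get('SVTYPE'),
                'groupid': rec.info.get('GROUPID'),
                'probtype': rec.info.get('PROBTYPE'),
                'support': rec.info.get('SUPPORT'),
                'cipos': tuple(rec.info.get('CIPOS', ())),
            })
    return out


def write_bedpe(variants: Iterable["IntegratedVariant"], path: str) -> None:
    """10-column BEDPE companion; 3-breakpoint events expand to 3 rows."""
    order = sorted(variants, key=lambda v: (v.breakpoints[0].chrom, v.breakpoints[0].inner))
    with open(path, 'w') as fh:
        for n, v in enumerate(order, start=1):
            group = v.group_id or f"G{n}"
            pairs = [(v.breakpoints[0], v.breakpoints[1], v.sv_type)]
            if len(v.breakpoints) == 3:
                x1, x2, x3 = v.breakpoints
                pairs = [(x1, x2, v.sv_type), (x1, x3, v.sv_type),
                         (x2, x3, 'DEL' if v.sv_type.startswith('INS_C') else 'DUP')]
            for b1, b2, typ in pairs:
                s1 = '+' if b1.orient == 'F' else '-'
                s2 = '+' if b2.orient == 'F' else '-'
                fh.write('\t'.join(map(str, [
                    b1.chrom, b1.lo, b1.hi, b2.chrom, b2.lo, b2.hi,
                    f"{typ}:{group}", len(v.variant_map), s1, s2,
                ])) + '\n')
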