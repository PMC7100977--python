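"""Deterministic synthesis of toy references, implanted SVs and alignments.

No aligner is involved: an altered ("sample") genome is assembled from the
reference as a list of segments, paired-end fragments are drawn uniformly
from it with a Gaussian insert-length distribution, and each read interval
is mapped *back* through the segment list to reference coordinates. The
geometry of every implanted event therefore dictates exactly the discordant
orientations (FR-long across deletions, RF across tandem duplications,
FF/RR flanking inversions, the FR+RF pairs of copy/cut-paste insertions)
and the split-read junctions a real aligner would report.

Mapping qualities are 60 for uniquely placed reads and 0 inside configured
unmappable decoy intervals; no sequencing errors are introduced by default
(the caller under test consumes coordinates, not base identities).

Supported event types: DEL, TD, INV, INS (copy-paste, optionally inverted),
INS_C (cut-paste) and DN_INS (novel insertion).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

_COMP = str.maketrans("ACGTN", "TGCAN")
DEFAULT_SV_SPEC = {
    "DEL": (20, (300, 5000)),
    "TD": (10, (300, 5000)),
    "INV": (5, (300, 5000)),
    "INS": (5, (300, 5000)),
    "INS_C": (3, (300, 5000)),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def make_reference(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def write_fasta(path: str, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Truth events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVEvent:
    sv_type: str
    chrom: str
    x1: int
    x2: int
    x3: int = -1          # -1 for 2-breakpoint events
    size: int = 0
    inverted: bool = False

    @property
    def breakpoints(self) -> tuple[int, ...]:
        pts = [self.x1, self.x2] + ([self.x3] if self.x3 >= 0 else [])
        return tuple(sorted(pts))


@dataclass
class TruthSet:
    events: list[SVEvent]
    params: dict = field(default_factory=dict)

    def write_bedpe(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, e in enumerate(self.events):
                name = f"{e.sv_type}:{i}:x3={e.x3}:size={e.size}:inv={int(e.inverted)}"
                fh.write("\t".join(map(str, [
                    e.chrom, e.x1, e.x1 + 1, e.chrom, e.x2, e.x2 + 1,
                    name, ".", "+", "+",
                ])) + "\n")

    @classmethod
    def read_bedpe(cls, path: str) -> "TruthSet":
        events = []
        with open(path) as fh:
            for line in fh:
                c1, s1, _, c2, s2, _, name, *_ = line.rstrip("\n").split("\t")
                sv_type, _, x3s, sizes, invs = name.split(":")
                events.append(SVEvent(
                    sv_type=sv_type, chrom=c1, x1=int(s1), x2=int(s2),
                    x3=int(x3s.split("=")[1]), size=int(sizes.split("=")[1]),
                    inverted=bool(int(invs.split("=")[1]))))
        return cls(events)


# ---------------------------------------------------------------------------
# Altered-genome construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One contiguous piece of the altered genome.

    Maps alt positions [alt_start, alt_end) onto reference
    [ref_start, ref_end) on the given strand; a '-' strand segment is the
    reverse complement. ``novel`` carries sequence with no reference origin.
    """

    alt_start: int
    alt_end: int
    ref_start: int
    ref_end: int
    strand: str = "+"
    novel: Optional[str] = None


class PlacementError(RuntimeError):
    pass


def _reserve(rng, occupied: list[tuple[int, int]], size: int, genome: int,
             flank: int, tries: int = 2000) -> int:
    for _ in range(tries):
        pos = int(rng.integers(flank, genome - flank - size))
        if all(pos - flank >= hi or pos + size + flank <= lo for lo, hi in occupied):
            occupied.append((pos, pos + size))
            return pos
    raise PlacementError("could not place event; reference too small for the requested spec")


def implant_svs(ref_len: int, sv_spec: Optional[dict] = None, seed: int = 0,
                chrom: str = "chr1", flank: int = 2000) -> TruthSet:
    """Choose non-overlapping event loci for every requested SV.

    ``sv_spec`` maps type -> (count, (min_size, max_size)). Events are kept
    at least ``flank`` bp apart so their discordant clusters stay separable.
    Copy/cut-paste sources and paste points are mutually reserved as well.
    """
    rng = np.random.default_rng(seed)
    spec = sv_spec or DEFAULT_SV_SPEC
    occupied: list[tuple[int, int]] = []
    events: list[SVEvent] = []
    for sv_type in sorted(spec):
        count, (smin, smax) = spec[sv_type]
        for _ in range(count):
            size = int(rng.integers(smin, smax + 1))
            if size > ref_len:
                raise PlacementError("SV larger than reference")
            if sv_type in ("DEL", "TD", "INV"):
                a = _reserve(rng, occupied, size, ref_len, flank)
                events.append(SVEvent(sv_type, chrom, a, a + size, size=size))
            elif sv_type in ("INS", "INS_C"):
                s = _reserve(rng, occupied, size, ref_len, flank)
                p = _reserve(rng, occupied, 1, ref_len, flank)
                events.append(SVEvent(sv_type, chrom, p, s, s + size, size=size))
            elif sv_type == "DN_INS":
                p = _reserve(rng, occupied, 1, ref_len, flank)
                events.append(SVEvent(sv_type, chrom, p, p, size=size))
            else:
                raise ValueError(f"unknown SV type {sv_type!r}")
    events.sort(key=lambda e: min(e.breakpoints))
    return TruthSet(events=events, params={"seed": seed, "ref_len": ref_len})


def build_segments(ref_len: int, truth: TruthSet, seed: int = 0) -> list[Segment]:
    """Assemble the altered genome as a reference-segment list."""
    rng = np.random.default_rng(seed + 1)
    ops = []  # (trigger_pos, kind, payload)
    for e in truth.events:
        if e.sv_type == "DEL":
            ops.append((e.x1, "skip", (e.x1, e.x2)))
        elif e.sv_type == "TD":
            ops.append((e.x1, "dup", (e.x1, e.x2)))
        elif e.sv_type == "INV":
            ops.append((e.x1, "inv", (e.x1, e.x2)))
        elif e.sv_type == "INS":
            ops.append((e.x1, "insert", (e.x2, e.x3, "-" if e.inverted else "+")))
        elif e.sv_type == "INS_C":
            ops.append((e.x1, "insert", (e.x2, e.x3, "+")))
            ops.append((e.x2, "skip", (e.x2, e.x3)))
        elif e.sv_type == "DN_INS":
            novel = "".join(np.array(list("ACGT"))[rng.integers(0, 4, e.size)])
            ops.append((e.x1, "novel", novel))
    ops.sort(key=lambda t: t[0])

    segs: list[Segment] = []
    alt = 0
    cursor = 0

    def emit(rs, re_, strand="+", novel=None):
        nonlocal alt
        length = len(novel) if novel is not None else re_ - rs
        if length <= 0:
            return
        segs.append(Segment(alt, alt + length, rs, re_, strand, novel))
        alt += length

    for pos, kind, payload in ops:
        emit(cursor, pos)
        if kind == "skip":
            cursor = payload[1]
        elif kind == "dup":
            a, b = payload
            emit(a, b)
            emit(a, b)
            cursor = b
        elif kind == "inv":
            a, b = payload
            emit(a, b, "-")
            cursor = b
        elif kind == "insert":
            s, e_, strand = payload
            emit(s, e_, strand)
            cursor = pos
        elif kind == "novel":
            emit(-1, -1, "+", payload)
            cursor = pos
    emit(cursor, ref_len)
    return segs


def altered_sequence(reference: str, segments: Sequence[Segment]) -> str:
    parts = []
    for s in segments:
        if s.novel is not None:
            parts.append(s.novel)
        elif s.strand == "+":
            parts.append(reference[s.ref_start:s.ref_end])
        else:
            parts.append(revcomp(reference[s.ref_start:s.ref_end]))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Alignment synthesis
# ---------------------------------------------------------------------------

@dataclass
class _Piece:
    ref_start: int
    ref_end: int
    reverse: bool
    roff_start: int   # read-order offsets of this piece
    roff_end: int


def _map_read(u: int, v: int, read2: bool, segs, alt_starts) -> Optional[list[_Piece]]:
    """Map alt interval [u, v) (one read) to reference pieces in read order."""
    i = int(np.searchsorted(alt_starts, u, side="right")) - 1
    pieces = []
    while i < len(segs) and segs[i].alt_start < v:
        s = segs[i]
        a, b = max(u, s.alt_start), min(v, s.alt_end)
        if s.novel is not None:
            pieces.append(None)
        else:
            if s.strand == "+":
                rs = s.ref_start + (a - s.alt_start)
                re_ = s.ref_start + (b - s.alt_start)
                rev = read2
            else:
                rs = s.ref_end - (b - s.alt_start)
                re_ = s.ref_end - (a - s.alt_start)
                rev = not read2
            if read2:
                roff = (v - b, v - a)
            else:
                roff = (a - u, b - u)
            pieces.append(_Piece(rs, re_, rev, roff[0], roff[1]))
        i += 1
    mapped = [p for p in pieces if p is not None]
    mapped.sort(key=lambda p: p.roff_start)
    # coalesce pieces that are contiguous in both read and reference:
    # a real aligner reports those as one alignment, not a split
    out: list[_Piece] = []
    for p in mapped:
        if out:
            q = out[-1]
            if q.roff_end == p.roff_start and q.reverse == p.reverse:
                if not p.reverse and q.ref_end == p.ref_start:
                    q.ref_end = p.ref_end
                    q.roff_end = p.roff_end
                    continue
                if p.reverse and p.ref_end == q.ref_start:
                    q.ref_start = p.ref_start
                    q.roff_end = p.roff_end
                    continue
        out.append(p)
    return out


def _cigar(p: _Piece, read_len: int) -> str:
    m = p.ref_end - p.ref_start
    pre, post = p.roff_start, read_len - p.roff_end
    if p.reverse:
        pre, post = post, pre
    out = []
    if pre:
        out.append(f"{pre}S")
    out.append(f"{m}M")
    if post:
        out.append(f"{post}S")
    return "".join(out)


def _overlaps_any(lo, hi, intervals) -> bool:
    return any(lo < b and a < hi for a, b in intervals)


def synthesize_alignments(reference: str, truth: TruthSet, out_sam: str,
                          coverage: float = 30.0, read_len: int = 100,
                          il_mean: float = 350.0, il_sd: float = 50.0,
                          seed: int = 0, chrom: str = "chr1",
                          unmappable: Optional[list[tuple[int, int]]] = None,
                          min_clip: int = 15) -> str:
    """Draw fragments from the altered genome and emit a sorted SAM.

    Reads crossing a segment junction with at least ``min_clip`` aligned
    bases on each side become split reads (primary + supplementary with SA
    tags); smaller overhangs are soft-clipped away, as an aligner would.
    Reads overlapping a configured unmappable decoy get MAPQ 0.
    """
    if coverage < 2:
        raise ValueError("coverage must be >= 2")
    ref_len = len(reference)
    segs = build_segments(ref_len, truth, seed=truth.params.get("seed", 0))
    alt = altered_sequence(reference, segs)
    alt_len = len(alt)
    alt_starts = np.array([s.alt_start for s in segs])
    decoys = unmappable or []

    rng = np.random.default_rng(seed)
    n_frag = int(round(coverage * alt_len / (2 * read_len)))
    fls = np.maximum(np.rint(rng.normal(il_mean, il_sd, n_frag)).astype(np.int64),
                     read_len + 1)
    fls = np.minimum(fls, alt_len - 1)
    fss = rng.integers(0, alt_len - fls)   # vectorized per-fragment start

    rows = []  # (chrom, pos, qname, flag, mapq, cigar, rnext, pnext, tlen, seq, sa)

    def mapq_for(rs, re_):
        return 0 if _overlaps_any(rs, re_, decoys) else 60

    for idx in range(n_frag):
        fs, fl = int(fss[idx]), int(fls[idx])
        qname = f"f{idx:07d}"
        reads = []  # per mate: list of pieces (may be empty = unmapped)
        seqs = []
        for read2 in (False, True):
            if read2:
                u, v = fs + fl - read_len, fs + fl
                seq = revcomp(alt[u:v])
            else:
                u, v = fs, fs + read_len
                seq = alt[u:v]
            pieces = _map_read(u, v, read2, segs, alt_starts)
            pieces = [p for p in pieces if p.ref_end - p.ref_start >= min_clip]
            reads.append(pieces)
            seqs.append(seq)
        if len(reads[0]) > 2 or len(reads[1]) > 2:
            continue  # >2-segment chimera: not modelled
        if not reads[0] and not reads[1]:
            continue

        prim_by_mate = []
        for r in (reads[0], reads[1]):
            prim_by_mate.append(None if not r else
                                max(r, key=lambda p: (p.ref_end - p.ref_start, -p.roff_start)))

        p1, p2 = prim_by_mate
        same_chrom = p1 is not None and p2 is not None
        tlen = 0
        if same_chrom:
            lo = min(p1.ref_start, p2.ref_start)
            hi = max(p1.ref_end, p2.ref_end)
            tlen = hi - lo
        proper = (same_chrom and p1 is not None and p2 is not None
                  and abs(tlen - il_mean) <= 4 * il_sd)

        for mate, (pieces, seq) in enumerate(zip(reads, seqs)):
            mp = prim_by_mate[1 - mate]
            base_flag = 1 | (64 if mate == 0 else 128)
            if proper:
                base_flag |= 2
            if mp is None:
                base_flag |= 8
            elif mp.reverse:
                base_flag |= 32
            if not pieces:
                # unmapped read placed at its mate's coordinates
                if mp is None:
                    continue
                rows.append((chrom, mp.ref_start, qname, base_flag | 4, 0, "*",
                             "=", mp.ref_start, 0, seq, None))
                continue
            my_prim = prim_by_mate[mate]
            sa_parts = {}
            if len(pieces) == 2:
                for p in pieces:
                    strand = "-" if p.reverse else "+"
                    sa_parts[id(p)] = (f"{chrom},{p.ref_start + 1},{strand},"
                                       f"{_cigar(p, read_len)},{mapq_for(p.ref_start, p.ref_end)},0")
            for p in pieces:
                flag = base_flag
                if p.reverse:
                    flag |= 16
                if p is not my_prim:
                    flag |= 2048
                mq = mapq_for(p.ref_start, p.ref_end)
                rseq = revcomp(seq) if p.reverse else seq
                if mp is not None:
                    rnext, pnext = "=", mp.ref_start
                    t = 0
                    if p is my_prim and same_chrom:
                        t = tlen if p.ref_start <= mp.ref_start else -tlen
                else:
                    rnext, pnext, t = "=", p.ref_start, 0
                sa = None
                if len(pieces) == 2:
                    other = pieces[0] if p is pieces[1] else pieces[1]
                    sa = sa_parts[id(other)] + ";"
                rows.append((chrom, p.ref_start, qname, flag, mq,
                             _cigar(p, read_len), rnext, pnext, t, rseq, sa))

    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": ref_len}]}
    with pysam.AlignmentFile(out_sam, "w", header=header) as af:
        for (c, pos, qname, flag, mq, cigar, rnext, pnext, tlen, seq, sa) in rows:
            a = pysam.AlignedSegment(af.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = af.get_tid(c)
            a.reference_start = pos
            a.mapping_quality = mq
            if cigar != "*":
                a.cigarstring = cigar
            a.next_reference_id = af.get_tid(c)
            a.next_reference_start = pnext
            a.template_length = tlen
            a.query_sequence = seq
            if sa is not None:
                a.set_tag("SA", sa)
            af.write(a)
    return out_sam


def simulate_dataset(out_dir: str, ref_len: int = 2_000_000,
                     sv_spec: Optional[dict] = None, coverage: float = 30.0,
                     read_len: int = 100, il_mean: float = 350.0,
                     il_sd: float = 50.0, seed: int = 0,
                     chrom: str = "chr1",
                     unmappable: Optional[list[tuple[int, int]]] = None) -> dict:
    """One-call fixture: reference FASTA, sorted SAM, truth BEDPE, mappability BED."""
    os.makedirs(out_dir, exist_ok=True)
    reference = make_reference(ref_len, seed)
    truth = implant_svs(ref_len, sv_spec, seed=seed, chrom=chrom)
    truth.params.update({"coverage": coverage, "read_len": read_len,
                         "il_mean": il_mean, "il_sd": il_sd})
    paths = {
        "fasta": os.path.join(out_dir, "reference.fa"),
        "sam": os.path.join(out_dir, "alignments.sam"),
        "truth": os.path.join(out_dir, "truth.bedpe"),
        "mappable": os.path.join(out_dir, "mappable.bed"),
    }
    write_fasta(paths["fasta"], {chrom: reference})
    synthesize_alignments(reference, truth, paths["sam"], coverage=coverage,
                          read_len=read_len, il_mean=il_mean, il_sd=il_sd,
                          seed=seed + 17, chrom=chrom, unmappable=unmappable)
    truth.write_bedpe(paths["truth"])
    with open(paths["mappable"], "w") as fh:
        cursor = 0
        for lo, hi in sorted(unmappable or []):
            if lo > cursor:
                fh.write(f"{chrom}\t{cursor}\t{lo}\n")
            cursor = max(cursor, hi)
        if cursor < ref_len:
            fh.write(f"{chrom}\t{cursor}\t{ref_len}\n")
    return {"paths": paths, "truth": truth}
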