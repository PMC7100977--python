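"""Empirical insert-length model, alignment classification, coverage.

The caller's probabilistic machinery is anchored in the empirical insert
length distribution (ILD) of the sequencing library, summarised by:

* ``mean_il`` — mean fragment (insert) length;
* ``sigma3``  — the "generalized 3 sigma": the insert length at the 99.85th
  percentile of the ILD (equals mean + 3 sd for a Gaussian library);
* ``p_mi``    — the insert length at the 99.9999th percentile, beyond which
  two discordant fragments are never considered mutually supporting;
* a binned histogram of absolute pairwise insert-length *differences*, the
  empirical mass function behind the clustering edge weight.

Percentiles use the nearest-rank convention on the sorted sample (no
interpolation), so on samples below 10^6 values ``p_mi`` equals the maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import ReadRec

log = logging.getLogger(__name__)

#: orientation labels: derived leftmost-aligned mate first; UM = one mate unmapped
ORIENTATIONS = ("FR", "RF", "FF", "RR", "UM")


class ModelError(ValueError):
    """Raised when the insert-length model cannot be constructed."""


def nearest_rank(sorted_values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile of an ascending-sorted sample."""
    n = len(sorted_values)
    if n == 0:
        raise ModelError("empty sample")
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(sorted_values[min(rank, n) - 1])


@dataclass(frozen=True)
class InsertLengthModel:
    mean_il: float
    sigma3: float
    p_mi: float
    bin_width: int
    bin_mass: np.ndarray = field(repr=False)   # normalized delta-difference histogram
    n_sampled: int = 0

    def delta_probability(self, delta: float) -> float:
        """Mass of the histogram bin containing ``delta``.

        Zero when ``delta`` exceeds the largest observed pairwise difference.
        """
        if delta < 0:
            raise ValueError("delta must be >= 0")
        idx = int(delta // self.bin_width)
        if idx >= len(self.bin_mass):
            return 0.0
        return float(self.bin_mass[idx])


def build_insert_model(insert_lengths: Sequence[float], bin_width: int = 5,
                       seed: int = 0, n_delta_pairs: int = 1_000_000) -> InsertLengthModel:
    """Build the ILD model from (subsampled) concordant insert lengths.

    The difference histogram is built from absolute differences of a bounded,
    seeded random pairing of the sample (an all-pairs construction would be
    quadratic); when the sample is small enough, all distinct pairs are used.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    x = np.asarray(insert_lengths, dtype=np.float64)
    if x.size < 2:
        raise ModelError("need at least 2 insert lengths")
    if np.any(x <= 0):
        raise ValueError("insert lengths must be positive")

    xs = np.sort(x)
    sigma3 = nearest_rank(xs, 99.85)
    p_mi = nearest_rank(xs, 99.9999)

    n = x.size
    if n * (n - 1) // 2 <= n_delta_pairs:
        deltas = np.abs(x[:, None] - x[None, :])[np.triu_indices(n, k=1)]
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, n_delta_pairs)
        j = rng.integers(0, n - 1, n_delta_pairs)
        j = np.where(j >= i, j + 1, j)     # j != i, uniform over the rest
        deltas = np.abs(x[i] - x[j])

    nbins = int(deltas.max() // bin_width) + 1
    counts, _ = np.histogram(deltas, bins=nbins, range=(0, nbins * bin_width))
    mass = counts / counts.sum()
    return InsertLengthModel(
        mean_il=float(x.mean()), sigma3=sigma3, p_mi=p_mi,
        bin_width=bin_width, bin_mass=mass, n_sampled=int(n),
    )


def delta_probability(model: InsertLengthModel, delta: float) -> float:
    return model.delta_probability(delta)


# ---------------------------------------------------------------------------
# Fragment-level view of one discordant pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentAlignment:
    """One discordant fragment: both mates' alignments, leftmost mate first.

    ``tip`` is the largest coordinate of a forward alignment and the smallest
    of a reverse one; ``tail`` is the opposite end. ``il_class`` records
    whether the observed insert length is significantly longer or shorter
    than the library mean ('long' / 'short' / 'na').
    """

    fragment_id: str
    chrom_left: str
    chrom_right: Optional[str]      # None when the right mate is unmapped
    left_tail: int
    left_tip: int
    right_tail: int
    right_tip: int
    left_reverse: bool
    right_reverse: bool
    orient: str                     # one of ORIENTATIONS
    insert_length: Optional[int]    # defined for same-chromosome pairs only
    mapq_left: int
    mapq_right: int
    il_class: str = "na"            # 'long' | 'short' | 'na'

    def left_span(self) -> tuple[int, int]:
        lo, hi = sorted((self.left_tail, self.left_tip))
        return lo, hi

    def right_span(self) -> tuple[int, int]:
        lo, hi = sorted((self.right_tail, self.right_tip))
        return lo, hi

    @property
    def signature(self) -> str:
        if self.orient == "FR":
            return f"FR_{self.il_class}" if self.il_class in ("long", "short") else "FR"
        return self.orient


def _strand(rec: ReadRec) -> str:
    return "R" if rec.is_reverse else "F"


def _make_fragment(left: ReadRec, right: Optional[ReadRec], orient: str,
                   il_class: str = "na") -> FragmentAlignment:
    if right is None:
        return FragmentAlignment(
            fragment_id=left.qname, chrom_left=left.chrom, chrom_right=None,
            left_tail=left.tail, left_tip=left.tip, right_tail=-1, right_tip=-1,
            left_reverse=left.is_reverse, right_reverse=False,
            orient="UM", insert_length=None,
            mapq_left=left.mapq, mapq_right=0, il_class="na",
        )
    same = left.chrom == right.chrom
    il = max(left.end, right.end) - min(left.start, right.start) if same else None
    return FragmentAlignment(
        fragment_id=left.qname, chrom_left=left.chrom, chrom_right=right.chrom,
        left_tail=left.tail, left_tip=left.tip,
        right_tail=right.tail, right_tip=right.tip,
        left_reverse=left.is_reverse, right_reverse=right.is_reverse,
        orient=orient, insert_length=il,
        mapq_left=left.mapq, mapq_right=right.mapq, il_class=il_class,
    )


def classify_alignment(pair: tuple[Optional[ReadRec], Optional[ReadRec]],
                       model: InsertLengthModel, mq_pe: int = 1, mq_sr: int = 10,
                       mq_rf: int = 20, short_floor: int = 200):
    """Assign one fragment to exactly one evidence class.

    Returns ``(label, payload)`` where label is one of ``'concordant'``,
    ``'discordant'`` (payload: :class:`FragmentAlignment`), ``'split-candidate'``
    or ``'dropped'`` (payload: reason string).

    FR pairs whose insert length lies inside the concordant window
    ``[short_floor, sigma3]`` are concordant. Orientation anomalies (RF, FF,
    RR), interchromosomal pairs, one-mate-unmapped pairs and FR pairs with
    significantly long (> sigma3) or short (< short_floor) inserts are
    discordant. RF pairs must reach ``mq_rf`` on both sides; any record
    carrying a supplementary-alignment annotation routes the fragment to the
    split-read stage instead (gated there at ``mq_sr``).
    """
    r1, r2 = pair
    recs = [r for r in (r1, r2) if r is not None]
    if not recs:
        return "dropped", "no primary records"
    if any(r.is_secondary or r.is_supplementary for r in recs):
        return "dropped", "secondary/supplementary record in primary slot"

    if any(r.has_sa for r in recs):
        return "split-candidate", None

    mapped = [r for r in recs if r.chrom is not None]
    if len(mapped) == 0:
        return "dropped", "both mates unmapped"
    if len(mapped) == 1:
        rec = mapped[0]
        if rec.mapq < mq_pe:
            return "dropped", f"one-mate-unmapped below mapq {mq_pe}"
        return "discordant", _make_fragment(rec, None, "UM")
    if len(recs) == 1:
        return "dropped", "missing mate record"

    left, right = sorted(mapped, key=lambda r: (r.chrom, r.start))
    orient = _strand(left) + _strand(right)
    min_mq = min(left.mapq, right.mapq)

    if left.chrom == right.chrom and orient == "FR":
        il = max(left.end, right.end) - min(left.start, right.start)
        if short_floor <= il <= model.sigma3:
            return "concordant", None
        il_class = "long" if il > model.sigma3 else "short"
        if min_mq < mq_pe:
            return "dropped", f"discordant FR below mapq {mq_pe}"
        return "discordant", _make_fragment(left, right, "FR", il_class)

    if orient == "RF" and left.chrom == right.chrom:
        if min_mq < mq_rf:
            return "dropped", f"RF pair below mapq {mq_rf} on one side"
        return "discordant", _make_fragment(left, right, "RF")

    if min_mq < mq_pe:
        return "dropped", f"discordant pair below mapq {mq_pe}"
    return "discordant", _make_fragment(left, right, orient)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class MappabilityMask:
    """Per-chromosome boolean arrays; True = mappable position."""

    masks: dict[str, np.ndarray]

    @classmethod
    def from_bed(cls, trees, chrom_lengths: dict[str, int]) -> "MappabilityMask":
        masks = {}
        for chrom, length in chrom_lengths.items():
            m = np.zeros(length, dtype=bool)
            if chrom in trees:
                for iv in trees[chrom]:
                    m[iv.begin:min(iv.end, length)] = True
            masks[chrom] = m
        return cls(masks)

    def get(self, chrom: str, length: int) -> Optional[np.ndarray]:
        return self.masks.get(chrom)


@dataclass
class CoverageTrack:
    """Per-base read depth per chromosome, MQ0 alignments excluded."""

    depth: dict[str, np.ndarray]
    chrom_median: dict[str, float]

    @property
    def global_median(self) -> float:
        vals = [m for m in self.chrom_median.values() if m > 0]
        return float(np.median(vals)) if vals else 0.0


def build_coverage(records: Iterable[ReadRec], chrom_lengths: dict[str, int],
                   mappability: Optional[MappabilityMask] = None) -> CoverageTrack:
    """Pile up primary, MQ>0 alignments into a per-base depth track.

    Chromosome medians are computed over mappable positions only when a mask
    is supplied; a chromosome absent from the mask falls back to all
    positions with a logged warning.
    """
    depth = {c: np.zeros(n, dtype=np.uint32) for c, n in chrom_lengths.items()}
    for r in records:
        if (r.chrom is None or r.is_secondary or r.is_supplementary or r.mapq == 0):
            continue
        arr = depth.get(r.chrom)
        if arr is None:
            continue
        arr[r.start:r.end] += 1

    medians = {}
    for chrom, arr in depth.items():
        mask = mappability.get(chrom, len(arr)) if mappability is not None else None
        if mappability is not None and mask is None:
            log.warning("chromosome %s missing from mappability mask; using all positions", chrom)
        vals = arr if mask is None else arr[mask]
        medians[chrom] = float(np.median(vals)) if vals.size else 0.0
    return CoverageTrack(depth=depth, chrom_median=medians)


def pooled_median_coverage(track: CoverageTrack,
                           mappability: Optional[MappabilityMask] = None) -> float:
    """Median depth pooled over (mappable) positions of all chromosomes."""
    parts = []
    for chrom, arr in track.depth.items():
        mask = mappability.get(chrom, len(arr)) if mappability is not None else None
        parts.append(arr if mask is None else arr[mask])
    if not parts:
        return 0.0
    pooled = np.concatenate(parts)
    return float(np.median(pooled)) if pooled.size else 0.0


def trimmed_concordant_sample(insert_lengths: Sequence[float], lo_factor: float = 0.5,
                              hi_factor: float = 2.0, cap: int = 1_000_000) -> np.ndarray:
    """Robust-trim a raw FR insert-length collection before model building.

    Concordance cannot be decided before the model exists, so the raw FR
    collection inevitably contains a small admixture of variant-spanning
    pairs; values outside [lo_factor, hi_factor] x median are discarded and
    the first ``cap`` survivors kept.
    """
    x = np.asarray(insert_lengths, dtype=np.float64)
    if x.size == 0:
        return x
    med = np.median(x)
    kept = x[(x >= lo_factor * med) & (x <= hi_factor * med)]
    return kept[:cap]
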