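# Methods

## Overview

svrecombine calls structural variants from a coordinate-sorted SAM/BAM of
paired-end alignments belonging to a single read group, in a fixed stage
order: preprocessing (insert-length model, coverage track), PE clustering,
cluster consolidation, split-read incorporation, dynamic-threshold +
disjointness filtering, read-depth arbitration, and VCF/BEDPE emission.
All internal coordinates are 0-based half-open; conversion to 1-based
happens only at VCF emission. Every stage is deterministic given the input
and the seed; the only seeded randomness is the pairing used to build the
insert-length difference histogram (and, in the simulator, fragment
placement).

## Insert-length model

The model is summarised by the library mean, σ₃ (the insert length at the
99.85th percentile — the "generalized 3 sigma", equal to mean + 3 sd for a
Gaussian library), p_mi (the 99.9999th percentile), and a binned histogram
of absolute pairwise insert-length differences. Percentiles are
nearest-rank on the sorted sample, with no interpolation; on samples below
10⁶ values p_mi therefore equals the sample maximum. The difference
histogram uses 10⁶ seeded random pairs (all distinct pairs when the sample
is small enough) and a default bin width of 5 bp; the bin masses form a
proper probability mass function, and a difference beyond the largest
observed one has mass zero.

Concordance cannot be decided before the model exists, so the raw
collection of FR pair insert lengths unavoidably contains a small
admixture of variant-spanning pairs. Values outside [0.5, 2.0] × median
are trimmed before the model is built, and up to 10⁶ survivors are kept.
The trim window is wide enough to retain the genuine 99.9999th-percentile
tail of a typical short-insert library (≈ 4.75 sd above the mean) while
removing deletion-elongated inserts; the admixture that remains below the
cap is far smaller than the 0.15 % tail that defines σ₃. The
`build_insert_model` function itself performs no trimming — it
characterises exactly the sample it is given.

## Classification

An FR same-chromosome pair is concordant when its insert lies in
[short_floor, σ₃], with short_floor defaulting to 2 × read length.
Orientation anomalies (RF/FF/RR), interchromosomal pairs,
one-mate-unmapped pairs, and FR pairs outside the window are discordant.
Mapping-quality gates: ≥ 1 for ordinary discordant pairs, ≥ 20 on *both*
sides of an RF pair (RF evidence is the most repeat-prone), ≥ 10 for both
segments of a split read. A pair in which either mate carries a
supplementary-alignment (SA) annotation is routed exclusively to the
split-read stage, so classification partitions fragments: exactly one
label each.

"Tip" is the largest coordinate of a forward alignment and the smallest of
a reverse one; "tail" the opposite. Orientation is read off the
leftmost-aligned mate first (chromosomes ordered lexicographically for
interchromosomal pairs).

## PE clustering

Edges exist where `W_ij = θ_ij · P(Δ=Δ_ij) · T(L_ij) > 0` (the threshold
is configurable but defaults to exactly 0). Candidate pairs are restricted
to fragments whose left tips are within p_mi — lossless, since T vanishes
beyond p_mi. Interchromosomal and one-mate-unmapped pairs carry no insert
length; their Δ is taken as 0 so proximity alone decides. Maximal cliques
are enumerated per connected component (NetworkX `find_cliques`) and
covered greedily: largest clique first, ties broken by smallest leftmost
tip and then lexicographic fragment ids, members struck from all remaining
cliques, cliques below the minimum size discarded. The minimum clique size
defaults to the dynamic support threshold evaluated at the dataset's
coverage.

Breakpoint regions are one-sided: a forward-supported breakpoint lies in
[tip, tip + margin), a reverse-supported one in [tip − margin, tip + 1),
with margin = σ₃ − (X_R − X_L) clamped to [10 bp, σ₃]. The +1 on the
reverse side keeps the tip itself — a legal breakpoint position — inside
the half-open interval, which matters when two clusters meet at an exact
junction. The 10 bp floor exists because the margin expression can go
non-positive for widely spread clusters and a non-positive search window
is unusable.

## Consolidation

Clusters are processed in coordinate order; each is first offered to the
growing variants, then to the still-unmatched clusters; among several
geometric matches the smallest total breakpoint distance wins, and a
cluster joins at most one variant. Before matching, same-signature
clusters whose breakpoint regions coincide on both sides are pooled into
one cluster: the discrete edge weight can split one breakpoint's fragments
into several cliques (insert-length differences straddling the histogram
support), and those cliques describe the same variant. Without the pooling
step the surplus clique would surface as a duplicate or spurious BND call.

Signature rules: FF+RR overlapping on both sides → INV; FF+RR overlapping
on exactly one side → inverted copy-paste insertion; FR+RF overlapping on
exactly one side → copy-paste INS, with the shared region the paste locus
x₁ and the mate-defined regions the source edges x₂ < x₃; an FR deletion
cluster flanking x₂ and x₃ upgrades INS to cut-paste INS_C; two
one-mate-unmapped clusters of opposite strand → DN_INS. Unmatched clusters
finalize as DEL (long FR), TD (RF), DN_INS (short FR) or BND (lone FF/RR);
a lone one-mate-unmapped cluster defines only a single breakpoint and is
dropped with a log line. FR+RF pairs overlapping on *both* sides (the
small-duplication "crossover" regime) are left unmatched — a known
limitation; it does not arise for the event-size/insert-length ratios the
simulator produces.

For an intrachromosomal cut-paste the three breakpoints admit two
labelings (either adjacent span could be the excised source); the one the
coordinate-ordered matching encounters first is kept, and the read-depth
stage later attempts to break the symmetry.

## Split reads

A split read is one primary plus exactly one supplementary segment
(chimeras with more segments are dropped). Junction coordinates come from
the read-order-adjacent ends of the two segments; the swap test compares
reference order of head and tail against read order, mirrored for
reverse-strand pairs. Classes: same chromosome + same orientation +
unswapped → DEL_INS; swapped → TD_I; different chromosomes → INS
candidate; opposite orientation → INV candidate. Inversion candidates also
carry a side flag — whether the segment at the lower junction ends or
starts there — distinguishing the two faces of an inverted segment.

A split supports an existing variant when its class matches the variant
type and both junctions land in distinct breakpoint regions (within a
10 bp window once a region is precise); matched regions collapse to the
exact junction, support becomes "mixed", and the fragment joins the
variant map. Leftover splits cluster by class, side and junction proximity
(10 bp); a TD_I cluster and a DEL_INS cluster sharing one junction define
a 3-breakpoint copy-paste insertion; inversion candidates complete only
when both faces are present; residual DEL_INS / TD_I clusters await depth
arbitration; residual INV/INS candidates emit as breakends.

## Filtering

Support thresholds are piecewise-linear in coverage over the anchor table
{5×: 3, 10×: 3, 25×: 4, 50×: 5, 100×: 6}, rounded to nearest integer and
floored at 3; the table is pinned so that 25× yields (PE, SR, mixed) =
(4, 4, 4), stays monotone, and keeps a low-coverage floor. Dataset
coverage is the pooled median read depth over mappable positions.

The disjointness filter is a greedy set cover over variant maps: the
variant with the most unique (unshared among remaining candidates)
fragments is accepted iff that unique count meets its class threshold; its
fragments are struck from all remaining maps; a rejected variant releases
its fragments, which may make a competitor acceptable. Thresholds apply to
integrated variant blocks, never to individual clusters. Accepted variant
maps are pairwise disjoint and the outcome is independent of input order
(ties break on unique count, then leading coordinate, then type).

## Read depth

The coverage track is per-base (uint32 per position; adequate at the
multi-megabase scale this package targets — a whole-genome deployment
would bin it), built from primary, MQ > 0 alignments; chromosome medians
use mappable positions only. The variant coverage ratio
VCR = sampled local mean / chromosomal median, with bases sampled
deterministically from the middle third plus two 100 bp edge windows of
the inner variant span (strided to ≤ 1000 bases); breakpoint-margin bases
are consulted only when the span yields fewer than 50 usable bases, and a
variant with fewer than 50 usable bases is rejected whatever its evidence
class. Gates: DEL with VCR ≥ 0.8 and TD/DUP with VCR ≤ 1.2 are demoted to
BND carrying a PROBTYPE (dropped outright only when flagged as sharing
support during consolidation); SR-only DEL_INS promotes to DEL below 0.8,
TD_I to TD above 1.2, otherwise both resolve to the insertion
interpretation (DN_INS). For intrachromosomal cut-paste events both
candidate source spans are tested for VCR ≈ 1 (±0.2); only when exactly
one ordering is consistent are the labels fixed (INS_C_P). For a
homozygous copy-neutral cut-paste both spans genuinely sit near VCR 1 —
the moved segment's reads still map back to the source — so the event is
reported as INS_C with unlabeled ordering; this is a property of the
evidence, not of the implementation.

## Emission

Symbolic records (DEL, DUP, INV, INS) anchor POS on the base before the
event with END the last affected base and signed SVLEN, the convention
htslib round-trips exactly. CIPOS/CIEND carry breakpoint margins, (0,0)
for SR-precise junctions. A 3-breakpoint insertion emits two BND
adjacencies (paste → each source edge) plus one DUP (copy-paste) or DEL
(cut-paste) over the source span, consecutively under one GROUPID; records
are otherwise ordered by leading coordinate, so multi-record adjacency is
preserved at the cost of strict global coordinate sort. BND ALT strings
use the single `N[chr:pos[` form without MATEID partner records. Variants
smaller than 100 bp (BNDs and interchromosomal events exempt) are not
reported.

## The simulator

`svrecombine.simulate` builds an altered genome as a segment list over a
random reference (DEL, TD, INV, copy-paste, cut-paste, novel insertion),
draws fragments uniformly from it with Gaussian insert lengths, and maps
each read interval back through the segments. Event geometry therefore
dictates exactly the discordant orientations and split junctions an
aligner would report: reads crossing a segment junction with ≥ 15 aligned
bases on each side become primary+supplementary split pairs with SA tags;
smaller overhangs are soft-clipped; reference-contiguous segment
boundaries (e.g. the outer edge of a tandem-duplication copy) are
coalesced into one alignment, as an aligner would. Mapping quality is 60,
or 0 inside configured unmappable decoy intervals; no base-level errors
are introduced by default (the caller consumes coordinates, not bases).
Defaults mirror the synthetic study the test suite runs: a 2 Mb
single-chromosome reference with 20 deletions, 10 tandem duplications,
5 inversions, 5 copy-paste and 3 cut-paste insertions of 300–5000 bp,
placed ≥ 2 kb apart, sequenced to 30× with 100 bp reads and a (350, 50)
insert library. These sizes keep a full simulate-and-call cycle around
twenty seconds on one core while leaving every cluster comfortably above
the dynamic support threshold.

What the simulator does not emulate — and what passing tests therefore do
not demonstrate about real data: repeat-biased breakpoint placement,
alignment artefacts and mismapping, base-call errors, chimeric fragments,
GC-dependent coverage waves, and heterozygosity (all events are implanted
homozygously, so depth signals are maximal). Real-data behaviour at
repeat-dense loci is bounded by the mapping-quality gates, not validated
here.

## Known limitations

* Events smaller than both the insert-length spread and the read length
  are invisible to all three evidence tiers.
* Multi-allelic overlaps (a DEL and a DUP sharing breakpoints) can cancel
  in the read-depth stage.
* The small-duplication FR+RF crossover signature is not consolidated.
* One library / read group per run; run read groups separately and merge
  downstream.
* Breakend records carry no MATEID partner bookkeeping.
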