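"""End-to-end orchestration of the three evidence tiers.

Stage order is fixed: preprocess (insert-length model + coverage), PE
clustering, cluster consolidation, split-read incorporation, dynamic
support threshold + disjointness filter, read-depth arbitration, emission.
Per-stage counts are logged to stderr and returned in the stage report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

from . import consolidation, filtering, io_formats, pe_clustering, read_depth, split_reads
from .insert_model import (
    MappabilityMask, build_coverage, build_insert_model, classify_alignment,
    pooled_median_coverage, trimmed_concordant_sample,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable knob of the caller, with working defaults.

    Mapping-quality gates: >=1 for discordant PE pairs, >=10 for split
    reads, and >=20 on both sides of an RF pair (RF evidence is the most
    repeat-prone). Depth gates 0.8 / 1.2 are the usual copy-number bounds
    for deletion / duplication at typical coverage dispersion.
    """

    mq_pe: int = 1
    mq_sr: int = 10
    mq_rf: int = 20
    bin_width: int = 5
    short_insert_factor: float = 2.0        # short-insert cut = factor * read length
    model_sample_cap: int = 1_000_000
    trim_lo: float = 0.5                    # model-sample trim, x median
    trim_hi: float = 2.0
    weight_threshold: float = 0.0
    margin_floor: int = 10
    min_cluster_size: Optional[int] = None  # None -> dynamic threshold at dataset coverage
    support_floor: int = 3
    anchor_table: dict = field(default_factory=lambda: dict(filtering.DEFAULT_ANCHOR_TABLE))
    del_thresh: float = 0.8
    dup_thresh: float = 1.2
    sufficiency_floor: int = 50
    max_depth_bases: int = 1000
    sr_merge_window: int = 10
    min_report_size: int = 100
    seed: int = 0


def run_pipeline(bam: str, out_vcf: Optional[str] = None,
                 out_bedpe: Optional[str] = None,
                 exclude_bed: Optional[str] = None,
                 mappable_bed: Optional[str] = None,
                 config: Optional[PipelineConfig] = None):
    """Run the full caller on one coordinate-sorted SAM/BAM.

    Returns ``(variants, report)``; writes VCF/BEDPE when paths are given.
    """
    cfg = config or PipelineConfig()
    report: dict = {}
    contigs = io_formats.reference_lengths(bam)

    # ---- single pass over the alignments -------------------------------
    pairs: dict[str, dict[int, io_formats.ReadRec]] = {}
    split_records: list[io_formats.ReadRec] = []
    fr_inserts: list[int] = []
    coverage_input: list[io_formats.ReadRec] = []
    read_len = 0
    raw_cap = 2 * cfg.model_sample_cap

    for rec in io_formats.read_alignments(bam):
        if rec.is_secondary:
            continue
        if rec.chrom is not None:
            coverage_input.append(rec)
            read_len = max(read_len, rec.aligned_len + rec.clip_left + rec.clip_right)
        if rec.is_supplementary:
            split_records.append(rec)
            continue
        if rec.has_sa:
            split_records.append(rec)
        slot = pairs.setdefault(rec.qname, {})
        slot[rec.read12] = rec
        if len(slot) == 2 and len(fr_inserts) < raw_cap:
            a, b = slot[1], slot[2]
            if (a.chrom is not None and a.chrom == b.chrom
                    and not a.has_sa and not b.has_sa
                    and a.mapq > 0 and b.mapq > 0):
                left, right = sorted((a, b), key=lambda r: r.start)
                if not left.is_reverse and right.is_reverse:
                    fr_inserts.append(max(left.end, right.end) - min(left.start, right.start))
    report["records"] = len(coverage_input)
    report["fragments"] = len(pairs)

    # ---- insert-length model and coverage ------------------------------
    sample = trimmed_concordant_sample(fr_inserts, cfg.trim_lo, cfg.trim_hi,
                                       cfg.model_sample_cap)
    if len(sample) < 2:
        log.warning("no usable concordant pairs; emitting an empty call set")
        report.update({"coverage": 0.0, "pe_clusters": 0, "split_reads": 0,
                       "final_variants": 0})
        if out_vcf:
            io_formats.write_vcf([], contigs, out_vcf,
                                 meta={"svrecombine_config": _config_string(cfg)})
        if out_bedpe:
            io_formats.write_bedpe([], out_bedpe)
        return [], report
    model = build_insert_model(sample, bin_width=cfg.bin_width, seed=cfg.seed)
    log.info("insert model: mean %.1f sigma3 %.0f p_mi %.0f (n=%d)",
             model.mean_il, model.sigma3, model.p_mi, model.n_sampled)

    mask = None
    if mappable_bed:
        mask = MappabilityMask.from_bed(io_formats.read_bed(mappable_bed), contigs)
    track = build_coverage(coverage_input, contigs, mask)
    dataset_cov = pooled_median_coverage(track, mask)
    report["coverage"] = dataset_cov
    del coverage_input

    thresholds = filtering.support_threshold(
        max(dataset_cov, 1e-9), cfg.anchor_table, cfg.support_floor)
    min_cluster = cfg.min_cluster_size if cfg.min_cluster_size is not None else thresholds.pe
    log.info("coverage %.1fx -> support thresholds (PE,SR,mixed)=(%d,%d,%d)",
             dataset_cov, thresholds.pe, thresholds.sr, thresholds.mixed)

    # ---- classification ------------------------------------------------
    short_floor = int(cfg.short_insert_factor * read_len) if read_len else 200
    fragments = []
    n_by_label = {"concordant": 0, "discordant": 0, "split-candidate": 0, "dropped": 0}
    for qname in sorted(pairs):
        slot = pairs[qname]
        label, payload = classify_alignment(
            (slot.get(1), slot.get(2)), model,
            mq_pe=cfg.mq_pe, mq_sr=cfg.mq_sr, mq_rf=cfg.mq_rf, short_floor=short_floor)
        n_by_label[label] += 1
        if label == "discordant":
            fragments.append(payload)
    report["classified"] = n_by_label

    if exclude_bed:
        trees = io_formats.read_bed(exclude_bed)
        before = len(fragments)
        fragments = io_formats.exclude_regions(fragments, trees)
        report["excluded_fragments"] = before - len(fragments)

        def rec_excluded(r):
            t = trees.get(r.chrom)
            return t is not None and bool(t.overlap(r.start, r.end))

        split_records = [r for r in split_records if not rec_excluded(r)]

    # ---- PE clustering and consolidation -------------------------------
    clusters = pe_clustering.cluster_fragments(
        fragments, model, min_size=min_cluster,
        margin_floor=cfg.margin_floor, weight_threshold=cfg.weight_threshold)
    report["pe_clusters"] = len(clusters)
    log.info("%d discordant fragments -> %d PE clusters", len(fragments), len(clusters))

    variants = consolidation.consolidate(clusters)
    report["pe_variants"] = len(variants)

    # ---- split reads ---------------------------------------------------
    splits = split_reads.extract_splits(split_records, mq_sr=cfg.mq_sr)
    report["split_reads"] = len(splits)
    variants = split_reads.incorporate_splits(splits, variants, cfg.sr_merge_window)
    report["variants_after_sr"] = len(variants)

    # ---- filtering -----------------------------------------------------
    consolidation.resolve_ambiguous_sharing(variants)
    passing, rejected = filtering.disjointness_filter(variants, thresholds)
    report["passing_disjointness"] = len(passing)
    report["rejected_disjointness"] = len(rejected)
    log.info("disjointness filter: %d pass, %d rejected", len(passing), len(rejected))

    # ---- read depth ----------------------------------------------------
    final = []
    demoted = rejected_depth = 0
    for v in passing:
        verdict = read_depth.depth_filter(
            v, track, mask, cfg.del_thresh, cfg.dup_thresh,
            cfg.sufficiency_floor, cfg.max_depth_bases)
        out = read_depth.apply_verdict(v, verdict)
        if out is None:
            rejected_depth += 1
            continue
        if verdict.decision == "demote_to_BND":
            demoted += 1
        out = read_depth.resolve_cut_paste(out, track, mask,
                                           sufficiency_floor=cfg.sufficiency_floor,
                                           max_bases=cfg.max_depth_bases)
        final.append(out)
    report["demoted_to_bnd"] = demoted
    report["rejected_depth"] = rejected_depth

    # ---- size filter and emission --------------------------------------
    def big_enough(v) -> bool:
        if v.sv_type == "BND" or len({b.chrom for b in v.breakpoints}) > 1:
            return True
        _, lo, hi = v.span()
        return hi - lo >= cfg.min_report_size

    final = [v for v in final if big_enough(v)]
    for n, v in enumerate(sorted(final, key=lambda v: v.sort_key()), start=1):
        v.group_id = f"G{n}"
    report["final_variants"] = len(final)
    log.info("final call set: %d variants", len(final))

    if out_vcf:
        io_formats.write_vcf(final, contigs, out_vcf,
                             meta={"svrecombine_config": _config_string(cfg)})
    if out_bedpe:
        io_formats.write_bedpe(final, out_bedpe)
    return final, report


def _config_string(cfg: PipelineConfig) -> str:
    items = sorted(asdict(cfg).items())
    return ",".join(f"{k}={v}" for k, v in items)
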