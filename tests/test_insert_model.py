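"""Insert-length model: percentiles, difference histogram, classification."""

import math

import numpy as np
import pytest

from svrecombine.insert_model import (
    ModelError, build_coverage, build_insert_model, classify_alignment,
    MappabilityMask, trimmed_concordant_sample,
)

from conftest import mk_pair, mk_rec


def sort_oracle(values, percentile):
    """Independent nearest-rank percentile: sort and index."""
    xs = sorted(values)
    rank = max(1, math.ceil(percentile / 100.0 * len(xs)))
    return xs[rank - 1]


class TestPercentiles:
    def test_sigma3_and_pmi_match_sort_oracle(self, gaussian_sample, gaussian_model):
        assert gaussian_model.sigma3 == sort_oracle(gaussian_sample, 99.85)
        assert gaussian_model.p_mi == sort_oracle(gaussian_sample, 99.9999)

    def test_pmi_is_maximum_below_1e6_samples(self, gaussian_sample, gaussian_model):
        assert gaussian_model.p_mi == max(gaussian_sample)

    def test_ordering_invariants(self, gaussian_model):
        m = gaussian_model
        assert m.mean_il <= m.sigma3 <= m.p_mi

    @pytest.mark.parametrize("n", [10, 137, 5000])
    def test_oracle_agreement_across_sizes(self, n):
        rng = np.random.default_rng(n)
        x = rng.gamma(5, 60, n) + 1
        m = build_insert_model(x, seed=0)
        assert m.sigma3 == sort_oracle(x, 99.85)
        assert m.p_mi == sort_oracle(x, 99.9999)


class TestDeltaHistogram:
    def test_mass_sums_to_one_over_bin_representatives(self, gaussian_model):
        m = gaussian_model
        total = sum(m.delta_probability(i * m.bin_width) for i in range(len(m.bin_mass)))
        assert total == pytest.approx(1.0)

    def test_degenerate_sample_concentrates_in_zero_bin(self, degenerate_model):
        assert degenerate_model.sigma3 == 350
        assert degenerate_model.p_mi == 350
        assert degenerate_model.delta_probability(0) == 1.0

    def test_out_of_support_delta_has_zero_mass(self, gaussian_model):
        assert gaussian_model.delta_probability(10 * gaussian_model.p_mi) == 0.0

    def test_negative_delta_rejected(self, gaussian_model):
        with pytest.raises(ValueError):
            gaussian_model.delta_probability(-1)


class TestConstructionErrors:
    def test_empty_input(self):
        with pytest.raises(ModelError):
            build_insert_model([])

    def test_single_value(self):
        with pytest.raises(ModelError):
            build_insert_model([350])

    def test_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            build_insert_model([350, -10, 400])

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            build_insert_model([300, 400], bin_width=0)


class TestClassification:
    def test_fr_at_mean_is_concordant(self, gaussian_model):
        label, _ = classify_alignment(mk_pair(insert=350), gaussian_model)
        assert label == "concordant"

    def test_rf_requires_mapq_20_on_both_sides(self, gaussian_model):
        r1, r2 = mk_pair(orient="RF", insert=350)
        r2 = r2._replace(mapq=19)
        label, reason = classify_alignment((r1, r2), gaussian_model, mq_rf=20)
        assert label == "dropped"
        r2 = r2._replace(mapq=20)
        label, frag = classify_alignment((r1, r2), gaussian_model, mq_rf=20)
        assert label == "discordant" and frag.orient == "RF"

    def test_long_insert_fr_is_discordant_long(self, gaussian_model):
        il = int(gaussian_model.sigma3) + 200
        label, frag = classify_alignment(mk_pair(insert=il), gaussian_model)
        assert label == "discordant"
        assert frag.orient == "FR" and frag.il_class == "long"
        assert frag.insert_length == il

    def test_short_insert_fr_is_discordant_short(self, gaussian_model):
        label, frag = classify_alignment(mk_pair(insert=150), gaussian_model,
                                         short_floor=200)
        assert label == "discordant" and frag.il_class == "short"

    def test_interchromosomal_is_discordant(self, gaussian_model):
        pair = mk_pair(chrom="chr1", chrom2="chr2", right_start=500)
        label, frag = classify_alignment(pair, gaussian_model)
        assert label == "discordant"
        assert {frag.chrom_left, frag.chrom_right} == {"chr1", "chr2"}

    def test_sa_tagged_pair_routes_to_split_stage(self, gaussian_model):
        r1, r2 = mk_pair(insert=350)
        r1 = r1._replace(has_sa=True)
        label, _ = classify_alignment((r1, r2), gaussian_model)
        assert label == "split-candidate"

    def test_one_mate_unmapped(self, gaussian_model):
        r1 = mk_rec("q", 1, "chr1", 1000, 1100, mate_unmapped=True)
        r2 = mk_rec("q", 2, None, -1, -1, mapq=0)
        label, frag = classify_alignment((r1, r2), gaussian_model)
        assert label == "discordant" and frag.orient == "UM"

    def test_partition_exactly_one_label(self, gaussian_model):
        # orientation x insert grid: every pair gets exactly one of the labels
        for orient in ("FR", "RF", "FF", "RR"):
            for il in (150, 350, 900):
                label, _ = classify_alignment(
                    mk_pair(orient=orient, insert=il), gaussian_model)
                assert label in ("concordant", "discordant", "split-candidate", "dropped")

    def test_tip_tail_convention(self, gaussian_model):
        il = int(gaussian_model.sigma3) + 500
        _, frag = classify_alignment(mk_pair(left_start=1000, insert=il,
                                             read_len=100), gaussian_model)
        # forward left mate: tip = largest coordinate (end); reverse right:
        # tip = smallest coordinate (start)
        assert frag.left_tip == 1100 and frag.left_tail == 1000
        assert frag.right_tip == 1000 + il - 100
        assert frag.right_tail == 1000 + il


def _uniform_reads(length=20_000, depth=30, read_len=100, mapq=60, offset=0):
    reads = []
    stride = read_len / depth
    i = 0
    pos = 0.0
    while pos < length - read_len:
        reads.append(mk_rec(f"r{offset}_{i}", 1, "chr1", int(pos),
                            int(pos) + read_len, mapq=mapq))
        i += 1
        pos += stride
    return reads


def pileup_oracle(reads, length, skip_mq0=True):
    """Independent pileup via a difference array."""
    diff = np.zeros(length + 1)
    for r in reads:
        if skip_mq0 and r.mapq == 0:
            continue
        diff[r.start] += 1
        diff[r.end] -= 1
    return np.cumsum(diff)[:-1]


class TestCoverage:
    def test_uniform_depth_matches_pileup_oracle(self):
        reads = _uniform_reads(depth=30)
        track = build_coverage(reads, {"chr1": 20_000})
        oracle = pileup_oracle(reads, 20_000)
        assert np.array_equal(track.depth["chr1"], oracle.astype(np.uint32))
        assert track.chrom_median["chr1"] == pytest.approx(30, abs=1)

    def test_mq0_alignments_excluded(self):
        reads = _uniform_reads(depth=15) + _uniform_reads(depth=15, mapq=0, offset=1)
        track = build_coverage(reads, {"chr1": 20_000})
        assert track.chrom_median["chr1"] == pytest.approx(15, abs=1)

    def test_empty_chromosome_has_zero_median(self):
        track = build_coverage([], {"chr1": 1000, "chr2": 1000})
        assert track.chrom_median == {"chr1": 0.0, "chr2": 0.0}

    def test_median_uses_only_masked_positions(self):
        reads = [mk_rec(f"r{i}", 1, "chr1", 100 * (i % 10), 100 * (i % 10) + 100)
                 for i in range(200)]
        mask = MappabilityMask({"chr1": np.zeros(10_000, dtype=bool)})
        mask.masks["chr1"][:1000] = True   # only the covered prefix is mappable
        track = build_coverage(reads, {"chr1": 10_000}, mask)
        assert track.chrom_median["chr1"] == 20.0


class TestTrimming:
    def test_contaminated_tail_is_removed(self):
        rng = np.random.default_rng(0)
        clean = rng.normal(350, 50, 50_000)
        contaminated = np.concatenate([clean, np.full(500, 1500.0)])
        trimmed = trimmed_concordant_sample(contaminated)
        assert trimmed.max() <= 2 * np.median(contaminated)
        assert len(trimmed) >= len(clean) * 0.99
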