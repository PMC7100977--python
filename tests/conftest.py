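"""Shared fixtures: insert-length models, record builders, simulated runs."""

import numpy as np
import pytest

from svrecombine import simulate as sim
from svrecombine.insert_model import FragmentAlignment, build_insert_model
from svrecombine.io_formats import ReadRec
from svrecombine.pe_clustering import BreakpointRegion, PECluster
from svrecombine.pipeline import PipelineConfig, run_pipeline


def mk_rec(qname="q", read12=1, chrom="chr1", start=0, end=100, reverse=False,
           mapq=60, supplementary=False, secondary=False, has_sa=False,
           mate_unmapped=False, clip_left=0, clip_right=0):
    return ReadRec(qname, read12, chrom, start, end, reverse, mapq,
                   supplementary, secondary, has_sa, mate_unmapped,
                   clip_left, clip_right)


def mk_pair(qname="q", chrom="chr1", left_start=1000, insert=350, read_len=100,
            orient="FR", mapq=60, chrom2=None, right_start=None, **kw):
    """Build the two primary mates of a fragment with a given geometry."""
    s1 = left_start
    s2 = right_start if right_start is not None else left_start + insert - read_len
    c2 = chrom2 or chrom
    rev = {"FR": (False, True), "RF": (True, False),
           "FF": (False, False), "RR": (True, True)}[orient]
    r1 = mk_rec(qname, 1, chrom, s1, s1 + read_len, rev[0], mapq, **kw)
    r2 = mk_rec(qname, 2, c2, s2, s2 + read_len, rev[1], mapq, **kw)
    return r1, r2


def mk_fragment(fragment_id="f0", chrom="chr1", left_tip=1000, orient="FR",
                il_class="long", insert_length=1500, chrom_right=None,
                right_tip=2500, read_len=100, mapq=60):
    """Discordant fragment with tip geometry consistent with its orientation."""
    left_rev = orient in ("RF", "RR")
    right_rev = orient in ("FR", "RR")
    left_tail = left_tip + read_len if left_rev else left_tip - read_len
    right_tail = right_tip + read_len if right_rev else right_tip - read_len
    return FragmentAlignment(
        fragment_id=fragment_id, chrom_left=chrom,
        chrom_right=chrom_right or chrom,
        left_tail=left_tail, left_tip=left_tip,
        right_tail=right_tail, right_tip=right_tip,
        left_reverse=left_rev, right_reverse=right_rev,
        orient=orient, insert_length=insert_length,
        mapq_left=mapq, mapq_right=mapq,
        il_class=il_class if orient == "FR" else "na",
    )


def mk_cluster(signature="FR_long", chrom="chr1", left=(1000, 1000, 1400, "F"),
               right=(1600, 2000, 2001, "R"), members=("a", "b", "c", "d")):
    frags = [mk_fragment(m, chrom, left_tip=left[1], right_tip=right[1],
                         orient=signature.split("_")[0],
                         il_class=signature.split("_")[1] if "_" in signature else "na")
             for m in members]
    c = PECluster(signature=signature, members=tuple(sorted(members)), fragments=frags)
    c.bp_left = BreakpointRegion(chrom, left[0], left[2], left[1], left[3])
    c.bp_right = BreakpointRegion(chrom, right[0], right[2], right[1], right[3])
    return c


@pytest.fixture(scope="session")
def gaussian_sample():
    rng = np.random.default_rng(42)
    return np.abs(rng.normal(350, 50, 100_000)) + 1


@pytest.fixture(scope="session")
def gaussian_model(gaussian_sample):
    return build_insert_model(gaussian_sample, bin_width=5, seed=42)


@pytest.fixture(scope="session")
def degenerate_model():
    return build_insert_model([350.0] * 100, bin_width=5, seed=0)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Modest simulated dataset plus a complete pipeline run."""
    out_dir = tmp_path_factory.mktemp("small_sim")
    data = sim.simulate_dataset(
        str(out_dir), ref_len=300_000,
        sv_spec={"DEL": (3, (300, 2000)), "TD": (2, (300, 2000)),
                 "INV": (1, (500, 2000)), "INS": (1, (500, 2000))},
        coverage=30, seed=5)
    vcf = str(out_dir / "calls.vcf")
    bedpe = str(out_dir / "calls.bedpe")
    variants, report = run_pipeline(
        data["paths"]["sam"], out_vcf=vcf, out_bedpe=bedpe,
        mappable_bed=data["paths"]["mappable"], config=PipelineConfig(seed=5))
    return {"data": data, "variants": variants, "report": report,
            "vcf": vcf, "bedpe": bedpe}


@pytest.fixture(scope="session")
def acceptance_run(tmp_path_factory):
    """The full-scale synthetic study: 2 Mb reference, 43 implanted events,
    30x coverage with a (350, 50) insert-length distribution."""
    out_dir = tmp_path_factory.mktemp("acceptance_sim")
    data = sim.simulate_dataset(str(out_dir), ref_len=2_000_000,
                                coverage=30, seed=11)
    vcf = str(out_dir / "calls.vcf")
    variants, report = run_pipeline(
        data["paths"]["sam"], out_vcf=vcf,
        mappable_bed=data["paths"]["mappable"], config=PipelineConfig(seed=11))
    return {"data": data, "variants": variants, "report": report, "vcf": vcf}


TYPE_COMPAT = {"DEL": {"DEL"}, "TD": {"TD"}, "INV": {"INV"},
               "INS": {"INS"}, "INS_C": {"INS_C", "INS_C_P"}}


def match_truth(event, variants, slop=0):
    """Find a call of compatible type whose breakpoint regions contain the
    implanted breakpoints (sorted positions compared pairwise)."""
    for v in variants:
        if v.sv_type not in TYPE_COMPAT.get(event.sv_type, set()):
            continue
        vb = sorted(v.breakpoints, key=lambda b: b.inner)
        tb = list(event.breakpoints)
        if len(vb) != len(tb):
            continue
        if all(b.lo - slop <= t < b.hi + slop for b, t in zip(vb, tb)):
            return v
    return None
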