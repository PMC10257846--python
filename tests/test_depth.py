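"""Depth extraction tests, including a brute-force overlap oracle."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanocnv.depth import (
    DepthProfile,
    compute_depth,
    enrichment_qc,
    summarize_region,
    window_depth,
)
from nanocnv.regions import Region

from conftest import write_tiny_bam

CHROMS = {"chr1": 10_000}
REGION = Region("chr1", 0, 1_000, "control", "r")


def test_empty_bam_gives_all_zero_profile(tmp_path):
    bam = write_tiny_bam(tmp_path / "e.bam", [], CHROMS)
    profile = compute_depth(bam, REGION)
    assert profile.per_base_depth.shape == (1_000,)
    assert not profile.per_base_depth.any()


def test_mapq_zero_reads_are_excluded(tmp_path):
    bam = write_tiny_bam(
        tmp_path / "q0.bam",
        [{"chrom": "chr1", "start": 0, "length": 1_000, "mapq": 0}],
        CHROMS,
    )
    assert not compute_depth(bam, REGION).per_base_depth.any()
    # raising the exclusive threshold drops low-but-nonzero MAPQ too
    bam2 = write_tiny_bam(
        tmp_path / "q5.bam",
        [{"chrom": "chr1", "start": 0, "length": 1_000, "mapq": 5}],
        CHROMS,
    )
    assert compute_depth(bam2, REGION).per_base_depth.sum() == 1_000
    assert not compute_depth(bam2, REGION, min_mapq_exclusive=5).per_base_depth.any()


def test_two_overlapping_reads(tmp_path):
    bam = write_tiny_bam(
        tmp_path / "two.bam",
        [{"chrom": "chr1", "start": 0, "length": 100},
         {"chrom": "chr1", "start": 0, "length": 100}],
        CHROMS,
    )
    profile = compute_depth(bam, Region("chr1", 0, 200, "control", "r"))
    assert (profile.per_base_depth[:100] == 2).all()
    assert (profile.per_base_depth[100:] == 0).all()


def test_deletions_and_soft_clips_add_no_depth(tmp_path):
    bam = write_tiny_bam(
        tmp_path / "cig.bam",
        [{"chrom": "chr1", "start": 10, "cigar": "5S20M10D20M5S"}],
        CHROMS,
    )
    profile = compute_depth(bam, Region("chr1", 0, 100, "control", "r"))
    expected = np.zeros(100, int)
    expected[10:30] = 1
    expected[40:60] = 1
    assert (profile.per_base_depth == expected).all()


def test_missing_index_raises_actionable_error(tmp_path):
    bam = write_tiny_bam(tmp_path / "x.bam", [], CHROMS)
    (tmp_path / "x.bam.bai").unlink()
    with pytest.raises(Exception, match="[Ii]ndex"):
        compute_depth(bam, REGION)


def test_unknown_chromosome_rejected(tmp_path):
    bam = write_tiny_bam(tmp_path / "c.bam", [], CHROMS)
    with pytest.raises(ValueError, match="chr9"):
        compute_depth(bam, Region("chr9", 0, 100, "control", "r"))


def _brute_force_depth(bam_path, region, min_mapq_exclusive=0):
    """Independent oracle: per-position membership in aligned positions."""
    depth = np.zeros(region.length, dtype=int)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(region.chrom, region.start, region.end):
            if read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality <= min_mapq_exclusive:
                continue
            for pos in read.get_reference_positions():
                if region.start <= pos < region.end:
                    depth[pos - region.start] += 1
    return depth


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_depth_matches_brute_force_oracle_on_random_bams(tmp_path, seed):
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(int(rng.integers(20, 100))):
        start = int(rng.integers(0, 9_000))
        kind = rng.integers(0, 3)
        if kind == 0:
            read = {"chrom": "chr1", "start": start, "length": int(rng.integers(10, 400))}
        elif kind == 1:
            m1, d, m2 = rng.integers(5, 100, 3)
            read = {"chrom": "chr1", "start": start, "cigar": f"{m1}M{d}D{m2}M"}
        else:
            s, m = rng.integers(2, 50, 2)
            read = {"chrom": "chr1", "start": start, "cigar": f"{s}S{m}M"}
        read["mapq"] = int(rng.choice([0, 1, 30, 60]))
        reads.append(read)
    bam = write_tiny_bam(tmp_path / f"r{seed}.bam", reads, CHROMS)
    region = Region("chr1", 500, 9_500, "control", "r")
    got = compute_depth(bam, region).per_base_depth
    assert (got == _brute_force_depth(bam, region)).all()
    # order invariance: reversing write order (shuffled dicts) changes nothing
    bam2 = write_tiny_bam(tmp_path / f"r{seed}b.bam", reads[::-1], CHROMS)
    assert (compute_depth(bam2, region).per_base_depth == got).all()


def test_summarize_region_mean():
    depth = np.zeros(200, int)
    depth[:100] = 2
    profile = DepthProfile(Region("chr1", 0, 200, "control", "r"), depth)
    s = summarize_region(profile)
    assert s.mean_depth == 1.0 and s.n_positions == 200


def test_windowing_shapes_and_remainder():
    profile = DepthProfile(Region("chr1", 0, 1_000, "control", "r"),
                           np.full(1_000, 5))
    w = window_depth(profile, 0.01)
    assert len(w.window_means) == 100 and w.window_size == 10
    assert (w.window_means == 5).all()

    profile = DepthProfile(Region("chr1", 0, 1_005, "control", "r"),
                           np.arange(1_005))
    w = window_depth(profile, 0.01)
    assert len(w.window_means) == 100
    assert w.window_sizes[-1] == 15 and (w.window_sizes[:-1] == 10).all()


@settings(max_examples=100, deadline=None)
@given(st.integers(100, 3_000), st.integers(0, 2**31 - 1))
def test_weighted_window_mean_equals_region_mean(length, seed):
    depth = np.random.default_rng(seed).integers(0, 30, length)
    profile = DepthProfile(Region("chr1", 0, length, "control", "r"), depth)
    w = window_depth(profile)
    weighted = float((w.window_means * w.window_sizes).sum() / w.window_sizes.sum())
    assert weighted == pytest.approx(depth.mean(), rel=1e-9)


def test_window_fraction_validation():
    profile = DepthProfile(Region("chr1", 0, 1_000, "control", "r"), np.zeros(1_000))
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            window_depth(profile, bad)


def test_enrichment_qc_values():
    assert enrichment_qc(9.5, 1.13) == 8.4
    assert enrichment_qc(7.0, 7.0) == 1.0
    assert enrichment_qc(10.0, 2.0) == 5.0
    with pytest.raises(ValueError):
        enrichment_qc(9.5, 0.0)
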