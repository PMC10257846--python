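"""Normalization, dynamic cutoffs, confirmation, and copy-number tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanocnv.confirm import (
    Cutoffs,
    NormalizedRatios,
    confirm,
    downsample_titration,
    dynamic_cutoff,
    estimate_copy_number,
    normalize_regions,
    resolve_context,
    run_confirmation,
)
from nanocnv.depth import RegionDepthSummary
from nanocnv.regions import Region


def summaries_from(control_means, cnv_mean, pad_means=()):
    out = [
        RegionDepthSummary(Region("chr1", i * 10, i * 10 + 10, "control", f"c{i}"), m, 10)
        for i, m in enumerate(control_means)
    ]
    for i, m in enumerate(pad_means):
        role = "pad_left" if i == 0 else "pad_right"
        out.append(RegionDepthSummary(Region("chr2", i * 10, i * 10 + 10, role, role), m, 10))
    out.append(RegionDepthSummary(Region("chr2", 100, 110, "cnv", "cnv"), cnv_mean, 10))
    return out


def test_normalize_simple_ratio():
    ratios = normalize_regions(summaries_from([10, 10, 10, 10, 10], 5))
    assert ratios.cnv_ratio == pytest.approx(0.5)
    assert ratios.normalizer == 10


def test_normalize_mixed_controls():
    ratios = normalize_regions(summaries_from([8, 9, 10, 11, 12], 10))
    assert ratios.normalizer == pytest.approx(10)
    assert ratios.cnv_ratio == pytest.approx(1.0)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0.1, 100), min_size=2, max_size=10),
       st.floats(0, 100))
def test_control_ratios_average_to_one(control_means, cnv_mean):
    ratios = normalize_regions(summaries_from(control_means, cnv_mean))
    assert float(np.mean(ratios.control_ratios)) == pytest.approx(1.0, abs=1e-9)


def test_all_zero_controls_rejected():
    with pytest.raises(ValueError, match="assay failure"):
        normalize_regions(summaries_from([0, 0, 0, 0, 0], 5))


def test_deletion_cutoff_matches_hand_computed_sample_sd():
    # control ratios {0.9, 0.95, 1.0, 1.05, 1.1}: sample SD 0.0790569,
    # deletion cutoff 1 - 3*SD = 0.762829
    ratios = normalize_regions(summaries_from([9, 9.5, 10, 10.5, 11], 5))
    cuts = dynamic_cutoff(ratios, "deletion")
    assert cuts.sd_controls == pytest.approx(0.0790569, abs=1e-6)
    assert cuts.controls_only == pytest.approx(0.762829, abs=1e-5)
    assert cuts.controls_plus_pads is None
    assert cuts.effective == cuts.controls_only


def test_degenerate_identical_controls_give_cutoff_at_mean():
    ratios = normalize_regions(summaries_from([10, 10, 10, 10, 10], 5))
    cuts = dynamic_cutoff(ratios, "deletion")
    assert cuts.sd_controls == 0.0
    assert cuts.effective == 1.0


def test_effective_cutoff_is_stricter_candidate():
    # deletions take the larger candidate, duplications the smaller
    base = normalize_regions(
        summaries_from([9, 9.5, 10, 10.5, 11], 5, pad_means=[10, 10])
    )
    for expected_type, pick in (("deletion", max), ("duplication", min)):
        cuts = dynamic_cutoff(base, expected_type)
        assert cuts.controls_plus_pads is not None
        assert cuts.effective == pick(cuts.controls_only, cuts.controls_plus_pads)


def test_confirmation_is_inclusive_at_the_cutoff():
    ratios = NormalizedRatios(np.ones(5), np.array([]), 0.80, 10.0)
    cuts = Cutoffs(0.80, None, 0.80, 0.05, None)
    assert confirm(ratios, cuts, "deletion")  # "at least" three SDs
    ratios.cnv_ratio = 0.5
    assert confirm(ratios, cuts, "deletion")
    ratios.cnv_ratio = 0.98
    assert not confirm(ratios, cuts, "deletion")
    dup_cuts = Cutoffs(1.2, None, 1.2, 0.05, None)
    ratios.cnv_ratio = 1.2
    assert confirm(ratios, dup_cuts, "duplication")


@pytest.mark.parametrize(
    "ratio,context,expected",
    [
        (0.02, "autosomal", 0),
        (0.52, "autosomal", 1),
        (1.0, "autosomal", 2),
        (1.48, "autosomal", 3),
        (2.5, "autosomal", 5),
        (0.75, "autosomal", 1),  # midpoint tie -> lower copy number
        (0.0, "male_sex", 0),
        (1.02, "male_sex", 1),
        (1.98, "male_sex", 2),
        (1.5, "male_sex", 1),  # tie -> lower
        (3.1, "male_sex", 3),
    ],
)
def test_copy_number_ladder(ratio, context, expected):
    assert estimate_copy_number(ratio, context) == expected


def test_copy_number_monotone_in_ratio():
    grid = np.linspace(0, 4, 200)
    for context in ("autosomal", "male_sex"):
        estimates = [estimate_copy_number(r, context) for r in grid]
        assert all(a <= b for a, b in zip(estimates, estimates[1:]))


def test_resolve_context_rules():
    assert resolve_context("chr7", 0, 100, "unknown") == "autosomal"
    assert resolve_context("chrX", 50_000_000, 51_000_000, "XX") == "autosomal"
    assert resolve_context("chrX", 50_000_000, 51_000_000, "XY") == "male_sex"
    # PAR1 lies at the X tip and behaves autosomally even in males
    assert resolve_context("chrX", 100_000, 200_000, "XY") == "autosomal"
    with pytest.raises(ValueError, match="unknown sample"):
        resolve_context("chrY", 14_000_000, 14_500_000, "unknown")


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0.5, 2.0), min_size=3, max_size=8))
def test_cutoffs_straddle_one_when_sd_positive(control_means):
    ratios = normalize_regions(summaries_from(control_means, 1.0))
    if float(np.asarray(ratios.control_ratios).std(ddof=1)) == 0:
        return
    del_cut = dynamic_cutoff(ratios, "deletion").effective
    dup_cut = dynamic_cutoff(ratios, "duplication").effective
    assert del_cut < 1.0 < dup_cut


def test_titration_full_depth_confirms_all_replicates(sim_deletion):
    sim, manifest, hyp = sim_deletion
    controls = [r for r in manifest if r.role == "control"]
    report = downsample_titration(
        sim.bam, manifest, hyp, target_depths=[9.9], reps=10, seed=7
    )
    assert report.confirmations[9.9] == 10


def test_titration_skips_unreachable_depths_and_empty_reps(sim_deletion):
    sim, manifest, hyp = sim_deletion
    report = downsample_titration(
        sim.bam, manifest, hyp, target_depths=[500.0], reps=2, seed=1
    )
    assert report.target_depths == []
    empty = downsample_titration(
        sim.bam, manifest, hyp, target_depths=[5.0], reps=0, seed=1
    )
    assert empty.confirmations == {5.0: 0}


def test_full_pipeline_on_simulated_deletion(sim_deletion):
    sim, manifest, hyp = sim_deletion
    result = run_confirmation(sim.bam, manifest, hyp)
    assert result.confirmed
    assert result.estimated_copy_number == 1
    assert 0.4 < result.cnv_ratio < 0.6
    assert result.cutoffs.effective < 1.0
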