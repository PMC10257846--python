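"""Identity-matching tests: locus selection, genotype calls, concordance."""

import numpy as np
import pandas as pd
import pytest

from nanocnv.identity import (
    GenotypeCall,
    GenotypePanel,
    SNVLocus,
    build_panel,
    call_genotype,
    match_matrix,
    match_panels,
    match_region,
    select_loci,
)
from nanocnv.regions import GenomeBuild, Region
from nanocnv.simulate import (
    SimulatedGenotype,
    SimulatedSampleSpec,
    draw_snv_candidates,
    simulate_reads,
)

REGION = Region("chr1", 0, 500_000, "control", "c1")


def test_select_loci_caps_at_150_sorted_ascending():
    rng = np.random.default_rng(0)
    positions = rng.choice(500_000, 300, replace=False)
    df = pd.DataFrame({
        "chrom": "chr1", "pos": positions, "ref": "A", "alt": "G",
        "af": rng.uniform(0.4, 0.6, 300),
    })
    loci = select_loci(df, [REGION])
    assert len(loci["c1"]) == 150
    got = [l.pos for l in loci["c1"]]
    assert got == sorted(got) == sorted(positions)[:150]


def test_select_loci_af_band_is_closed():
    df = pd.DataFrame({
        "chrom": ["chr1"] * 4, "pos": [10, 20, 30, 40],
        "ref": ["A"] * 4, "alt": ["G"] * 4,
        "af": [0.39, 0.40, 0.60, 0.61],
    })
    loci = select_loci(df, [REGION])
    assert [l.pos for l in loci["c1"]] == [20, 30]


def test_select_loci_empty_region_excluded_with_warning(caplog):
    df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "af"])
    with caplog.at_level("WARNING"):
        loci = select_loci(df, [REGION])
    assert loci == {}
    assert "no qualifying SNVs" in caplog.text


LOCUS = SNVLocus("chr1", 100, "A", "G", 0.5)


@pytest.mark.parametrize(
    "platform,depth,ref,alt,expected",
    [
        ("short_read", 9, 9, 0, "no_call"),  # below the 10-read minimum
        ("short_read", 10, 10, 0, "hom_ref"),
        ("long_read", 1, 0, 1, "hom_alt"),  # one read suffices for long reads
        ("long_read", 0, 0, 0, "no_call"),
        ("long_read", 20, 19, 1, "other"),  # 0.95 is not > 0.95
        ("long_read", 20, 1, 19, "other"),
        ("long_read", 21, 20, 1, "hom_ref"),
        ("short_read", 12, 5, 7, "other"),
    ],
)
def test_call_genotype_thresholds(platform, depth, ref, alt, expected):
    assert call_genotype(LOCUS, depth, ref, alt, platform).call == expected


def _panel(name, platform, calls_by_region):
    return GenotypePanel(name, platform, calls_by_region)


def _calls(genotypes, chrom="chr1", offset=0):
    return [
        GenotypeCall(SNVLocus(chrom, offset + i, "A", "G", 0.5), 20,
                     20 if g == "hom_ref" else 0,
                     20 if g == "hom_alt" else 0, g)
        for i, g in enumerate(genotypes)
    ]


def test_match_region_identical_and_boundary():
    a = _calls(["hom_ref"] * 20 + ["hom_alt"] * 20)
    prop, matched, n = match_region(a, a)
    assert (prop, matched, n) == (1.0, True, 40)

    # 89/100 agreeing is below the >90% bar
    b = _calls(["hom_ref"] * 100)
    c = _calls(["hom_ref"] * 89 + ["hom_alt"] * 11)
    prop, matched, n = match_region(b, c)
    assert prop == pytest.approx(0.89)
    assert matched is False and n == 100


def test_match_region_no_shared_loci_is_no_data():
    a = _calls(["other"] * 10)
    prop, matched, n = match_region(a, a)
    assert (prop, matched, n) == (None, None, 0)


def test_loci_homozygous_in_one_sample_only_are_excluded():
    a = _calls(["hom_ref", "hom_ref", "hom_alt"])
    b = _calls(["hom_ref", "other", "hom_alt"])
    prop, matched, n = match_region(a, b)
    assert n == 2 and prop == 1.0 and matched


def test_unrelated_panels_match_about_half_of_loci():
    """Independent genotypes at AF-0.5 loci agree ~50% of the time.

    Under independence, two homozygous calls coincide with probability 1/2
    (each is hom_ref or hom_alt with equal chance), so the concordance for
    unrelated samples concentrates near 0.5, far below the >0.9 bar.
    """
    rng = np.random.default_rng(123)
    n = 2_000
    a = _calls(list(rng.choice(["hom_ref", "hom_alt"], n)))
    b = _calls(list(rng.choice(["hom_ref", "hom_alt"], n)))
    prop, matched, shared = match_region(a, b)
    assert shared == n
    assert prop == pytest.approx(0.5, abs=0.05)
    assert matched is False


def test_match_matrix_symmetric_with_self_match_one():
    rng = np.random.default_rng(5)
    def random_panel(name, seed):
        r = np.random.default_rng(seed)
        return _panel(name, "long_read", {
            f"r{k}": _calls(list(r.choice(["hom_ref", "hom_alt"], 50)),
                            offset=k * 100)
            for k in range(4)
        })
    panels = [random_panel(f"s{i}", i) for i in range(3)]
    m = match_matrix(panels)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 1.0)
    same = match_panels(panels[0], panels[0])
    assert same.fraction_regions_matched == 1.0 and same.overall_matched


def test_cross_platform_matching_on_simulated_bams(tmp_path):
    """Long- vs short-read panels from the same simulated individual match
    in all regions; an unrelated individual matches none."""
    controls = [
        Region("chr1", 50_000 + i * 200_000, 150_000 + i * 200_000,
               "control", f"c{i + 1}")
        for i in range(4)
    ]
    genome = GenomeBuild.from_dict({"chr1": 900_000})
    candidates = draw_snv_candidates(controls, 200, seed=9)
    loci = select_loci(candidates, controls)

    def genotypes(seed):
        r = np.random.default_rng(seed)
        return [
            SimulatedGenotype(l, str(r.choice(["0/0", "0/1", "1/1"],
                                              p=[0.25, 0.5, 0.25])))
            for ls in loci.values() for l in ls
        ]

    def simulate(name, genos, depth, read_len, seed):
        spec = SimulatedSampleSpec(
            genome=genome, target_regions=controls, diploid_mean_depth=depth,
            on_target_read_length_mean=read_len, off_target_mean_depth=0,
            snv_genotypes=genos, seed=seed,
        )
        return simulate_reads(spec, tmp_path, name=name).bam

    g_same = genotypes(1)
    long_a = build_panel(simulate("la", g_same, 9.5, 4805, 11), loci, "a", "long_read")
    short_a = build_panel(simulate("sa", g_same, 25, 300, 12), loci, "a", "short_read")
    short_b = build_panel(simulate("sb", genotypes(2), 25, 300, 13), loci, "b",
                          "short_read")

    same = match_panels(long_a, short_a)
    assert same.overall_matched and same.fraction_regions_matched == 1.0
    other = match_panels(long_a, short_b)
    assert not other.overall_matched and other.fraction_regions_matched == 0.0
    for prop in other.proportions.values():
        assert prop is not None and prop < 0.75
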