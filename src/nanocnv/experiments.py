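"""Reusable simulation experiments: copy-number ladder, specificity,
copy-number recovery, and scaled-down cohort concordance.

Each experiment generates samples with the built-in read simulator, runs the
full confirmation pipeline on the emitted BAMs, and aggregates the resulting
normalized depth ratios / decisions. They are the computational backbone of
both the test suite and the reproduction script.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np

from .confirm import run_confirmation
from .regions import GenomeBuild, Region
from .simulate import (
    CohortSample,
    CopySegment,
    SimulatedSampleSpec,
    make_validation_cohort,
    simulate_reads,
)
from .target_design import CNVHypothesis

__all__ = [
    "ratio_spec",
    "RatioExperimentResult",
    "ratio_experiment",
    "specificity_experiment",
    "copy_recovery_experiment",
    "cohort_concordance",
]

_PAD = 500_000
_CNV_SIZE = 500_000


def ratio_spec(
    copies: int,
    seed: int,
    male_sex_chrom: bool = False,
    depth: float = 10.0,
    write_sequences: bool = False,
) -> tuple[SimulatedSampleSpec, list[Region], Region]:
    """Standard single-CNV design: five 500-kb copy-neutral controls on chr1
    and a 500-kb test region with 500-kb pads on a second chromosome (chrX
    treated as haploid when ``male_sex_chrom``)."""
    test_chrom = "chrX" if male_sex_chrom else "chr2"
    controls = [
        Region("chr1", 100_000 + i * 600_000, 600_000 + i * 600_000,
               "control", f"ctrl{i + 1}")
        for i in range(5)
    ]
    cnv_start = 100_000 + _PAD
    cnv = Region(test_chrom, cnv_start, cnv_start + _CNV_SIZE, "cnv", "cnv")
    pads = [
        Region(test_chrom, cnv.start - _PAD, cnv.start, "pad_left", "pad_left"),
        Region(test_chrom, cnv.end, cnv.end + _PAD, "pad_right", "pad_right"),
    ]
    genome = GenomeBuild.from_dict({
        "chr1": controls[-1].end + 100_000,
        test_chrom: pads[1].end + 100_000,
    })
    spec = SimulatedSampleSpec(
        genome=genome,
        target_regions=[*controls, *pads, cnv],
        copy_number_map=[CopySegment(cnv, copies)],
        diploid_mean_depth=depth,
        haploid_chroms=frozenset({"chrX"}) if male_sex_chrom else frozenset(),
        write_sequences=write_sequences,
        seed=seed,
    )
    manifest = [*controls, *pads, cnv]
    return spec, manifest, cnv


@dataclass
class RatioExperimentResult:
    ratios: np.ndarray
    confirmed: np.ndarray  # bool per replicate
    copy_estimates: np.ndarray

    @property
    def mean_ratio(self) -> float:
        return float(self.ratios.mean())


def _hypothesis_for(copies: int, male: bool) -> str:
    expected = 1 if male else 2
    return "deletion" if copies < expected else "duplication"


def run_single(
    copies: int,
    seed: int,
    expected_type: str,
    male_sex_chrom: bool = False,
    depth: float = 10.0,
):
    """Simulate one sample and run the confirmation pipeline on its BAM."""
    spec, manifest, cnv_region = ratio_spec(copies, seed, male_sex_chrom, depth)
    hypothesis = CNVHypothesis(
        cnv_region, expected_type,
        sample_sex="XY" if male_sex_chrom else "unknown",
    )
    # mini-genome chrX region sits outside the GRCh37 PAR windows only by
    # accident of coordinates; pass no PARs for the synthetic build
    par = () if male_sex_chrom else None
    with tempfile.TemporaryDirectory() as tmp:
        sim = simulate_reads(spec, tmp)
        if par is None:
            return run_confirmation(sim.bam, manifest, hypothesis)
        return run_confirmation(sim.bam, manifest, hypothesis, par_intervals=par)


def ratio_experiment(
    copies: int,
    n_seeds: int,
    seed: int,
    male_sex_chrom: bool = False,
    depth: float = 10.0,
    expected_type: str | None = None,
) -> RatioExperimentResult:
    """Mean normalized CNV depth ratio (and decisions) over ``n_seeds``
    replicate simulations of the standard single-CNV design."""
    sub_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, n_seeds)
    if expected_type is None:
        expected_type = _hypothesis_for(copies, male_sex_chrom)
    ratios, confirmed, estimates = [], [], []
    for s in sub_seeds:
        result = run_single(copies, int(s), expected_type, male_sex_chrom, depth)
        ratios.append(result.cnv_ratio)
        confirmed.append(result.confirmed)
        estimates.append(result.estimated_copy_number)
    return RatioExperimentResult(
        np.array(ratios), np.array(confirmed), np.array(estimates)
    )


def specificity_experiment(n_seeds: int, seed: int, depth: float = 10.0) -> float:
    """False-positive rate on copy-neutral samples.

    Each replicate mirrors one false-positive case: a single hypothesized CNV
    type tested against a copy-neutral region (directions alternate across
    replicates so both tails are exercised). Returns the fraction confirmed.
    """
    sub_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, n_seeds)
    false_pos = 0
    for i, s in enumerate(sub_seeds):
        spec, manifest, cnv_region = ratio_spec(2, int(s), depth=depth)
        expected = "deletion" if i % 2 == 0 else "duplication"
        with tempfile.TemporaryDirectory() as tmp:
            sim = simulate_reads(spec, tmp)
            hyp = CNVHypothesis(cnv_region, expected)
            false_pos += run_confirmation(sim.bam, manifest, hyp).confirmed
    return false_pos / n_seeds


def copy_recovery_experiment(
    copies_list: list[int], n_per_state: int, seed: int, depth: float = 10.0
) -> float:
    """Fraction of simulations in which the integer copy-number estimate
    recovers the simulated truth (autosomal ladder)."""
    rng = np.random.default_rng(seed)
    correct = total = 0
    for copies in copies_list:
        expected_type = _hypothesis_for(copies, male=False)
        for _ in range(n_per_state):
            result = run_single(copies, int(rng.integers(0, 2**31 - 1)), expected_type)
            correct += result.estimated_copy_number == copies
            total += 1
    return correct / total


@dataclass
class CohortOutcome:
    n_samples: int
    n_true_cnv: int
    true_confirmed: int
    false_positives: int
    per_sample: list[dict]

    @property
    def concordance_percent(self) -> float:
        """Percent of samples called correctly: true CNVs confirmed, the
        copy-neutral sample not confirmed."""
        correct = self.true_confirmed + (
            (self.n_samples - self.n_true_cnv) - self.false_positives
        )
        return 100.0 * correct / self.n_samples


def cohort_concordance(
    n_samples: int,
    seed: int,
    size_range: tuple[int, int] = (40_000, 2_000_000),
    on_target_depth: float = 9.5,
    write_sequences: bool = True,
) -> CohortOutcome:
    """End-to-end concordance on a simulated validation cohort of known
    deletions/duplications plus one copy-neutral (false-positive) sample."""
    cohort = make_validation_cohort(
        n_samples, seed, size_range, on_target_depth,
        write_sequences=write_sequences,
    )
    true_confirmed = false_pos = n_true = 0
    per_sample = []
    for sample in cohort:
        hyp = CNVHypothesis(sample.cnv_region, sample.expected_type)
        with tempfile.TemporaryDirectory() as tmp:
            sim = simulate_reads(sample.spec, tmp, name=sample.name)
            result = run_confirmation(sim.bam, sample.manifest, hyp)
        if sample.is_copy_neutral:
            false_pos += result.confirmed
        else:
            n_true += 1
            true_confirmed += result.confirmed
        per_sample.append({
            "sample": sample.name,
            "cnv_size": sample.cnv_region.length,
            "expected_type": sample.expected_type,
            "true_copies": sample.true_copies,
            "copy_neutral": sample.is_copy_neutral,
            "cnv_ratio": result.cnv_ratio,
            "effective_cutoff": result.cutoffs.effective,
            "confirmed": bool(result.confirmed),
            "estimated_copy_number": result.estimated_copy_number,
        })
    return CohortOutcome(len(cohort), n_true, true_confirmed, false_pos, per_sample)
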