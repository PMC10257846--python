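"""CNV confirmation from normalized read depth.

The suspected region's mean depth is divided by the mean of the control-region
mean depths; a deletion (duplication) is confirmed when that ratio sits at
least three sample standard deviations below (above) the mean of a reference
ratio set. Two candidate cutoffs are computed — one from the controls alone,
one from controls plus the CNV-specific pad regions, each in its own
normalization — and the stricter one (larger for deletions, smaller for
duplications) is applied. Copy number is then read off a depth-ratio ladder:
0.5 per copy on autosomes, the female X and pseudoautosomal regions; 1 per
copy on the male X/Y outside the PARs.
"""

from __future__ import annotations

import logging
import math
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .depth import RegionDepthSummary, summarize_regions
from .regions import Region
from .target_design import CNVHypothesis

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedRatios",
    "Cutoffs",
    "ConfirmationResult",
    "DownsampleReport",
    "normalize_regions",
    "dynamic_cutoff",
    "confirm",
    "estimate_copy_number",
    "resolve_context",
    "run_confirmation",
    "downsample_titration",
    "GRCH37_PAR_INTERVALS",
]

SD_MULTIPLIER_DEFAULT = 3.0

# GRCh37 pseudoautosomal intervals, 0-based half-open.
GRCH37_PAR_INTERVALS: tuple[tuple[str, int, int], ...] = (
    ("chrX", 60_000, 2_699_520),
    ("chrX", 154_931_043, 155_260_560),
    ("chrY", 10_000, 2_649_520),
    ("chrY", 59_034_049, 59_363_566),
    ("X", 60_000, 2_699_520),
    ("X", 154_931_043, 155_260_560),
    ("Y", 10_000, 2_649_520),
    ("Y", 59_034_049, 59_363_566),
)

SEX_CHROM_NAMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class NormalizedRatios:
    """Region mean depths on two normalization scales.

    ``control_ratios``/``pad_ratios``/``cnv_ratio`` are normalized by the mean
    of the analysis-control mean depths (so the control ratios average to 1 by
    construction). The ``cp_*`` fields repeat the calculation with the mean
    over controls *and* pads as denominator, feeding the second cutoff
    candidate; they are None when no pads exist.
    """

    control_ratios: np.ndarray
    pad_ratios: np.ndarray
    cnv_ratio: float
    normalizer: float
    cp_control_ratios: np.ndarray | None = None
    cp_pad_ratios: np.ndarray | None = None
    cp_cnv_ratio: float | None = None
    cp_normalizer: float | None = None
    control_labels: list[str] = field(default_factory=list)


def normalize_regions(summaries: list[RegionDepthSummary]) -> NormalizedRatios:
    """Normalize region mean depths by the mean control depth.

    ``summaries`` carries the analysis manifest roles: >=2 controls, 0-2 pads,
    exactly one CNV region. All-zero controls indicate assay failure and are
    rejected.
    """
    controls = [s for s in summaries if s.region.role == "control"]
    pads = [s for s in summaries if s.region.role in ("pad_left", "pad_right")]
    cnvs = [s for s in summaries if s.region.role == "cnv"]
    if len(controls) < 2:
        raise ValueError("need at least two control-region summaries")
    if len(cnvs) != 1:
        raise ValueError(f"need exactly one CNV-region summary, got {len(cnvs)}")
    control_means = np.array([s.mean_depth for s in controls], dtype=float)
    normalizer = float(control_means.mean())
    if normalizer <= 0:
        raise ValueError("all control regions have zero depth: assay failure")
    pad_means = np.array([s.mean_depth for s in pads], dtype=float)
    cnv_mean = cnvs[0].mean_depth

    ratios = NormalizedRatios(
        control_ratios=control_means / normalizer,
        pad_ratios=pad_means / normalizer if len(pads) else np.array([]),
        cnv_ratio=cnv_mean / normalizer,
        normalizer=normalizer,
        control_labels=[s.region.label for s in controls],
    )
    if len(pads):
        cp_norm = float(np.concatenate([control_means, pad_means]).mean())
        if cp_norm > 0:
            ratios.cp_control_ratios = control_means / cp_norm
            ratios.cp_pad_ratios = pad_means / cp_norm
            ratios.cp_cnv_ratio = cnv_mean / cp_norm
            ratios.cp_normalizer = cp_norm
    return ratios


@dataclass(frozen=True)
class Cutoffs:
    controls_only: float
    controls_plus_pads: float | None
    effective: float
    sd_controls: float
    sd_controls_plus_pads: float | None


def dynamic_cutoff(
    ratios: NormalizedRatios,
    expected_type: str,
    sd_multiplier: float = SD_MULTIPLIER_DEFAULT,
) -> Cutoffs:
    """Per-sample confirmation cutoffs at ``sd_multiplier`` (default 3) sample
    standard deviations below (deletion) / above (duplication) the reference
    mean; the effective cutoff is the stricter candidate: the larger for
    deletions, the smaller for duplications."""
    sign = -1.0 if expected_type == "deletion" else +1.0
    ref1 = np.asarray(ratios.control_ratios, dtype=float)
    if len(ref1) < 2:
        raise ValueError("standard deviation undefined with fewer than two controls")
    sd1 = float(ref1.std(ddof=1))
    if sd1 == 0:
        log.warning("control-ratio SD is zero; cutoff degenerates to the mean "
                    "and is unreliable")
    cut1 = float(ref1.mean() + sign * sd_multiplier * sd1)

    cut2 = sd2 = None
    if ratios.cp_control_ratios is not None and len(ratios.cp_pad_ratios) > 0:
        ref2 = np.concatenate([ratios.cp_control_ratios, ratios.cp_pad_ratios])
        sd2 = float(ref2.std(ddof=1))
        cut2 = float(ref2.mean() + sign * sd_multiplier * sd2)

    if cut2 is None:
        effective = cut1
    elif expected_type == "deletion":
        effective = max(cut1, cut2)
    else:
        effective = min(cut1, cut2)
    return Cutoffs(cut1, cut2, effective, sd1, sd2)


def confirm(ratios: NormalizedRatios, cutoffs: Cutoffs, expected_type: str) -> bool:
    """Inclusive comparison ("at least" three SDs): deletion confirmed iff the
    CNV ratio <= the effective cutoff, duplication iff >=."""
    if expected_type == "deletion":
        return ratios.cnv_ratio <= cutoffs.effective
    return ratios.cnv_ratio >= cutoffs.effective


def resolve_context(
    chrom: str,
    start: int,
    end: int,
    sample_sex: str,
    par_intervals: tuple[tuple[str, int, int], ...] = GRCH37_PAR_INTERVALS,
    sex_chrom_names: set[str] = SEX_CHROM_NAMES,
) -> str:
    """Return the copy-number ladder context for a region.

    ``autosomal`` covers autosomes, the female X, and PAR intervals (expected
    ratio 0.5 per copy); ``male_sex`` covers the male X/Y outside the PARs
    (expected ratio 1 per copy). Sex chromosomes with unknown sample sex
    cannot be resolved.
    """
    if chrom not in sex_chrom_names:
        return "autosomal"
    in_par = any(
        c == chrom and start >= s and end <= e for c, s, e in par_intervals
    )
    if in_par:
        return "autosomal"
    if sample_sex == "XX":
        return "autosomal"
    if sample_sex == "XY":
        return "male_sex"
    raise ValueError(
        f"cannot resolve copy-number context for {chrom} with unknown sample "
        "sex; set sample_sex to XX or XY"
    )


def estimate_copy_number(cnv_ratio: float, context: str) -> int:
    """Nearest rung of the depth-ratio ladder (ties go to the lower copy
    number): step 0.5 per copy in the ``autosomal`` context, step 1 per copy
    in the ``male_sex`` context."""
    if cnv_ratio < 0:
        raise ValueError("depth ratio must be non-negative")
    step = 0.5 if context == "autosomal" else 1.0
    return max(0, math.ceil(cnv_ratio / step - 0.5))


@dataclass
class ConfirmationResult:
    cnv: CNVHypothesis
    ratios: NormalizedRatios
    cutoffs: Cutoffs
    confirmed: bool
    estimated_copy_number: int
    context: str

    @property
    def cnv_ratio(self) -> float:
        return self.ratios.cnv_ratio

    def to_row(self) -> dict:
        r = self.cnv.region
        return {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "expected_type": self.cnv.expected_type,
            "cnv_ratio": self.ratios.cnv_ratio,
            "cutoff_controls_only": self.cutoffs.controls_only,
            "cutoff_controls_plus_pads": self.cutoffs.controls_plus_pads,
            "effective_cutoff": self.cutoffs.effective,
            "confirmed": self.confirmed,
            "estimated_copy_number": self.estimated_copy_number,
            "context": self.context,
        }


def run_confirmation(
    alignments: str | Path,
    manifest: list[Region],
    cnv: CNVHypothesis,
    sd_multiplier: float = SD_MULTIPLIER_DEFAULT,
    min_mapq_exclusive: int = 0,
    par_intervals: tuple[tuple[str, int, int], ...] = GRCH37_PAR_INTERVALS,
) -> ConfirmationResult:
    """Full confirmation for one sample: depth summaries over the manifest,
    normalization, dynamic cutoffs, decision, and copy-number estimate."""
    summaries = summarize_regions(alignments, manifest, min_mapq_exclusive)
    ratios = normalize_regions(summaries)
    cutoffs = dynamic_cutoff(ratios, cnv.expected_type, sd_multiplier)
    confirmed = confirm(ratios, cutoffs, cnv.expected_type)
    context = resolve_context(
        cnv.region.chrom, cnv.region.start, cnv.region.end, cnv.sample_sex,
        par_intervals,
    )
    copies = estimate_copy_number(ratios.cnv_ratio, context)
    return ConfirmationResult(cnv, ratios, cutoffs, confirmed, copies, context)


@dataclass
class DownsampleReport:
    target_depths: list[float]
    replicates_per_depth: int
    confirmations: dict[float, int]
    realized_depths: dict[float, list[float]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "target_depth": self.target_depths,
            "confirmed": [self.confirmations[d] for d in self.target_depths],
            "replicates": self.replicates_per_depth,
            "mean_realized_control_depth": [
                float(np.mean(self.realized_depths[d])) if self.realized_depths[d]
                else float("nan")
                for d in self.target_depths
            ],
        })


def downsample_titration(
    alignments: str | Path,
    manifest: list[Region],
    cnv: CNVHypothesis,
    target_depths: list[float],
    reps: int = 10,
    seed: int = 0,
    sd_multiplier: float = SD_MULTIPLIER_DEFAULT,
) -> DownsampleReport:
    """Coverage titration: repeatedly thin the BAM to target mean control
    depths (whole-read Bernoulli retention) and rerun confirmation.

    Replicate j at depth index i uses RNG seed ``seed + i*reps + j``. Target
    depths above the available control depth are skipped with a warning.
    """
    controls = [r for r in manifest if r.role == "control"]
    full_summaries = summarize_regions(alignments, controls)
    full_mean = float(np.mean([s.mean_depth for s in full_summaries]))
    confirmations: dict[float, int] = {}
    realized: dict[float, list[float]] = {}
    kept_depths: list[float] = []
    for i, target in enumerate(target_depths):
        if target > full_mean:
            log.warning("target depth %.2fX exceeds available %.2fX; skipping",
                        target, full_mean)
            continue
        kept_depths.append(target)
        confirmations[target] = 0
        realized[target] = []
        p = target / full_mean
        for j in range(reps):
            rng = np.random.default_rng(seed + i * reps + j)
            with tempfile.TemporaryDirectory() as tmp:
                sub = Path(tmp) / "subsampled.bam"
                _bernoulli_thin(alignments, sub, p, rng)
                result = run_confirmation(sub, manifest, cnv, sd_multiplier)
                if result.confirmed:
                    confirmations[target] += 1
                realized[target].append(result.ratios.normalizer)
    return DownsampleReport(kept_depths, reps, confirmations, realized)


def _bernoulli_thin(
    src: str | Path, dst: Path, keep_prob: float, rng: np.random.Generator
) -> None:
    """Retain each read independently with probability ``keep_prob``;
    coordinate order is preserved, so only indexing is needed afterwards."""
    with pysam.AlignmentFile(str(src)) as bam_in:
        with pysam.AlignmentFile(str(dst), "wb", template=bam_in) as bam_out:
            for read in bam_in.fetch():
                if rng.random() < keep_prob:
                    bam_out.write(read)
    pysam.index(str(dst))
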