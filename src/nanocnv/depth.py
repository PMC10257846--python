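"""Per-base read depth with mapping-quality filtering, and region summaries.

Depth semantics follow the usual per-base conventions: only primary alignments
count; reads with MAPQ strictly greater than the exclusive threshold (default
0, i.e. MAPQ-0 reads are dropped) contribute one unit at every reference
position covered by an aligned block, so deletions within a read and
soft-clipped bases add nothing. Positions with no coverage report 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .regions import Region

__all__ = [
    "DepthProfile",
    "RegionDepthSummary",
    "WindowedDepth",
    "compute_depth",
    "summarize_region",
    "summarize_regions",
    "window_depth",
    "enrichment_qc",
]


@dataclass
class DepthProfile:
    region: Region
    per_base_depth: np.ndarray  # int array, one entry per region position

    def __post_init__(self) -> None:
        self.per_base_depth = np.asarray(self.per_base_depth)
        if len(self.per_base_depth) != self.region.length:
            raise ValueError("profile length does not match region length")


@dataclass(frozen=True)
class RegionDepthSummary:
    region: Region
    mean_depth: float
    n_positions: int


@dataclass
class WindowedDepth:
    region: Region
    window_means: np.ndarray
    window_sizes: np.ndarray
    window_size: int


def _open_indexed(alignments: str | Path | pysam.AlignmentFile) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, False
    bam = pysam.AlignmentFile(str(alignments))
    return bam, True


def compute_depth(
    alignments: str | Path | pysam.AlignmentFile,
    region: Region,
    min_mapq_exclusive: int = 0,
) -> DepthProfile:
    """Per-base depth over ``region`` counting reads with MAPQ > threshold.

    Secondary and supplementary alignments are excluded; duplicates (unmarked
    upstream) are counted. Raises a clear error when the BAM index is missing
    or the region's chromosome is absent from the header.
    """
    bam, owned = _open_indexed(alignments)
    try:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{bam.filename.decode() if bam.filename else 'BAM'} has no "
                "index; run `samtools index` (or pysam.index) first"
            )
        if region.chrom not in bam.references:
            raise ValueError(f"chromosome {region.chrom!r} not in BAM header")
        depth = np.zeros(region.length, dtype=np.int64)
        for read in bam.fetch(region.chrom, region.start, region.end):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality <= min_mapq_exclusive:
                continue
            for bstart, bend in read.get_blocks():
                s = max(bstart, region.start) - region.start
                e = min(bend, region.end) - region.start
                if e > s:
                    depth[s:e] += 1
        return DepthProfile(region, depth)
    finally:
        if owned:
            bam.close()


def summarize_region(profile: DepthProfile) -> RegionDepthSummary:
    """Mean depth over the region (zero-length regions are rejected upstream)."""
    n = profile.region.length
    return RegionDepthSummary(profile.region, float(profile.per_base_depth.sum()) / n, n)


def summarize_regions(
    alignments: str | Path | pysam.AlignmentFile,
    regions: list[Region],
    min_mapq_exclusive: int = 0,
) -> list[RegionDepthSummary]:
    bam, owned = _open_indexed(alignments)
    try:
        return [
            summarize_region(compute_depth(bam, r, min_mapq_exclusive))
            for r in regions
        ]
    finally:
        if owned:
            bam.close()


def window_depth(profile: DepthProfile, window_fraction: float = 0.01) -> WindowedDepth:
    """Mean depth in non-overlapping windows sized a fixed fraction (default
    1%) of the region; the final window absorbs any remainder so the
    length-weighted mean of window means equals the region mean exactly."""
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    length = profile.region.length
    size = int(length * window_fraction)
    if size < 1:
        raise ValueError("window size below 1 bp; region too short for fraction")
    n_windows = length // size
    bounds = [i * size for i in range(n_windows)] + [length]
    means = np.array([
        profile.per_base_depth[bounds[i]:bounds[i + 1]].mean()
        for i in range(n_windows)
    ])
    sizes = np.diff(bounds)
    return WindowedDepth(profile.region, means, sizes, size)


def enrichment_qc(on_target_mean: float, genome_wide_mean: float) -> float:
    """Fold enrichment of adaptive sampling: on-target over genome-wide mean
    depth, reported to one decimal (e.g. 9.5X / 1.13X -> 8.4)."""
    if genome_wide_mean <= 0:
        raise ValueError("genome-wide mean depth must be positive")
    return round(on_target_mean / genome_wide_mean, 1)
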