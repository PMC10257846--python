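"""Cross-platform sample identity via homozygous SNV genotype concordance.

Candidate biallelic SNVs with population allele frequencies near 0.5 (band
[0.4, 0.6], maximizing inter-individual variability) are selected inside the
control regions, genotyped from pileup allele counts in both short- and
long-read alignments, and compared region by region. Only loci homozygous in
both datasets enter the comparison; a match region passes when more than 90%
of shared genotypes agree. Two nearby control regions may be merged into one
match region to avoid double-counting linked loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .regions import Region

log = logging.getLogger(__name__)

__all__ = [
    "SNVLocus",
    "GenotypeCall",
    "GenotypePanel",
    "MatchResult",
    "select_loci",
    "allele_counts",
    "call_genotype",
    "build_panel",
    "match_region",
    "match_panels",
    "match_matrix",
]

AF_BAND = (0.4, 0.6)
LOCI_PER_REGION = 150
HOM_FRACTION = 0.95
MIN_DEPTH = {"short_read": 10, "long_read": 1}
MATCH_THRESHOLD = 0.90
BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SNVLocus:
    """A candidate fingerprinting SNV; ``pos`` is stored 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    population_af: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class GenotypeCall:
    locus: SNVLocus
    depth: int
    ref_count: int
    alt_count: int
    call: str  # hom_ref | hom_alt | other | no_call


@dataclass
class GenotypePanel:
    """Per-sample genotype calls grouped into identity match regions."""

    sample: str
    platform: str  # short_read | long_read
    calls: dict[str, list[GenotypeCall]] = field(default_factory=dict)

    @property
    def region_names(self) -> list[str]:
        return list(self.calls)


@dataclass
class MatchResult:
    proportions: dict[str, float | None]  # None = no shared homozygous loci
    matched: dict[str, bool | None]
    shared_counts: dict[str, int]

    @property
    def fraction_regions_matched(self) -> float:
        """Fraction of match regions agreeing (no-data regions count against)."""
        if not self.matched:
            return 0.0
        return sum(1 for v in self.matched.values() if v) / len(self.matched)

    @property
    def overall_matched(self) -> bool:
        """Identity confirmed only when every match region agrees."""
        return bool(self.matched) and all(v is True for v in self.matched.values())


def load_af_table(path: str | Path) -> pd.DataFrame:
    """Read a gnomAD-style candidate table (chrom, pos [1-based], ref, alt,
    AF) from TSV; positions are converted to 0-based here."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower().lstrip("#") for c in df.columns]
    df = df.rename(columns={"chr": "chrom", "position": "pos", "af": "af"})
    df["pos"] = df["pos"].astype(int) - 1
    return df[["chrom", "pos", "ref", "alt", "af"]]


def select_loci(
    candidates: pd.DataFrame,
    control_regions: list[Region],
    af_band: tuple[float, float] = AF_BAND,
    max_per_region: int = LOCI_PER_REGION,
) -> dict[str, list[SNVLocus]]:
    """Up to ``max_per_region`` biallelic SNVs per control region with AF in
    the closed band, deterministically the first by ascending position.

    ``candidates`` columns: chrom, pos (0-based), ref, alt, af. Regions with
    no qualifying locus are excluded with a warning.
    """
    out: dict[str, list[SNVLocus]] = {}
    for region in control_regions:
        sub = candidates[
            (candidates["chrom"] == region.chrom)
            & (candidates["pos"] >= region.start)
            & (candidates["pos"] < region.end)
            & (candidates["af"] >= af_band[0])
            & (candidates["af"] <= af_band[1])
            & candidates["ref"].isin(BASES)
            & candidates["alt"].isin(BASES)
        ].sort_values("pos").head(max_per_region)
        if sub.empty:
            log.warning("control region %s has no qualifying SNVs; excluded "
                        "from identity matching", region.label or str(region))
            continue
        out[region.label or str(region)] = [
            SNVLocus(r.chrom, int(r.pos), r.ref, r.alt, float(r.af))
            for r in sub.itertuples()
        ]
    return out


def query_position(read: pysam.AlignedSegment, refpos: int) -> int | None:
    """Query offset aligned to ``refpos``, or None when the read skips or
    deletes that reference position. Cheap CIGAR walk instead of
    materializing all aligned pairs."""
    qpos, rpos = 0, read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M / = / X consume both
            if rpos <= refpos < rpos + length:
                return qpos + (refpos - rpos)
            qpos += length
            rpos += length
        elif op in (1, 4):  # I / S consume query only
            qpos += length
        elif op in (2, 3):  # D / N consume reference only
            if rpos <= refpos < rpos + length:
                return None
            rpos += length
    return None


def allele_counts(
    bam: pysam.AlignmentFile, locus: SNVLocus, min_mapq_exclusive: int = 0
) -> tuple[int, int, int]:
    """(depth, ref_count, alt_count) at the locus from primary reads with
    MAPQ above the exclusive threshold; depth counts any aligned base."""
    depth = ref_n = alt_n = 0
    for read in bam.fetch(locus.chrom, locus.pos, locus.pos + 1):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality <= min_mapq_exclusive:
            continue
        qpos = query_position(read, locus.pos)
        if qpos is None:
            continue
        base = read.query_sequence[qpos].upper()
        depth += 1
        if base == locus.ref:
            ref_n += 1
        elif base == locus.alt:
            alt_n += 1
    return depth, ref_n, alt_n


def call_genotype(
    locus: SNVLocus,
    depth: int,
    ref_count: int,
    alt_count: int,
    platform: str,
    min_depth: dict[str, int] | None = None,
    hom_fraction: float = HOM_FRACTION,
) -> GenotypeCall:
    """Homozygosity call from allele counts.

    ``no_call`` below the platform depth minimum (10 short-read / 1
    long-read); ``hom_ref``/``hom_alt`` when the allele fraction strictly
    exceeds ``hom_fraction`` (0.95); anything else is ``other`` and excluded
    from matching.
    """
    minima = MIN_DEPTH if min_depth is None else min_depth
    if depth < minima[platform]:
        call = "no_call"
    elif ref_count / depth > hom_fraction:
        call = "hom_ref"
    elif alt_count / depth > hom_fraction:
        call = "hom_alt"
    else:
        call = "other"
    return GenotypeCall(locus, depth, ref_count, alt_count, call)


def build_panel(
    alignments: str | Path,
    loci_by_region: dict[str, list[SNVLocus]],
    sample: str,
    platform: str,
    merge_groups: dict[str, str] | None = None,
    min_mapq_exclusive: int = 0,
    min_depth: dict[str, int] | None = None,
) -> GenotypePanel:
    """Genotype every selected locus and group calls into match regions,
    merging control regions that share a merge group."""
    merge_groups = merge_groups or {}
    panel = GenotypePanel(sample, platform)
    with pysam.AlignmentFile(str(alignments)) as bam:
        for region_name, loci in loci_by_region.items():
            key = merge_groups.get(region_name, region_name)
            bucket = panel.calls.setdefault(key, [])
            for locus in loci:
                d, r, a = allele_counts(bam, locus, min_mapq_exclusive)
                bucket.append(call_genotype(locus, d, r, a, platform, min_depth))
    return panel


def match_region(
    calls_a: list[GenotypeCall],
    calls_b: list[GenotypeCall],
    threshold: float = MATCH_THRESHOLD,
) -> tuple[float | None, bool | None, int]:
    """Compare two samples over one match region.

    Restricted to loci homozygous in both panels; returns (proportion
    identical, matched at > threshold, number of shared homozygous loci).
    With zero shared loci the result is no-data (None, None, 0).
    """
    hom = {"hom_ref", "hom_alt"}
    b_by_locus = {c.locus: c for c in calls_b}
    shared = [
        (c.call, b_by_locus[c.locus].call)
        for c in calls_a
        if c.call in hom
        and c.locus in b_by_locus
        and b_by_locus[c.locus].call in hom
    ]
    if not shared:
        return None, None, 0
    prop = sum(1 for x, y in shared if x == y) / len(shared)
    return prop, prop > threshold, len(shared)


def match_panels(
    panel_a: GenotypePanel, panel_b: GenotypePanel, threshold: float = MATCH_THRESHOLD
) -> MatchResult:
    regions = [r for r in panel_a.region_names if r in panel_b.calls]
    proportions: dict[str, float | None] = {}
    matched: dict[str, bool | None] = {}
    counts: dict[str, int] = {}
    for name in regions:
        p, m, n = match_region(panel_a.calls[name], panel_b.calls[name], threshold)
        proportions[name], matched[name], counts[name] = p, m, n
    return MatchResult(proportions, matched, counts)


def match_matrix(
    panels: list[GenotypePanel], threshold: float = MATCH_THRESHOLD
) -> pd.DataFrame:
    """Symmetric matrix of the fraction of match regions agreeing per pair
    of panels (values in {0, 0.25, 0.5, 0.75, 1} with four match regions)."""
    if len(panels) < 2:
        raise ValueError("need at least two panels")
    names = [f"{p.sample}:{p.platform}" for p in panels]
    mat = np.ones((len(panels), len(panels)))
    for i in range(len(panels)):
        for j in range(i + 1, len(panels)):
            frac = match_panels(panels[i], panels[j], threshold).fraction_regions_matched
            mat[i, j] = mat[j, i] = frac
    return pd.DataFrame(mat, index=names, columns=names)
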