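"""Haplotype-resolved CpG methylation at an imprinted locus.

Long reads intersecting an imprinted promoter CpG island (default: the SNRPN
promoter island, methylated only on the maternal allele) are assigned to a
haplotype from the base they carry at a nearby heterozygous SNV, and their
per-read 5mC status is summarized per haplotype. Methylation calls are
consumed from standard MM/ML base-modification tags, so any basecaller (or
the built-in simulator) that writes those tags interoperates.

The module reports haplotype labels only; which haplotype is maternal is an
interpretation left to the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .identity import query_position
from .regions import Region

log = logging.getLogger(__name__)

__all__ = [
    "PhasingSNV",
    "HaplotypedRead",
    "MethylationSummary",
    "SNRPN_PHASING_SNV",
    "SNRPN_CPG_ISLAND",
    "assign_haplotype",
    "island_cpg_probs",
    "classify_read_methylation",
    "phase_island_reads",
    "summarize",
]


@dataclass(frozen=True)
class PhasingSNV:
    """A heterozygous SNV used to split reads into haplotypes.

    ``pos`` is 0-based. Reads carrying ``allele_a`` go to hap1, ``allele_b``
    to hap2; anything else (no coverage, third allele, deletion) stays
    unassigned.
    """

    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b or not (
            len(self.allele_a) == len(self.allele_b) == 1
        ):
            raise ValueError("phasing alleles must be distinct single bases")


# GRCh37 defaults for the SNRPN promoter locus: the phasing SNV
# chr15:25,199,992 C/G (1-based) and the promoter CpG island
# chr15:25,200,035-25,201,054 (1-based inclusive), stored 0-based half-open.
SNRPN_PHASING_SNV = PhasingSNV("chr15", 25_199_991, "C", "G")
SNRPN_CPG_ISLAND = Region("chr15", 25_200_034, 25_201_054, "control", "SNRPN_CpG_island")


@dataclass
class HaplotypedRead:
    read_id: str
    haplotype: str  # hap1 | hap2 | unassigned
    cpg_calls: list[tuple[int, float]]  # (reference position, P(5mC))
    read_methylated: bool | None  # None when no island CpG calls


@dataclass
class MethylationSummary:
    read_counts: dict[str, int] = field(default_factory=dict)
    methylated_counts: dict[str, int] = field(default_factory=dict)
    excluded_no_calls: int = 0

    def fraction_methylated(self, haplotype: str) -> float | None:
        n = self.read_counts.get(haplotype, 0)
        if n == 0:
            return None
        return self.methylated_counts.get(haplotype, 0) / n


def assign_haplotype(read: pysam.AlignedSegment, snv: PhasingSNV) -> str:
    """hap1/hap2 from the read's base at the phasing SNV, else unassigned."""
    if read.reference_name != snv.chrom:
        return "unassigned"
    qpos = query_position(read, snv.pos)
    if qpos is None:
        return "unassigned"
    base = read.query_sequence[qpos].upper()
    if base == snv.allele_a:
        return "hap1"
    if base == snv.allele_b:
        return "hap2"
    return "unassigned"


def island_cpg_probs(read: pysam.AlignedSegment, island: Region) -> list[tuple[int, float]]:
    """Per-CpG 5mC probabilities inside the island, from the read's MM/ML
    tags, as (reference position, probability) pairs.

    ML stores the probability bin floor(p*256); the bin midpoint (ml+0.5)/256
    is returned. Only calls at reference-aligned positions count.
    """
    mods = read.modified_bases
    if not mods:
        return []
    qpos_to_ref = {
        q: r for q, r in read.get_aligned_pairs(matches_only=True)
    }
    out: list[tuple[int, float]] = []
    for (base, _strand, mod), calls in mods.items():
        if base != "C" or mod != "m":
            continue
        for qpos, ml in calls:
            rpos = qpos_to_ref.get(qpos)
            if rpos is not None and island.start <= rpos < island.end:
                out.append((rpos, (ml + 0.5) / 256.0))
    out.sort()
    return out


def classify_read_methylation(
    cpg_calls: list[tuple[int, float]],
    prob_threshold: float = 0.5,
    fraction_threshold: float = 0.5,
) -> bool:
    """A read is methylated when the fraction of its island CpG sites with
    P(5mC) >= ``prob_threshold`` exceeds ``fraction_threshold``."""
    if not cpg_calls:
        raise ValueError("read has no CpG calls in the island")
    modified = sum(1 for _, p in cpg_calls if p >= prob_threshold)
    return modified / len(cpg_calls) > fraction_threshold


def phase_island_reads(
    alignments: str | Path,
    snv: PhasingSNV = SNRPN_PHASING_SNV,
    island: Region = SNRPN_CPG_ISLAND,
    prob_threshold: float = 0.5,
    fraction_threshold: float = 0.5,
    min_mapq_exclusive: int = 0,
) -> list[HaplotypedRead]:
    """Haplotype and classify every primary read intersecting the island."""
    out: list[HaplotypedRead] = []
    with pysam.AlignmentFile(str(alignments)) as bam:
        for read in bam.fetch(island.chrom, island.start, island.end):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality <= min_mapq_exclusive:
                continue
            hap = assign_haplotype(read, snv)
            calls = island_cpg_probs(read, island)
            if calls:
                methylated = classify_read_methylation(
                    calls, prob_threshold, fraction_threshold
                )
            else:
                log.warning("read %s has no CpG calls in the island; excluded",
                            read.query_name)
                methylated = None
            out.append(HaplotypedRead(read.query_name, hap, calls, methylated))
    return out


def summarize(reads: list[HaplotypedRead]) -> MethylationSummary:
    """Per-haplotype read and methylated-read counts; reads without island
    CpG calls are tallied as excluded."""
    summary = MethylationSummary(
        read_counts={"hap1": 0, "hap2": 0, "unassigned": 0},
        methylated_counts={"hap1": 0, "hap2": 0, "unassigned": 0},
    )
    for read in reads:
        if read.read_methylated is None:
            summary.excluded_no_calls += 1
            continue
        summary.read_counts[read.haplotype] += 1
        if read.read_methylated:
            summary.methylated_counts[read.haplotype] += 1
    return summary
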