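"""Synthetic aligned-read generator with adaptive-sampling structure.

Emits coordinate-sorted, indexed BAMs (plus truth manifests and optional
reference FASTA) that emulate the coverage structure of a targeted
adaptive-sampling run: long reads (mean 4,805 bp) at high depth (9.5X for two
copies) inside target regions, short rejected reads (mean 603 bp) at low
genome-wide depth (1.13X) elsewhere. Read starts follow a Poisson process
whose local rate scales with copy number — rate(x) = on-target depth x
copies(x)/2 / mean read length on diploid chromosomes, and copies(x)/1 on
male non-PAR sex chromosomes so that the depth-ratio ladder steps by 1 per
copy there, matching the confirmation model. Read lengths are exponential
(memoryless fragment model) truncated at chromosome ends.

Optionally injects SNV genotypes into read sequences (het alleles tied to a
simulated haplotype), per-read CpG 5mC MM/ML tags over a designated island,
a configurable fraction of MAPQ-0 reads, and uniform substitution errors.
"""

from __future__ import annotations

import array
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam

from .identity import SNVLocus
from .methylation import PhasingSNV, SNRPN_CPG_ISLAND, SNRPN_PHASING_SNV
from .regions import GenomeBuild, Region

__all__ = [
    "CopySegment",
    "SimulatedGenotype",
    "MethylationProfile",
    "SimulatedSampleSpec",
    "SimulationOutput",
    "simulate_reads",
    "make_validation_cohort",
    "make_imprinting_fixture",
    "draw_snv_candidates",
    "reference_window",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_REF_BLOCK = 1 << 20

ON_TARGET_DEPTH_DEFAULT = 9.5
OFF_TARGET_DEPTH_DEFAULT = 1.13
ON_TARGET_READ_LEN_DEFAULT = 4805.0
OFF_TARGET_READ_LEN_DEFAULT = 603.0


def reference_window(
    chrom: str, start: int, end: int, reference_seed: int = 0
) -> np.ndarray:
    """Deterministic random reference sequence for [start, end) as a uint8
    array of ASCII bases. Random-access: generated in fixed 1-Mb blocks each
    seeded by (reference_seed, chrom, block index), so any window can be
    reproduced without materializing the chromosome."""
    out = np.empty(end - start, dtype=np.uint8)
    chrom_key = zlib.crc32(chrom.encode())
    b0, b1 = start // _REF_BLOCK, (end - 1) // _REF_BLOCK
    for block in range(b0, b1 + 1):
        data = _ref_block(reference_seed, chrom_key, block)
        lo = max(start, block * _REF_BLOCK)
        hi = min(end, (block + 1) * _REF_BLOCK)
        out[lo - start:hi - start] = data[lo - block * _REF_BLOCK:hi - block * _REF_BLOCK]
    return out


@lru_cache(maxsize=32)
def _ref_block(reference_seed: int, chrom_key: int, block: int) -> np.ndarray:
    rng = np.random.default_rng([reference_seed, chrom_key, block])
    return _BASES[rng.integers(0, 4, _REF_BLOCK)]


@dataclass(frozen=True)
class CopySegment:
    region: Region
    copies: int
    haplotype: int | None = None  # pin all reads of this segment to one hap

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass(frozen=True)
class SimulatedGenotype:
    locus: SNVLocus
    genotype: str  # "0/0" | "0/1" | "1/1"
    alt_hap: int = 1  # haplotype carrying the alt allele for hets


@dataclass
class MethylationProfile:
    """Per-haplotype per-site 5mC probability over one CpG island."""

    island: Region = SNRPN_CPG_ISLAND
    snv: PhasingSNV = SNRPN_PHASING_SNV
    site_mod_prob: dict[str, float] = field(
        default_factory=lambda: {"hap1": 0.95, "hap2": 0.05}
    )


@dataclass
class SimulatedSampleSpec:
    """Full generative description of one simulated sample."""

    genome: GenomeBuild
    target_regions: list[Region]
    copy_number_map: list[CopySegment] = field(default_factory=list)
    diploid_mean_depth: float = ON_TARGET_DEPTH_DEFAULT
    off_target_mean_depth: float = OFF_TARGET_DEPTH_DEFAULT
    on_target_read_length_mean: float = ON_TARGET_READ_LEN_DEFAULT
    off_target_read_length_mean: float = OFF_TARGET_READ_LEN_DEFAULT
    haploid_chroms: frozenset = frozenset()  # male non-PAR sex chromosomes
    snv_genotypes: list[SimulatedGenotype] = field(default_factory=list)
    methylation: MethylationProfile | None = None
    mapq0_fraction: float = 0.0
    error_rate: float = 0.0
    write_sequences: bool = True
    reference_seed: int = 0
    seed: int = 0

    def validate(self) -> None:
        for r in self.target_regions:
            self.genome.validate_region(r)
        for seg in self.copy_number_map:
            self.genome.validate_region(seg.region)
        for g in self.snv_genotypes:
            if g.locus.chrom not in self.genome or not (
                0 <= g.locus.pos < self.genome.length(g.locus.chrom)
            ):
                raise ValueError(f"SNV locus {g.locus} outside genome")
        if self.methylation is not None:
            self.genome.validate_region(self.methylation.island)
            snv = self.methylation.snv
            if snv.chrom not in self.genome or not (
                0 <= snv.pos < self.genome.length(snv.chrom)
            ):
                raise ValueError("phasing SNV outside genome")
        if self.methylation is not None and not self.write_sequences:
            raise ValueError("methylation tags require write_sequences=True")


@dataclass
class _Read:
    chrom: str
    start: int
    end: int
    mapq: int
    hap: int
    seq: bytes | None = None
    mm: str | None = None
    ml: list[int] | None = None


@dataclass
class SimulationOutput:
    bam: Path
    fasta: Path | None
    truth_regions: "object"  # pandas DataFrame
    truth_loci: "object"  # pandas DataFrame
    spec: SimulatedSampleSpec


def _segments(spec: SimulatedSampleSpec, chrom: str):
    """Elementary (start, end, on_target, copies, haplotype) intervals."""
    length = spec.genome.length(chrom)
    cuts = {0, length}
    targets = [r for r in spec.target_regions if r.chrom == chrom]
    copy_segs = [s for s in spec.copy_number_map if s.region.chrom == chrom]
    for r in targets:
        cuts.update((r.start, r.end))
    for s in copy_segs:
        cuts.update((s.region.start, s.region.end))
    edges = sorted(cuts)
    default_copies = 1 if chrom in spec.haploid_chroms else 2
    for a, b in zip(edges, edges[1:]):
        mid = (a + b) // 2
        on_target = any(r.start <= mid < r.end for r in targets)
        copies, hap = default_copies, None
        for s in copy_segs:
            if s.region.start <= mid < s.region.end:
                copies, hap = s.copies, s.haplotype
                break
        yield a, b, on_target, copies, hap


def _draw_reads(spec: SimulatedSampleSpec, rng: np.random.Generator) -> list[_Read]:
    reads: list[_Read] = []
    for chrom in spec.genome.chrom_names:
        chrom_len = spec.genome.length(chrom)
        base = 1.0 if chrom in spec.haploid_chroms else 2.0
        for a, b, on_target, copies, hap in _segments(spec, chrom):
            depth = spec.diploid_mean_depth if on_target else spec.off_target_mean_depth
            mean_len = (
                spec.on_target_read_length_mean if on_target
                else spec.off_target_read_length_mean
            )
            rate = depth * copies / base / mean_len
            if rate <= 0:
                continue
            n = rng.poisson(rate * (b - a))
            if n == 0:
                continue
            starts = rng.integers(a, b, n)
            lengths = np.maximum(1, rng.exponential(mean_len, n).astype(np.int64))
            ends = np.minimum(starts + lengths, chrom_len)
            mapq0 = (
                rng.random(n) < spec.mapq0_fraction
                if spec.mapq0_fraction > 0 else np.zeros(n, bool)
            )
            haps = (
                np.full(n, hap) if hap is not None else rng.integers(1, 3, n)
            )
            for i in range(n):
                reads.append(_Read(chrom, int(starts[i]), int(ends[i]),
                                   0 if mapq0[i] else 60, int(haps[i])))
    return reads


def _attach_sequences(
    spec: SimulatedSampleSpec, reads: list[_Read], rng: np.random.Generator,
    locus_counts: dict,
) -> None:
    genotypes_by_chrom: dict[str, list[SimulatedGenotype]] = {}
    for g in spec.snv_genotypes:
        genotypes_by_chrom.setdefault(g.locus.chrom, []).append(g)
    meth = spec.methylation
    for read in reads:
        seq = reference_window(read.chrom, read.start, read.end,
                               spec.reference_seed).copy()
        for g in genotypes_by_chrom.get(read.chrom, ()):
            pos = g.locus.pos
            if not read.start <= pos < read.end:
                continue
            if g.genotype == "0/0":
                allele = g.locus.ref
            elif g.genotype == "1/1":
                allele = g.locus.alt
            else:  # het: alt rides the designated haplotype
                allele = g.locus.alt if read.hap == g.alt_hap else g.locus.ref
            seq[pos - read.start] = ord(allele)
            if read.mapq > 0:
                counts = locus_counts.setdefault(g.locus, {"ref": 0, "alt": 0, "depth": 0})
                counts["depth"] += 1
                counts["ref" if allele == g.locus.ref else "alt"] += 1
        if meth is not None and read.chrom == meth.snv.chrom:
            if read.start <= meth.snv.pos < read.end:
                allele = meth.snv.allele_a if read.hap == 1 else meth.snv.allele_b
                seq[meth.snv.pos - read.start] = ord(allele)
        if spec.error_rate > 0:
            n_err = rng.binomial(len(seq), spec.error_rate)
            if n_err:
                idx = rng.integers(0, len(seq), n_err)
                shifts = rng.integers(1, 4, n_err)
                cur = np.searchsorted(_BASES, seq[idx])  # bases are sorted ACGT
                seq[idx] = _BASES[(cur + shifts) % 4]
        if meth is not None and read.chrom == meth.island.chrom:
            if read.start < meth.island.end and read.end > meth.island.start:
                _attach_methylation(meth, read, seq, rng)
        read.seq = seq.tobytes()


def _attach_methylation(
    meth: MethylationProfile, read: _Read, seq: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Write MM/ML 5mC calls for the read's island CpG cytosines.

    MM deltas count skipped C's in the read sequence (C+m? skip semantics);
    ML holds the probability bin floor(p*256)."""
    is_c = seq == ord("C")
    cpg = np.flatnonzero(is_c[:-1] & (seq[1:] == ord("G")))
    ref_pos = cpg + read.start
    in_island = (ref_pos >= meth.island.start) & (ref_pos < meth.island.end)
    sites = cpg[in_island]
    if len(sites) == 0:
        return
    p_mod = meth.site_mod_prob.get(f"hap{read.hap}", 0.0)
    modified = rng.random(len(sites)) < p_mod
    ml = np.where(
        modified,
        rng.integers(205, 256, len(sites)),
        rng.integers(0, 51, len(sites)),
    )
    c_positions = np.flatnonzero(is_c)
    c_rank = np.searchsorted(c_positions, sites)
    deltas = np.diff(np.concatenate([[-1], c_rank])) - 1
    read.mm = "C+m?," + ",".join(str(d) for d in deltas) + ";"
    read.ml = [int(v) for v in ml]


def _write_bam(
    spec: SimulatedSampleSpec, reads: list[_Read], bam_path: Path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": spec.genome.length(name)}
            for name in spec.genome.chrom_names
        ],
    }
    tid = {name: i for i, name in enumerate(spec.genome.chrom_names)}
    reads.sort(key=lambda r: (tid[r.chrom], r.start, r.end))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for i, read in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"sim{i:07d}"
            a.flag = 0
            a.reference_id = tid[read.chrom]
            a.reference_start = read.start
            a.mapping_quality = read.mapq
            a.cigartuples = [(0, read.end - read.start)]
            if read.seq is not None:
                a.query_sequence = read.seq.decode()
            a.set_tag("HP", read.hap, "i")
            if read.mm is not None:
                a.set_tag("MM", read.mm, "Z")
                a.set_tag("ML", array.array("B", read.ml))
            bam.write(a)
    pysam.index(str(bam_path))


def _truth_tables(spec: SimulatedSampleSpec, reads: list[_Read], locus_counts: dict):
    import pandas as pd

    regions: list[Region] = list(spec.target_regions)
    seen = {(r.chrom, r.start, r.end) for r in regions}
    for seg in spec.copy_number_map:
        key = (seg.region.chrom, seg.region.start, seg.region.end)
        if key not in seen:
            regions.append(seg.region)
            seen.add(key)
    copies_of = {
        (s.region.chrom, s.region.start, s.region.end): s.copies
        for s in spec.copy_number_map
    }
    by_chrom: dict[str, list[_Read]] = {}
    for read in reads:
        if read.mapq > 0:
            by_chrom.setdefault(read.chrom, []).append(read)
    rows = []
    for r in regions:
        cov = np.zeros(r.length, dtype=np.int64)
        for read in by_chrom.get(r.chrom, ()):
            s = max(read.start, r.start) - r.start
            e = min(read.end, r.end) - r.start
            if e > s:
                cov[s:e] += 1
        default = 1 if r.chrom in spec.haploid_chroms else 2
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "role": r.role, "label": r.label,
            "copies": copies_of.get((r.chrom, r.start, r.end), default),
            "realized_mean_depth": float(cov.mean()),
        })
    truth_regions = pd.DataFrame(rows)
    loci_rows = [
        {
            "chrom": g.locus.chrom, "pos": g.locus.pos, "ref": g.locus.ref,
            "alt": g.locus.alt, "genotype": g.genotype,
            "depth": locus_counts.get(g.locus, {}).get("depth", 0),
            "ref_count": locus_counts.get(g.locus, {}).get("ref", 0),
            "alt_count": locus_counts.get(g.locus, {}).get("alt", 0),
        }
        for g in spec.snv_genotypes
    ]
    truth_loci = pd.DataFrame(
        loci_rows,
        columns=["chrom", "pos", "ref", "alt", "genotype", "depth",
                 "ref_count", "alt_count"],
    )
    return truth_regions, truth_loci


def simulate_reads(
    spec: SimulatedSampleSpec,
    out_dir: str | Path,
    name: str = "sample",
    write_reference: bool = False,
) -> SimulationOutput:
    """Generate the BAM (+ index), truth manifest TSVs, and optionally the
    reference FASTA for one simulated sample. Fully determined by the spec's
    seeds."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    reads = _draw_reads(spec, rng)
    locus_counts: dict = {}
    if spec.write_sequences:
        _attach_sequences(spec, reads, rng, locus_counts)
    bam_path = out_dir / f"{name}.bam"
    _write_bam(spec, reads, bam_path)
    truth_regions, truth_loci = _truth_tables(spec, reads, locus_counts)
    truth_regions.to_csv(out_dir / f"{name}.truth_regions.tsv", sep="\t", index=False)
    truth_loci.to_csv(out_dir / f"{name}.truth_loci.tsv", sep="\t", index=False)
    fasta_path = None
    if write_reference:
        fasta_path = out_dir / f"{name}.ref.fa"
        with open(fasta_path, "w") as fh:
            for chrom in spec.genome.chrom_names:
                fh.write(f">{chrom}\n")
                length = spec.genome.length(chrom)
                for s in range(0, length, 80):
                    window = reference_window(
                        chrom, s, min(s + 80, length), spec.reference_seed
                    )
                    fh.write(window.tobytes().decode() + "\n")
        pysam.faidx(str(fasta_path))
    return SimulationOutput(bam_path, fasta_path, truth_regions, truth_loci, spec)


def draw_snv_candidates(
    regions: Iterable[Region],
    n_per_region: int,
    seed: int,
    reference_seed: int = 0,
    af_range: tuple[float, float] = (0.3, 0.7),
):
    """Random candidate SNV table (gnomAD-style columns, 0-based pos) inside
    the given regions; ref alleles agree with the simulated reference."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        n_pick = min(n_per_region, region.length)
        positions = np.sort(
            rng.choice(region.length, size=n_pick, replace=False)
        ) + region.start
        for pos in positions:
            ref = chr(reference_window(region.chrom, pos, pos + 1, reference_seed)[0])
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append({
                "chrom": region.chrom, "pos": int(pos), "ref": ref,
                "alt": str(alt), "af": float(rng.uniform(*af_range)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort construction (scaled-down validation-study emulation)
# ---------------------------------------------------------------------------

@dataclass
class CohortSample:
    name: str
    spec: SimulatedSampleSpec
    expected_type: str  # hypothesized CNV type
    true_copies: int
    is_copy_neutral: bool
    cnv_region: Region
    control_regions: list[Region]
    pad_regions: list[Region]

    @property
    def manifest(self) -> list[Region]:
        return [*self.control_regions, *self.pad_regions, self.cnv_region]


def _standard_layout(cnv_size: int, pad_size: int = 500_000):
    """Controls on chr1 (five 500-kb regions), CNV + pads on chr2."""
    controls = [
        Region("chr1", 100_000 + i * 600_000, 600_000 + i * 600_000,
               "control", f"ctrl{i + 1}")
        for i in range(5)
    ]
    cnv_start = 100_000 + pad_size
    cnv = Region("chr2", cnv_start, cnv_start + cnv_size, "cnv", "cnv")
    pads = [
        Region("chr2", cnv.start - pad_size, cnv.start, "pad_left", "pad_left"),
        Region("chr2", cnv.end, cnv.end + pad_size, "pad_right", "pad_right"),
    ]
    genome = GenomeBuild.from_dict({
        "chr1": controls[-1].end + 100_000,
        "chr2": pads[1].end + 100_000,
    })
    return genome, controls, cnv, pads


def make_validation_cohort(
    n_samples: int,
    seed: int,
    size_range: tuple[int, int] = (40_000, 2_000_000),
    on_target_depth: float = ON_TARGET_DEPTH_DEFAULT,
    include_copy_neutral: bool = True,
    write_sequences: bool = True,
) -> list[CohortSample]:
    """A scaled-down validation cohort: deletion/duplication samples with CNV
    sizes log-uniform in ``size_range`` plus (optionally) one copy-neutral
    sample emulating a false positive. Deterministic for a given seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for i in range(n_samples):
        neutral = include_copy_neutral and i == n_samples - 1
        size = int(np.exp(rng.uniform(np.log(size_range[0]), np.log(size_range[1]))))
        genome, controls, cnv, pads = _standard_layout(size)
        if neutral:
            expected, copies = ("deletion" if i % 2 == 0 else "duplication"), 2
        elif i % 2 == 0:
            expected, copies = "deletion", int(rng.choice([0, 1], p=[0.2, 0.8]))
        else:
            expected, copies = "duplication", int(rng.choice([3, 4], p=[0.8, 0.2]))
        spec = SimulatedSampleSpec(
            genome=genome,
            target_regions=[*controls, *pads, cnv],
            copy_number_map=[CopySegment(cnv, copies)],
            diploid_mean_depth=on_target_depth,
            write_sequences=write_sequences,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(CohortSample(
            f"sim{i + 1:02d}", spec, expected, copies, neutral, cnv, controls, pads
        ))
    return samples


def make_imprinting_fixture(
    out_dir: str | Path,
    n_hap1: int = 4,
    n_hap2: int = 7,
    hap1_prob: float = 0.95,
    hap2_prob: float = 0.05,
    seed: int = 0,
) -> SimulationOutput:
    """Imprinted-locus fixture at the SNRPN promoter default coordinates:
    ``n_hap1`` reads on the methylated haplotype and ``n_hap2`` on the
    unmethylated one, all spanning the phasing SNV and the CpG island."""
    genome = GenomeBuild.from_dict({"chr15": 102_531_392})
    meth = MethylationProfile(
        site_mod_prob={"hap1": hap1_prob, "hap2": hap2_prob}
    )
    spec = SimulatedSampleSpec(
        genome=genome, target_regions=[], methylation=meth, seed=seed
    )
    rng = np.random.default_rng(seed)
    reads: list[_Read] = []
    snv, island = meth.snv, meth.island
    for hap, count in ((1, n_hap1), (2, n_hap2)):
        for _ in range(count):
            start = int(rng.integers(snv.pos - 2_000, snv.pos - 100))
            end = int(rng.integers(island.end + 100, island.end + 1_500))
            reads.append(_Read("chr15", start, end, 60, hap))
    locus_counts: dict = {}
    _attach_sequences(spec, reads, rng, locus_counts)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bam_path = out_dir / "imprinting.bam"
    _write_bam(spec, reads, bam_path)
    truth_regions, truth_loci = _truth_tables(spec, reads, locus_counts)
    return SimulationOutput(bam_path, None, truth_regions, truth_loci, spec)
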