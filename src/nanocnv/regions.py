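"""Genomic intervals, genome builds, and BED / manifest I/O.

All coordinates are 0-based half-open internally and in BED output. Inputs
quoted in 1-based conventions (e.g. variant tables) are converted at the
parser boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Region",
    "GenomeBuild",
    "ROLES",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_manifest",
    "write_manifest",
]

ROLES = ("control", "pad_left", "pad_right", "cnv")


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval with an analysis role.

    Roles: ``control`` (copy-number-neutral normalization region), ``pad_left``
    / ``pad_right`` (flanks of the suspected CNV), ``cnv`` (the suspected
    variant itself).
    """

    chrom: str
    start: int
    end: int
    role: str = "control"
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def with_role(self, role: str, label: str | None = None) -> "Region":
        return replace(self, role=role, label=self.label if label is None else label)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.role})"


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome names and lengths for one reference build."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} missing or non-positive length")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeBuild":
        return cls(tuple(lengths), dict(lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome build") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def validate_region(self, region: Region) -> None:
        """Raise ValueError unless ``region`` lies fully within its chromosome."""
        if region.chrom not in self:
            raise ValueError(f"chromosome {region.chrom!r} not in genome build")
        if region.end > self.length(region.chrom):
            raise ValueError(
                f"region {region} exceeds {region.chrom} length "
                f"{self.length(region.chrom)}"
            )

    def sort_key(self, region: Region) -> tuple[int, int, int]:
        return (self.chrom_names.index(region.chrom), region.start, region.end)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def read_chrom_sizes(path: str | Path) -> GenomeBuild:
    """Read a two-column (name, length) chromosome-sizes TSV."""
    lengths: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed chrom-sizes line: {line!r}")
        lengths[fields[0]] = int(fields[1])
    if not lengths:
        raise ValueError(f"no chromosomes found in {path}")
    return GenomeBuild.from_dict(lengths)


def read_bed(path: str | Path, role: str = "control") -> list[Region]:
    """Read a BED file (3+ columns) into Regions with a uniform role."""
    regions: list[Region] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        label = fields[3] if len(fields) > 3 else ""
        regions.append(Region(fields[0], int(fields[1]), int(fields[2]), role, label))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Write 4-column BED (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label or r.role}\n")


def write_manifest(regions: Iterable[Region], path: str | Path) -> None:
    """Write the analysis manifest TSV (chrom, start, end, role, label)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\trole\tlabel\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.role}\t{r.label}\n")


def read_manifest(path: str | Path) -> list[Region]:
    regions: list[Region] = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        chrom, start, end, role, *rest = line.split("\t")
        label = rest[0] if rest else ""
        regions.append(Region(chrom, int(start), int(end), role, label))
    return regions


def merge_touching(regions: Sequence[Region], label: str = "") -> list[Region]:
    """Merge overlapping or abutting intervals on the same chromosome.

    Role information is discarded (merged intervals get role ``cnv`` when any
    member is a CNV/pad, else the first member's role); used only for the BED
    emitted to the sequencer, never for analysis.
    """
    if not regions:
        return []
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[Region] = []
    cur = ordered[0]
    for r in ordered[1:]:
        if r.chrom == cur.chrom and r.start <= cur.end:
            cur = Region(
                cur.chrom, cur.start, max(cur.end, r.end), cur.role,
                label or cur.label,
            )
        else:
            merged.append(cur)
            cur = r
    merged.append(cur)
    return merged
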