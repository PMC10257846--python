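"""Adaptive-sampling target design.

Builds the target BED handed to the sequencer: nine fixed 500-kb control
regions plus the suspected CNV with 500-kb flanking pads, truncated at
chromosome ends. Control regions are assumed copy-number-neutral; a subset of
them (autosomal, adequately covered) forms the normalization denominator for
confirmation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .regions import GenomeBuild, Region, merge_touching, write_bed, write_manifest

log = logging.getLogger(__name__)

__all__ = [
    "CNVHypothesis",
    "ControlPanel",
    "DesignResult",
    "build_target_bed",
    "load_control_panel",
    "default_control_panel",
]

DEFAULT_PAD_SIZE = 500_000
SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass(frozen=True)
class CNVHypothesis:
    """The suspected variant driving target design and confirmation."""

    region: Region
    expected_type: str  # "deletion" | "duplication"
    sample_sex: str = "unknown"  # "XX" | "XY" | "unknown"
    pad_size: int = DEFAULT_PAD_SIZE

    def __post_init__(self) -> None:
        if self.expected_type not in ("deletion", "duplication"):
            raise ValueError(f"expected_type must be deletion|duplication, got {self.expected_type!r}")
        if self.sample_sex not in ("XX", "XY", "unknown"):
            raise ValueError(f"sample_sex must be XX|XY|unknown, got {self.sample_sex!r}")
        if self.pad_size < 0:
            raise ValueError("pad_size must be >= 0")
        if self.region.role != "cnv":
            object.__setattr__(self, "region", self.region.with_role("cnv"))


@dataclass
class ControlPanel:
    """The fixed control-region design plus the subset used for analysis.

    ``regions`` is the full sequencing design (nine 500-kb regions in the
    default panel). ``analysis_names`` selects the copy-number-neutral
    autosomal controls retained as the normalization denominator;
    sex-chromosome controls and any regions flagged by the panel file are
    excluded. ``merge_groups`` maps control names to an identity-matching
    merge group (nearby regions merged to dodge linkage disequilibrium).
    """

    regions: list[Region]
    analysis_names: list[str]
    merge_groups: dict[str, str] = field(default_factory=dict)

    @property
    def analysis_subset(self) -> list[Region]:
        return [r for r in self.regions if r.label in self.analysis_names]

    @property
    def total_span(self) -> int:
        return sum(r.length for r in self.regions)

    def match_regions(self) -> dict[str, list[Region]]:
        """Analysis controls grouped for identity matching (merged groups)."""
        groups: dict[str, list[Region]] = {}
        for r in self.analysis_subset:
            key = self.merge_groups.get(r.label, r.label)
            groups.setdefault(key, []).append(r)
        return groups

    def drop_from_analysis(self, name: str) -> None:
        if name in self.analysis_names:
            self.analysis_names.remove(name)


def load_control_panel(path: str | Path) -> ControlPanel:
    """Load a control panel from a TSV manifest or plain BED.

    The TSV form has columns chrom, start, end, name, analysis (0/1),
    merge_group (may be empty). A plain 3/4-column BED is accepted too, in
    which case every non-sex-chromosome control joins the analysis subset.
    """
    regions: list[Region] = []
    analysis: list[str] = []
    merge_groups: dict[str, str] = {}
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    header = lines[0].split("\t")
    has_meta = "analysis" in header
    body = lines[1:] if header[0] in ("chrom", "#chrom") else lines
    for i, line in enumerate(body):
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] else f"control{i + 1:02d}"
        regions.append(Region(chrom, start, end, "control", name))
        if has_meta:
            if fields[4] == "1":
                analysis.append(name)
            if len(fields) > 5 and fields[5]:
                merge_groups[name] = fields[5]
        elif chrom not in SEX_CHROMS:
            analysis.append(name)
    return ControlPanel(regions, analysis, merge_groups)


def default_control_panel() -> ControlPanel:
    """The packaged default panel (synthetic stand-in coordinates).

    Nine 500-kb regions totalling 4.5 Mb: five autosomal analysis controls
    (two of them adjacent on chr17, merged for identity matching), two
    autosomal regions excluded for low coverage, and one region each on chrX
    and chrY excluded from normalization. Coordinates are synthetic
    placeholders on GRCh37-sized chromosomes; override with a site-specific
    panel BED/TSV for real use.
    """
    ref = resources.files("nanocnv.data") / "controls_synthetic_grch37.tsv"
    with resources.as_file(ref) as p:
        return load_control_panel(p)


@dataclass
class DesignResult:
    """Target design output: analysis manifest plus sequencer BED intervals."""

    manifest: list[Region]  # roles preserved: controls, pads, cnv
    bed_regions: list[Region]  # CNV+pads merged for the sequencer
    panel: ControlPanel
    cnv: CNVHypothesis

    @property
    def total_target_span(self) -> int:
        return sum(r.length for r in self.bed_regions)

    def write(self, bed_path: str | Path, manifest_path: str | Path | None = None) -> None:
        write_bed(self.bed_regions, bed_path)
        if manifest_path is not None:
            write_manifest(self.manifest, manifest_path)


def build_target_bed(
    cnv: CNVHypothesis,
    genome: GenomeBuild,
    controls: ControlPanel | None = None,
) -> DesignResult:
    """Assemble the adaptive-sampling target set for one CNV hypothesis.

    Pads abut the CNV exactly and are truncated at chromosome bounds. The CNV
    must not overlap any control region (controls must stay copy-number
    neutral); a pad overlapping a control demotes that control from the
    analysis subset with a warning rather than aborting.
    """
    panel = controls if controls is not None else default_control_panel()
    genome.validate_region(cnv.region)
    for ctrl in panel.regions:
        genome.validate_region(ctrl)
        if cnv.region.overlaps(ctrl):
            raise ValueError(
                f"CNV region {cnv.region} overlaps control {ctrl.label} "
                f"({ctrl}); controls must be copy-number-neutral — supply a "
                "different control panel"
            )

    chrom_len = genome.length(cnv.region.chrom)
    manifest: list[Region] = [r for r in panel.regions]
    pads: list[Region] = []
    left_start = max(0, cnv.region.start - cnv.pad_size)
    if left_start < cnv.region.start:
        pads.append(Region(cnv.region.chrom, left_start, cnv.region.start,
                           "pad_left", "pad_left"))
    right_end = min(chrom_len, cnv.region.end + cnv.pad_size)
    if right_end > cnv.region.end:
        pads.append(Region(cnv.region.chrom, cnv.region.end, right_end,
                           "pad_right", "pad_right"))

    panel = ControlPanel(list(panel.regions), list(panel.analysis_names),
                         dict(panel.merge_groups))
    for pad in pads:
        for ctrl in panel.regions:
            if pad.overlaps(ctrl) and ctrl.label in panel.analysis_names:
                warnings.warn(
                    f"pad {pad} overlaps control {ctrl.label}; dropping that "
                    "control from the analysis subset", stacklevel=2,
                )
                panel.drop_from_analysis(ctrl.label)

    cnv_region = cnv.region if cnv.region.label else cnv.region.with_role("cnv", "cnv")
    manifest.extend(pads)
    manifest.append(cnv_region)
    manifest.sort(key=genome.sort_key)

    cnv_block = merge_touching([cnv_region, *pads], label=f"{cnv_region.label}_target")
    bed_regions = sorted([*panel.regions, *cnv_block], key=genome.sort_key)
    return DesignResult(manifest, bed_regions, panel, cnv)
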