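"""Run configuration: every tunable of the workflow with its default.

Defaults mirror the assay design: 500-kb pads, 3-SD dynamic cutoffs, 1%
depth windows, fingerprint SNVs with population AF in [0.4, 0.6] capped at
150 per control region, >0.95 allele fraction for homozygous calls, >90%
genotype agreement per match region, platform depth minima of 10 (short-read)
and 1 (long-read), and a 10-replicate downsampling titration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "dump_default_config"]


@dataclass
class RunConfig:
    pad_size: int = 500_000
    sd_multiplier: float = 3.0
    window_fraction: float = 0.01
    min_mapq_exclusive: int = 0
    af_band: tuple[float, float] = (0.4, 0.6)
    loci_per_region: int = 150
    hom_fraction: float = 0.95
    match_threshold: float = 0.90
    min_depth_short_read: int = 10
    min_depth_long_read: int = 1
    methylation_prob_threshold: float = 0.5
    methylation_fraction_threshold: float = 0.5
    titration_depths: list[float] = field(
        default_factory=lambda: [0.1, 0.5, 1.0, 2.0, 4.0, 8.0, 15.0]
    )
    titration_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")
        if not 0 <= self.af_band[0] <= self.af_band[1] <= 1:
            raise ValueError("af_band must be an ordered pair in [0, 1]")
        for name in ("hom_fraction", "match_threshold",
                     "methylation_prob_threshold",
                     "methylation_fraction_threshold"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sd_multiplier <= 0 or self.pad_size < 0:
            raise ValueError("sd_multiplier must be > 0 and pad_size >= 0")

    @property
    def min_depth(self) -> dict[str, int]:
        return {"short_read": self.min_depth_short_read,
                "long_read": self.min_depth_long_read}


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "af_band" in data:
        data["af_band"] = tuple(data["af_band"])
    return RunConfig(**data)


def dump_default_config(path: str | Path) -> None:
    cfg = asdict(RunConfig())
    cfg["af_band"] = list(cfg["af_band"])
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
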