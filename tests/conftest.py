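"""Shared fixtures: hand-built tiny BAMs and session-scoped simulations."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from nanocnv.experiments import ratio_spec
from nanocnv.simulate import simulate_reads
from nanocnv.target_design import CNVHypothesis


def write_tiny_bam(
    path: Path,
    reads: list[dict],
    chrom_lengths: dict[str, int],
) -> Path:
    """Write a coordinate-sorted, indexed BAM from read dicts.

    Each dict: chrom, start, and either ``cigar`` (string) or ``length``
    (mapped as a single match block); optional mapq (default 60), seq,
    flag, name, tags (list of (tag, value, type)).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
    }
    tids = {c: i for i, c in enumerate(chrom_lengths)}
    reads = sorted(reads, key=lambda r: (tids[r["chrom"]], r["start"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, spec in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = spec.get("name", f"read{i}")
            a.flag = spec.get("flag", 0)
            a.reference_id = tids[spec["chrom"]]
            a.reference_start = spec["start"]
            a.mapping_quality = spec.get("mapq", 60)
            if "cigar" in spec:
                a.cigarstring = spec["cigar"]
            else:
                a.cigartuples = [(0, spec["length"])]
            if "seq" in spec:
                a.query_sequence = spec["seq"]
            elif a.infer_query_length():
                a.query_sequence = "A" * a.infer_query_length()
            for tag, value, vtype in spec.get("tags", ()):
                a.set_tag(tag, value, vtype)
            bam.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def sim_deletion(tmp_path_factory):
    """One simulated heterozygous-deletion sample (10X, standard layout)."""
    out_dir = tmp_path_factory.mktemp("sim_deletion")
    spec, manifest, cnv_region = ratio_spec(copies=1, seed=42, depth=10.0)
    sim = simulate_reads(spec, out_dir, name="del1")
    hyp = CNVHypothesis(cnv_region, "deletion")
    return sim, manifest, hyp
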