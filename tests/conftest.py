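"""Shared fixtures: in-memory alignments and one default-scale pipeline run."""

from __future__ import annotations

import pysam
import pytest

from shorthap import pipeline, simdata


def make_header(contigs: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in contigs.items()],
    })


def make_read(header: pysam.AlignmentHeader, contig: str, start: int, seq: str,
              cigar: str | None = None, mapq: int = 60,
              name: str = "r") -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = header.get_tid(contig)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the standard study design (2 species x 2
    subpopulations x 5 diploids, 2 x 50 kb contigs, 30x) with 200 bootstrap
    replicates. Session-scoped: several structure-recovery tests share it."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = pipeline.PipelineConfig(
        out_dir=str(out), simulate=simdata.SimulationConfig(seed=1),
        n_bootstrap=200, seed=1)
    manifest = pipeline.run_pipeline(cfg)
    return {"dir": out, "manifest": manifest, "config": cfg}
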