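"""Shared fixtures: tiny annotations, coverage tracks, and SAM builders."""

from __future__ import annotations

import textwrap

import numpy as np
import pandas as pd
import pytest

from quantpipes.formats_io import CoverageTrack, GenomicInterval, TranscriptModel


@pytest.fixture
def gtf_file(tmp_path):
    """A two-gene GTF (one plus, one minus strand) as gffutils input."""
    text = textwrap.dedent(
        """\
        chr1\tsrc\tgene\t1001\t9000\t.\t+\t.\tgene_id "gA";
        chr1\tsrc\ttranscript\t1001\t9000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
        chr1\tsrc\texon\t1001\t9000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
        chr1\tsrc\tgene\t20001\t30000\t.\t-\t.\tgene_id "gB";
        chr1\tsrc\ttranscript\t20001\t30000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
        """
    )
    path = tmp_path / "anno.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_transcript():
    return TranscriptModel(
        gene_id="g1",
        transcript_id="g1.t1",
        interval=GenomicInterval("chr1", 10_000, 18_000, "+"),
    )


@pytest.fixture
def flat_track():
    """Uniform depth 4.0 over a 60 kb chromosome."""
    return CoverageTrack(
        name="flat",
        depths={"chr1": np.full(60_000, 4.0)},
        library_size=1e6,
    )


def make_sam(path, reads, chrom="chr1", length=10_000):
    """Write a small single-chromosome SAM file with pysam.

    ``reads`` is a list of dicts with keys: name, pos, mapq, reverse,
    unmapped (all but name optional).
    """
    import pysam

    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for spec in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = spec["name"]
            a.query_sequence = "A" * 50
            a.query_qualities = pysam.qualitystring_to_array("I" * 50)
            if spec.get("unmapped"):
                a.is_unmapped = True
            else:
                a.reference_id = 0
                a.reference_start = spec.get("pos", 100)
                a.mapping_quality = spec.get("mapq", 30)
                a.cigarstring = "50M"
                a.is_reverse = bool(spec.get("reverse", False))
            out.write(a)
    return path


@pytest.fixture
def sam_builder(tmp_path):
    def build(reads, name="reads.sam", **kw):
        return make_sam(tmp_path / name, reads, **kw)

    return build


@pytest.fixture
def evidence_row():
    """A template evidence row; tests override individual fields."""

    def make(**overrides):
        row = {
            "sequence": "AAASPK",
            "modifications": "S4:Phospho",
            "phospho_count": 1,
            "proteins": "P1",
            "is_contaminant": False,
            "is_decoy": False,
            "intensity_total": 1e6,
            "ratio_HL": 1.0,
            "experiment": "Ti",
            "fraction": 1,
            "replicate": "rep1",
            "site_positions": "P1:4",
            "raw_file": "f1.raw",
        }
        row.update(overrides)
        return row

    return make


@pytest.fixture
def evidence_table(evidence_row):
    def make(rows):
        return pd.DataFrame([evidence_row(**r) for r in rows])

    return make
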