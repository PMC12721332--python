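"""Readers, writers and schema validation for the formats the pipelines touch.

Coordinate conventions: everything internal is 0-based half-open. GTF is
read as 1-based inclusive and converted on the way in; BED is already
0-based half-open. Alignment filtering re-implements the published
contract — drop reads with mapping quality below 20, then collapse
duplicates to one read per (chromosome, 5'-end, strand), single-end
semantics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_MAPQ = 20

#: Required columns of a MaxQuant-style phospho evidence table.
EVIDENCE_COLUMNS = [
    "sequence",
    "modifications",
    "phospho_count",
    "proteins",
    "is_contaminant",
    "is_decoy",
    "intensity_total",
    "ratio_HL",
    "experiment",
    "fraction",
    "replicate",
    "site_positions",
    "raw_file",
]

#: Required fixed columns of a protein-groups table; per-sample
#: ``intensity_<sample>`` (and, depending on pipeline, ``ratio_HL_<sample>``
#: or ``peptides_<sample>``) columns are validated separately.
PROTEIN_GROUP_COLUMNS = ["protein_ids", "peptide_count", "is_contaminant", "is_decoy"]

#: Required columns of the label-incorporation peptide table.
PEPTIDE_COLUMNS = ["sequence", "modifications", "intensity_labeled", "intensity_unlabeled"]


class SchemaError(ValueError):
    """A table does not conform to its required schema."""


class AnnotationParseError(ValueError):
    """A GTF/BED line could not be parsed; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript with its gene assignment and strand-derived anchors.

    TSS is the 5' end of the transcript (``start`` on plus strand,
    ``end`` on minus strand); TTS is the 3' end.
    """

    gene_id: str
    transcript_id: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


def group_by_gene(transcripts: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    """Group transcripts under their gene id, preserving input order."""
    genes: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    return genes


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _prevalidate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[3]!r}/{fields[4]!r}"
                ) from exc


def _read_gtf(path: Path) -> list[TranscriptModel]:
    import gffutils

    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: list[TranscriptModel] = []
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            warnings.warn(
                f"transcript {feat.id} has no strand; record rejected", stacklevel=2
            )
            continue
        out.append(
            TranscriptModel(
                gene_id=feat.attributes["gene_id"][0],
                transcript_id=feat.attributes["transcript_id"][0],
                # GTF is 1-based inclusive -> 0-based half-open
                interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand),
            )
        )
    return out


def _read_bed12(path: Path) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED needs >= 6 fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                warnings.warn(f"{path}:{lineno}: no strand; record rejected", stacklevel=2)
                continue
            gene_id, _, tx_id = name.partition("|")
            out.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=tx_id or name,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                )
            )
    return out


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF (Ensembl dialect) or BED12 annotation into transcripts.

    Returns transcripts carrying gene id, strand and interval; group them
    with :func:`group_by_gene`. An empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        transcripts = _read_bed12(path)
    else:
        transcripts = _read_gtf(path)
    if not transcripts:
        warnings.warn(f"annotation {path} contains no transcripts", stacklevel=2)
    return transcripts


def write_bed(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as BED6, 0-based half-open, name = gene|transcript."""
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(
                f"{tx.chrom}\t{tx.interval.start}\t{tx.interval.end}\t"
                f"{tx.gene_id}|{tx.transcript_id}\t0\t{tx.strand}\n"
            )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-base depth per chromosome plus the library size used for scaling.

    ``depths`` maps chromosome -> float array of per-base depth. Queries
    outside the stored arrays return zeros; a query on an unknown
    chromosome warns and returns zeros.
    """

    depths: dict[str, np.ndarray]
    library_size: float
    name: str = ""
    _cumsums: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.library_size > 0:
            raise ValueError("library_size must be > 0")
        for chrom, arr in self.depths.items():
            if np.any(arr < 0):
                raise ValueError(f"negative depth on {chrom}")

    def _cumsum(self, chrom: str) -> np.ndarray:
        if chrom not in self._cumsums:
            arr = self.depths[chrom]
            cs = np.zeros(len(arr) + 1)
            np.cumsum(arr, out=cs[1:])
            self._cumsums[chrom] = cs
        return self._cumsums[chrom]

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); zero-padded beyond bounds."""
        out = np.zeros(end - start)
        if chrom not in self.depths:
            warnings.warn(f"chromosome {chrom!r} not in track; returning zeros", stacklevel=2)
            return out
        arr = self.depths[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base depth over [start, end), clipped to bounds."""
        if chrom not in self.depths:
            return 0.0
        cs = self._cumsum(chrom)
        n = len(cs) - 1
        lo, hi = min(max(start, 0), n), min(max(end, 0), n)
        if lo >= hi:
            return 0.0
        return float(cs[hi] - cs[lo])

    def total_signal(self) -> float:
        return float(sum(arr.sum() for arr in self.depths.values()))


@dataclass
class AlignmentFilterStats:
    """Bookkeeping from :func:`filter_alignments`, recorded in the manifest."""

    total: int = 0
    unmapped: int = 0
    low_mapq: int = 0
    duplicates: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "unmapped": self.unmapped,
            "low_mapq": self.low_mapq,
            "duplicates": self.duplicates,
            "retained": self.retained,
        }


def filter_alignments(reads: Iterable, min_mapq: int = MIN_MAPQ) -> tuple[list, AlignmentFilterStats]:
    """Apply the read filters: MAPQ < ``min_mapq`` dropped, duplicates removed.

    Duplicates are collapsed to one read per (reference, 5'-end, strand) —
    single-end semantics. The MAPQ boundary is exclusive: quality 20 is
    kept. Unmapped reads are skipped silently but counted. Operates on
    pysam ``AlignedSegment`` objects; the MAPQ filter runs before
    duplicate collapsing.
    """
    stats = AlignmentFilterStats()
    seen: set[tuple[int, int, bool]] = set()
    kept: list = []
    for read in reads:
        stats.total += 1
        if read.is_unmapped:
            stats.unmapped += 1
            continue
        if read.mapping_quality < min_mapq:
            stats.low_mapq += 1
            continue
        five_prime = read.reference_end if read.is_reverse else read.reference_start
        key = (read.reference_id, five_prime, read.is_reverse)
        if key in seen:
            stats.duplicates += 1
            continue
        seen.add(key)
        kept.append(read)
    stats.retained = len(kept)
    return kept, stats


def _read_bedgraph(path: Path, library_size: float | None) -> CoverageTrack:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        skiprows=lambda i: False,
    )
    df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
    depths: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = np.zeros(int(sub["end"].max()))
        for start, end, value in zip(
            sub["start"].astype(int), sub["end"].astype(int), sub["value"].astype(float)
        ):
            arr[start:end] += value
        depths[str(chrom)] = arr
    if library_size is None:
        raise ValueError(
            "bedGraph/bigWig tracks carry no read counts; pass library_size "
            "explicitly (e.g. the total filtered-read count of the library)"
        )
    return CoverageTrack(depths=depths, library_size=float(library_size), name=path.name)


def _read_bigwig(path: Path, library_size: float | None) -> CoverageTrack:
    import pyBigWig

    if library_size is None:
        raise ValueError(
            "bedGraph/bigWig tracks carry no read counts; pass library_size explicitly"
        )
    bw = pyBigWig.open(str(path))
    try:
        depths = {}
        for chrom, length in bw.chroms().items():
            vals = np.nan_to_num(np.asarray(bw.values(chrom, 0, length), dtype=float))
            depths[chrom] = vals
    finally:
        bw.close()
    return CoverageTrack(depths=depths, library_size=float(library_size), name=path.name)


def _read_bam(path: Path, min_mapq: int) -> CoverageTrack:
    import pysam

    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        lengths = dict(zip(bam.references, bam.lengths))
        kept, stats = filter_alignments(bam.fetch(until_eof=True), min_mapq=min_mapq)
        depths = {chrom: np.zeros(length) for chrom, length in lengths.items()}
        for read in kept:
            arr = depths[read.reference_name]
            arr[read.reference_start : read.reference_end] += 1
    logger.info("filtered %s: %s", path.name, stats.as_dict())
    track = CoverageTrack(
        depths=depths, library_size=float(max(stats.retained, 1)), name=path.name
    )
    track.filter_stats = stats  # type: ignore[attr-defined]
    return track


def read_coverage(
    path: str | Path, library_size: float | None = None, min_mapq: int = MIN_MAPQ
) -> CoverageTrack:
    """Read coverage from bedGraph, bigWig, or BAM/SAM.

    BAM/SAM input is filtered with :func:`filter_alignments` first and its
    library size is the retained read count; bedGraph/bigWig require an
    explicit ``library_size`` because a (possibly normalized) track cannot
    reveal it.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".bam", ".sam"):
        return _read_bam(path, min_mapq)
    if suffix in (".bw", ".bigwig"):
        return _read_bigwig(path, library_size)
    return _read_bedgraph(path, library_size)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length encoding constant stretches."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            arr = track.depths[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Tables and manifest
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} is missing required columns: {missing}")


def validate_evidence_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the phospho evidence schema; returns the table unchanged."""
    _require_columns(df, EVIDENCE_COLUMNS, "evidence table")
    bad_exp = set(df["experiment"].dropna().unique()) - {"Ti", "IM"}
    if bad_exp:
        raise SchemaError(f"evidence experiment must be Ti or IM, found {sorted(bad_exp)}")
    if (df["intensity_total"].dropna() < 0).any():
        raise SchemaError("evidence intensity_total must be >= 0 or missing")
    if (df["ratio_HL"].dropna() <= 0).any():
        raise SchemaError("evidence ratio_HL must be > 0 or missing")
    return df


def validate_protein_group_table(
    df: pd.DataFrame, sample_prefixes: Sequence[str] = ("intensity_",)
) -> pd.DataFrame:
    """Validate a protein-groups schema with per-sample wide columns."""
    _require_columns(df, PROTEIN_GROUP_COLUMNS, "protein-groups table")
    for prefix in sample_prefixes:
        cols = [c for c in df.columns if c.startswith(prefix)]
        if not cols:
            raise SchemaError(f"protein-groups table has no {prefix}* sample columns")
        vals = df[cols].to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise SchemaError(f"{prefix}* values must be >= 0 or missing")
    return df


def validate_peptide_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, PEPTIDE_COLUMNS, "peptide table")
    return df


def sample_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    """Ordered per-sample column names with the given prefix."""
    return [c for c in df.columns if c.startswith(prefix)]


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with a header, deterministic order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    seed: int | None,
    config: Mapping | None = None,
    inputs: Sequence[str | Path] = (),
    extra: Mapping | None = None,
) -> dict:
    """Write a JSON run manifest: seed, config, input checksums, versions.

    Deliberately excludes timestamps so identical runs produce identical
    manifests.
    """
    from quantpipes import __version__

    manifest = {
        "package": "quantpipes",
        "version": __version__,
        "seed": seed,
        "config": dict(config or {}),
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
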