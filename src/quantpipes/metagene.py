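"""ChIP-seq metagene analysis on a fixed 90/180/215-bin coordinate system.

The analysis is restricted to transcripts of at least 3180 bp belonging
to genes at least 5000 nt away from their nearest neighbour. For each
gene one representative transcript is chosen (highest library-size
normalized reference coverage around TSS and TTS). The region −3 kb to
+1.5 kb of the TSS is tiled with 50 bp bins (90 bins), −1.5 kb to
+20 kb of the TTS with 100 bp bins (215 bins), and the remaining gene
body with 180 bins of variable length, so genes of different lengths
are comparable. Per bin the mean per-base coverage is computed and
scaled to counts per million of the library. Profiles average first
across genes, then across replicates. Differences between conditions
are tested per bin with a paired Wilcoxon signed-rank test on per-gene
values and Bonferroni-corrected across the 485 bins of the comparison;
adjusted p-values are color-coded red/orange/yellow at 1e-15 / 1e-10 /
1e-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from quantpipes._stats import bonferroni
from quantpipes.formats_io import CoverageTrack, TranscriptModel, group_by_gene
from quantpipes.thresholds import MetageneColorCodes

logger = logging.getLogger(__name__)


@dataclass
class BinSchemeConfig:
    """Geometry of the metagene bin scheme (defaults as published)."""

    tss_upstream: int = 3000
    tss_downstream: int = 1500
    tss_bin: int = 50
    tts_upstream: int = 1500
    tts_downstream: int = 20000
    tts_bin: int = 100
    body_bins: int = 180
    min_transcript_length: int = 3180
    min_gene_distance: int = 5000

    def __post_init__(self) -> None:
        if (self.tss_upstream + self.tss_downstream) % self.tss_bin:
            raise ValueError("TSS region length must be a multiple of tss_bin")
        if (self.tts_upstream + self.tts_downstream) % self.tts_bin:
            raise ValueError("TTS region length must be a multiple of tts_bin")
        if self.min_transcript_length < self.tss_downstream + self.tts_upstream + self.body_bins:
            raise ValueError(
                "min_transcript_length must leave every body bin >= 1 bp"
            )

    @property
    def n_tss_bins(self) -> int:
        return (self.tss_upstream + self.tss_downstream) // self.tss_bin

    @property
    def n_tts_bins(self) -> int:
        return (self.tts_upstream + self.tts_downstream) // self.tts_bin

    @property
    def n_bins(self) -> int:
        return self.n_tss_bins + self.body_bins + self.n_tts_bins


@dataclass
class BinScheme:
    """Ordered genomic bins of one transcript, 5'→3' (bin 0 is 5'-most).

    Starts/ends are genomic coordinates that may extend beyond
    chromosome bounds; coverage queries treat out-of-bounds bases as
    zero depth.
    """

    transcript: TranscriptModel
    starts: np.ndarray
    ends: np.ndarray
    parts: np.ndarray  # "tss" | "body" | "tts" per bin

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts


def filter_transcripts(
    transcripts: Sequence[TranscriptModel], config: BinSchemeConfig | None = None
) -> list[TranscriptModel]:
    """Keep transcripts >= min length from genes with isolated neighbourhood.

    The gene distance is measured between gene spans (union of each
    gene's transcripts) on the same chromosome, strand-agnostic;
    overlapping neighbours count as distance 0. A single gene on a
    chromosome has infinite distance and is kept.
    """
    config = config or BinSchemeConfig()
    genes = group_by_gene(transcripts)
    spans: dict[str, tuple[str, int, int]] = {}
    for gid, txs in genes.items():
        chrom = txs[0].chrom
        spans[gid] = (chrom, min(t.interval.start for t in txs), max(t.interval.end for t in txs))

    # nearest-neighbour gap per gene, computed per chromosome
    isolated: dict[str, bool] = {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, (chrom, s, e) in spans.items():
        by_chrom.setdefault(chrom, []).append((s, e, gid))
    for chrom, entries in by_chrom.items():
        entries.sort()
        for i, (s, e, gid) in enumerate(entries):
            gap = np.inf
            if i > 0:
                gap = min(gap, s - entries[i - 1][1])
            if i + 1 < len(entries):
                gap = min(gap, entries[i + 1][0] - e)
            isolated[gid] = gap >= config.min_gene_distance

    kept = [
        tx
        for tx in transcripts
        if tx.length >= config.min_transcript_length and isolated[tx.gene_id]
    ]
    logger.info("filter_transcripts kept %d/%d transcripts", len(kept), len(transcripts))
    return kept


def select_representative_transcript(
    transcripts: Sequence[TranscriptModel],
    reference_tracks: Sequence[CoverageTrack] | None = None,
    window: int = 3000,
    mode: str = "coverage",
) -> TranscriptModel:
    """Pick one transcript per gene by reference coverage around TSS and TTS.

    Score = sum over reference samples of the coverage sum inside the
    union of TSS±window and TTS±window, divided by each sample's library
    size. Ties break to the longest transcript, then lexicographic
    transcript id. ``mode="longest"`` skips coverage scoring.
    """
    if not transcripts:
        raise ValueError("no transcripts for gene")
    if mode == "longest" or len(transcripts) == 1:
        return max(transcripts, key=lambda t: (t.length, t.transcript_id))
    if mode != "coverage":
        raise ValueError(f"unknown mode {mode!r}")
    if not reference_tracks:
        raise ValueError(
            "representative-transcript selection needs reference coverage "
            "tracks; supply them or use mode='longest'"
        )

    def score(tx: TranscriptModel) -> float:
        w1 = (tx.tss - window, tx.tss + window)
        w2 = (tx.tts - window, tx.tts + window)
        # merge overlapping windows so shared bases count once
        if w1[0] > w2[0]:
            w1, w2 = w2, w1
        windows = [(w1[0], max(w1[1], w2[1]))] if w2[0] <= w1[1] else [w1, w2]
        total = 0.0
        for track in reference_tracks:
            s = sum(track.interval_sum(tx.chrom, lo, hi) for lo, hi in windows)
            total += s / track.library_size
        return total

    return max(transcripts, key=lambda t: (score(t), t.length, t.transcript_id))


def build_bin_scheme(tx: TranscriptModel, config: BinSchemeConfig | None = None) -> BinScheme:
    """Build the 485-bin scheme for one eligible transcript.

    The body (between TSS+tss_downstream and TTS−tts_upstream in
    transcript orientation) is split into ``body_bins`` contiguous bins
    whose lengths differ by at most 1 bp; the remainder bases go to the
    5'-most bins. On the minus strand all regions are mirrored so bin 0
    is always 5'-most.
    """
    config = config or BinSchemeConfig()
    if tx.length < config.min_transcript_length:
        raise ValueError(
            f"transcript {tx.transcript_id} is {tx.length} bp, below the "
            f"{config.min_transcript_length} bp minimum (filter first)"
        )
    body_len = tx.length - config.tss_downstream - config.tts_upstream
    base, rem = divmod(body_len, config.body_bins)
    body_sizes = np.full(config.body_bins, base, dtype=int)
    body_sizes[:rem] += 1  # extra bases to the 5'-most bins

    # transcript-oriented offsets relative to the TSS, 5'→3'
    tss_sizes = np.full(config.n_tss_bins, config.tss_bin, dtype=int)
    tts_sizes = np.full(config.n_tts_bins, config.tts_bin, dtype=int)
    sizes = np.concatenate([tss_sizes, body_sizes, tts_sizes])
    offsets = np.concatenate([[0], np.cumsum(sizes)]) - config.tss_upstream

    if tx.strand == "+":
        starts = tx.tss + offsets[:-1]
        ends = tx.tss + offsets[1:]
    else:
        starts = tx.tss - offsets[1:]
        ends = tx.tss - offsets[:-1]
    parts = np.array(
        ["tss"] * config.n_tss_bins + ["body"] * config.body_bins + ["tts"] * config.n_tts_bins
    )
    return BinScheme(transcript=tx, starts=starts, ends=ends, parts=parts)


@dataclass
class BinnedCoverageMatrix:
    """Genes x bins matrix of depth-normalized (CPM) mean bin coverage."""

    values: np.ndarray
    gene_ids: list[str]
    sample: str = ""
    condition: str = ""
    replicate: str = ""


def compute_binned_coverage(
    track: CoverageTrack, schemes: Sequence[BinScheme], **meta: str
) -> BinnedCoverageMatrix:
    """Mean per-base coverage per bin, scaled to counts per million.

    cell = (sum of depth in bin / bin length) * 1e6 / library_size.
    Bins beyond chromosome bounds contribute zero depth.
    """
    scale = 1e6 / track.library_size
    values = np.empty((len(schemes), len(schemes[0]) if schemes else 0))
    for i, scheme in enumerate(schemes):
        chrom = scheme.transcript.chrom
        sums = np.array(
            [track.interval_sum(chrom, int(s), int(e)) for s, e in zip(scheme.starts, scheme.ends)]
        )
        values[i] = sums / scheme.lengths * scale
    return BinnedCoverageMatrix(
        values=values,
        gene_ids=[s.transcript.gene_id for s in schemes],
        sample=meta.get("sample", track.name),
        condition=meta.get("condition", ""),
        replicate=meta.get("replicate", ""),
    )


@dataclass
class MetageneProfile:
    """Replicate-averaged metagene profile plus per-replicate profiles."""

    mean: np.ndarray
    per_replicate: np.ndarray  # replicates x bins
    replicate_names: list[str] = field(default_factory=list)


def aggregate_profile(matrices: Sequence[BinnedCoverageMatrix]) -> MetageneProfile:
    """Average bins across genes per replicate, then across replicates."""
    if not matrices:
        raise ValueError("no matrices to aggregate")
    gene_ids = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != gene_ids:
            raise ValueError("replicates cover different gene sets")
    per_rep = np.vstack([m.values.mean(axis=0) for m in matrices])
    return MetageneProfile(
        mean=per_rep.mean(axis=0),
        per_replicate=per_rep,
        replicate_names=[m.sample for m in matrices],
    )


def _condition_gene_matrix(matrices: Sequence[BinnedCoverageMatrix]) -> np.ndarray:
    """Replicate-averaged genes x bins matrix for one condition."""
    gene_ids = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != gene_ids:
            raise ValueError("replicates cover different gene sets")
    return np.mean([m.values for m in matrices], axis=0)


def wilcoxon_paired(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 25
) -> tuple[float, float, int]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (classical signed-rank convention); the
    exact null distribution is used for effective n <= ``exact_max_n``
    and tie-free ranks, otherwise the normal approximation with
    continuity correction. Returns (W, p, effective n); fewer than two
    nonzero pairs give p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n < 2:
        return np.nan, 1.0, n
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not has_ties:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided", method="approx", correction=True
        )
    return float(res.statistic), float(res.pvalue), n


def per_bin_paired_test(
    control: Sequence[BinnedCoverageMatrix],
    treated: Sequence[BinnedCoverageMatrix],
    colors: MetageneColorCodes | None = None,
    pair_on: str = "gene_mean",
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Paired Wilcoxon per bin between conditions, Bonferroni across bins.

    ``pair_on="gene_mean"`` (default) averages replicates per gene per
    condition and pairs genes; ``pair_on="replicate"`` keeps every
    (gene, replicate) pair. The Bonferroni factor is the number of bins
    of the profile (one comparison = one correction family).
    """
    colors = colors or MetageneColorCodes()
    if pair_on == "gene_mean":
        c = _condition_gene_matrix(control)
        t = _condition_gene_matrix(treated)
    elif pair_on == "replicate":
        if len(control) != len(treated):
            raise ValueError("pair_on='replicate' needs matched replicate lists")
        c = np.vstack([m.values for m in control])
        t = np.vstack([m.values for m in treated])
    else:
        raise ValueError(f"unknown pair_on {pair_on!r}")
    if c.shape != t.shape:
        raise ValueError("control and treated gene sets differ in size")

    n_bins = c.shape[1]
    rows = []
    for b in range(n_bins):
        w, p, n_eff = wilcoxon_paired(t[:, b], c[:, b], exact_max_n=exact_max_n)
        rows.append((b, w, p, n_eff, n_eff < 2))
    df = pd.DataFrame(rows, columns=["bin", "W", "p", "n_pairs", "degenerate"])
    df["p_adj"] = bonferroni(df["p"].to_numpy(), m=n_bins)
    df["category"] = [colors.category(p) for p in df["p_adj"]]
    return df


def run_metagene(
    transcripts: Sequence[TranscriptModel],
    control_tracks: Sequence[CoverageTrack],
    treated_tracks: Sequence[CoverageTrack],
    reference_tracks: Sequence[CoverageTrack] | None = None,
    config: BinSchemeConfig | None = None,
    colors: MetageneColorCodes | None = None,
    pair_on: str = "gene_mean",
    representative_mode: str | None = None,
) -> dict:
    """End-to-end metagene analysis; returns profiles, tests and schemes.

    Filters transcripts, picks one representative per gene (reference
    coverage if provided, otherwise longest), builds the bin schemes,
    bins every track, and runs the per-bin paired tests.
    """
    config = config or BinSchemeConfig()
    eligible = filter_transcripts(transcripts, config)
    if not eligible:
        raise ValueError("no eligible transcripts after filtering")
    if representative_mode is None:
        representative_mode = "coverage" if reference_tracks else "longest"
    genes = group_by_gene(eligible)
    schemes = [
        build_bin_scheme(
            select_representative_transcript(
                txs, reference_tracks, mode=representative_mode
            ),
            config,
        )
        for txs in genes.values()
    ]

    def bin_all(tracks: Sequence[CoverageTrack], condition: str) -> list[BinnedCoverageMatrix]:
        return [
            compute_binned_coverage(
                tr, schemes, condition=condition, replicate=str(i + 1), sample=tr.name
            )
            for i, tr in enumerate(tracks)
        ]

    control_m = bin_all(control_tracks, "control")
    treated_m = bin_all(treated_tracks, "treated")
    profile_c = aggregate_profile(control_m)
    profile_t = aggregate_profile(treated_m)
    tests = per_bin_paired_test(control_m, treated_m, colors=colors, pair_on=pair_on)

    parts = schemes[0].parts
    profile = pd.DataFrame({"bin": np.arange(len(parts)), "part": parts})
    profile["mean_control"] = profile_c.mean
    profile["mean_treated"] = profile_t.mean
    for i, row in enumerate(profile_c.per_replicate):
        profile[f"control_rep{i + 1}"] = row
    for i, row in enumerate(profile_t.per_replicate):
        profile[f"treated_rep{i + 1}"] = row
    tests.insert(1, "part", parts)
    return {
        "profile": profile,
        "tests": tests,
        "schemes": schemes,
        "control_matrices": control_m,
        "treated_matrices": treated_m,
    }
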