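"""Seeded generators emulating the statistical structure of the study data.

Three simulators with known ground truth:

* ChIP-seq: gene-body-enriched occupancy with accumulation at and beyond
  the transcription termination site, reduced multiplicatively under an
  inhibitor, Poisson per-base counts over a constant background.
* SILAC phosphoproteomics: a small set of truly dephosphorylated sites
  (large negative log2 fold-change) among many nulls, measured as
  MaxQuant-style evidence rows with H/L ratios under a label-flip
  replicate design, plus a null protein-level table.
* BioID: bait-enriched interactors among nulls with intensity-dependent
  (MNAR) and random (MCAR) missingness.

Noise models are the simplest ones consistent with the downstream
pipelines: Poisson counts for coverage, log-normal multiplicative noise
for MS intensities, and ratio noise on the log scale. Every generator is
fully deterministic under a fixed seed, and the truth records suffice to
score sensitivity/specificity of every downstream caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from quantpipes.formats_io import CoverageTrack, GenomicInterval, TranscriptModel

AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # 20 minus K/R (tryptic termini added separately)


def _random_tryptic_peptide(rng: np.random.Generator, min_len: int = 7, max_len: int = 25) -> str:
    """Random 7–25-mer over the 20 amino acids ending in K or R."""
    n = int(rng.integers(min_len, max_len + 1))
    body = "".join(rng.choice(list(AMINO_ACIDS), size=n - 1))
    return body + rng.choice(["K", "R"])


# ---------------------------------------------------------------------------
# ChIP-seq
# ---------------------------------------------------------------------------


@dataclass
class ChipSimSpec:
    """Conditions of the ChIP-seq simulation.

    ``body_signal`` is the mean per-base depth over gene bodies in the
    control; the window around the TTS is scaled by ``tts_peak_factor``;
    treated tracks retain ``inhibitor_loss_factor`` of the gene-derived
    signal while the background stays constant. ``short_fraction`` /
    ``close_fraction`` deliberately violate the transcript-length and
    gene-distance filters, flagged in the truth record.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (4000, 12000)
    intergenic_gap_range: tuple[int, int] = (6000, 12000)
    body_signal: float = 10.0
    tts_peak_factor: float = 3.0
    inhibitor_loss_factor: float = 1.0
    background_signal: float = 0.5
    n_replicates: int = 2
    seed: int = 0
    library_size: float | None = 2e7
    library_size_cv: float = 0.0
    short_fraction: float = 0.0
    close_fraction: float = 0.0
    tts_peak_upstream: int = 500
    tts_peak_downstream: int = 1500
    chrom: str = "chrSim"
    min_transcript_length: int = 3180
    min_gene_distance: int = 5000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.inhibitor_loss_factor <= 1:
            raise ValueError("inhibitor_loss_factor must be in (0, 1]")
        if self.tts_peak_factor < 1:
            raise ValueError("tts_peak_factor must be >= 1")
        if self.gene_length_range[0] > self.gene_length_range[1] or self.gene_length_range[0] <= 0:
            raise ValueError("invalid gene_length_range")
        if self.intergenic_gap_range[0] <= 0:
            raise ValueError("intergenic gap range would produce non-positive gaps")


def gen_annotation(spec: ChipSimSpec) -> tuple[list[TranscriptModel], dict]:
    """Genes on one synthetic chromosome, alternating strands, with truth.

    Truth flags each gene's length and neighbour-distance eligibility for
    the metagene filters.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = rng.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=spec.n_genes
    )
    short = rng.random(spec.n_genes) < spec.short_fraction
    lengths[short] = rng.integers(1000, spec.min_transcript_length, size=int(short.sum()))

    gaps = rng.integers(
        spec.intergenic_gap_range[0], spec.intergenic_gap_range[1] + 1, size=spec.n_genes
    )
    close = rng.random(spec.n_genes) < spec.close_fraction
    gaps[close] = rng.integers(500, spec.min_gene_distance, size=int(close.sum()))

    transcripts: list[TranscriptModel] = []
    starts = np.empty(spec.n_genes, dtype=int)
    pos = int(gaps[0])
    for i in range(spec.n_genes):
        starts[i] = pos
        strand = "+" if i % 2 == 0 else "-"
        gid = f"gene{i + 1:04d}"
        transcripts.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                interval=GenomicInterval(spec.chrom, pos, pos + int(lengths[i]), strand),
            )
        )
        if i + 1 < spec.n_genes:
            pos = pos + int(lengths[i]) + int(gaps[i + 1])

    truth_genes = []
    for i, tx in enumerate(transcripts):
        gap_left = gaps[i] if i > 0 else np.inf
        gap_right = gaps[i + 1] if i + 1 < spec.n_genes else np.inf
        length_ok = tx.length >= spec.min_transcript_length
        distance_ok = min(gap_left, gap_right) >= spec.min_gene_distance
        truth_genes.append(
            {
                "gene_id": tx.gene_id,
                "length": tx.length,
                "length_ok": bool(length_ok),
                "distance_ok": bool(distance_ok),
                "eligible": bool(length_ok and distance_ok),
            }
        )
    truth = {
        "genes": truth_genes,
        "eligible_genes": [g["gene_id"] for g in truth_genes if g["eligible"]],
        "chrom_length": int(transcripts[-1].interval.end + 25000),
    }
    return transcripts, truth


def _chip_intensity_field(
    transcripts: list[TranscriptModel], spec: ChipSimSpec, chrom_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """(background field, gene-derived field) of Poisson means per base."""
    gene_field = np.zeros(chrom_length)
    for tx in transcripts:
        gene_field[tx.interval.start : tx.interval.end] = spec.body_signal
        if tx.strand == "+":
            lo, hi = tx.tts - spec.tts_peak_upstream, tx.tts + spec.tts_peak_downstream
        else:
            lo, hi = tx.tts - spec.tts_peak_downstream, tx.tts + spec.tts_peak_upstream
        gene_field[max(lo, 0) : min(hi, chrom_length)] = spec.body_signal * spec.tts_peak_factor
    background = np.full(chrom_length, spec.background_signal)
    return background, gene_field


def gen_chip_coverage(
    transcripts: list[TranscriptModel], spec: ChipSimSpec, chrom_length: int | None = None
) -> tuple[dict[str, list[CoverageTrack]], dict]:
    """Poisson coverage tracks per condition x replicate, plus truth.

    Control tracks draw Poisson(background + gene field); treated tracks
    draw Poisson(background + loss_factor * gene field). The simulated
    chromosome emulates a window of the genome, so each track's library
    size is a nominal genome-wide filtered-read count (``library_size``
    with per-replicate log-normal jitter), equal in expectation across
    conditions — occupancy loss at genes then survives depth
    normalization, as it does on real libraries where the affected
    regions are a negligible fraction of the reads. Set
    ``library_size=None`` to use each track's own total signal instead.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if chrom_length is None:
        chrom_length = int(max(tx.interval.end for tx in transcripts) + 25000)
    background, gene_field = _chip_intensity_field(transcripts, spec, chrom_length)
    lam_control = background + gene_field
    lam_treated = background + spec.inhibitor_loss_factor * gene_field

    tracks: dict[str, list[CoverageTrack]] = {"control": [], "treated": []}
    for condition, lam in (("control", lam_control), ("treated", lam_treated)):
        for rep in range(spec.n_replicates):
            depth = rng.poisson(lam).astype(float)
            if spec.library_size is None:
                lib = float(max(depth.sum(), 1.0))
            else:
                lib = float(spec.library_size * np.exp(rng.normal(0, spec.library_size_cv)))
            tracks[condition].append(
                CoverageTrack(
                    depths={spec.chrom: depth},
                    library_size=lib,
                    name=f"{condition}_rep{rep + 1}",
                )
            )
    truth = {
        "expected_body_mean_control": spec.body_signal + spec.background_signal,
        "expected_body_mean_treated": spec.inhibitor_loss_factor * spec.body_signal
        + spec.background_signal,
        "tts_peak_factor": spec.tts_peak_factor,
        "inhibitor_loss_factor": spec.inhibitor_loss_factor,
        "chrom_length": chrom_length,
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# SILAC phosphoproteomics
# ---------------------------------------------------------------------------


@dataclass
class SilacSimSpec:
    """Conditions of the SILAC phospho simulation.

    ``true_log2fc`` is the log2 treated/control change of the true hits
    (negative = dephosphorylation); ``replicate_sd`` is the biological
    spread of the per-replicate log2 difference; ``ratio_noise_cv`` is
    multiplicative noise on individual evidence-row ratios. Half of the
    replicates carry the heavy label on the treated sample, half on the
    control (label flip).
    """

    n_sites: int = 2000
    n_true_hits: int = 30
    true_log2fc: float = -2.0
    replicate_sd: float = 0.25
    n_replicates: int = 4
    ratio_noise_cv: float = 0.05
    missing_rate: float = 0.1
    n_proteins: int = 300
    n_fractions: int = 2
    contaminant_rate: float = 0.02
    decoy_rate: float = 0.01
    nonphospho_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_hits > self.n_sites:
            raise ValueError("n_true_hits must be <= n_sites")
        if self.n_replicates % 2:
            raise ValueError("n_replicates must be even for a balanced label flip")

    @property
    def treated_is_heavy(self) -> list[bool]:
        return [i % 2 == 0 for i in range(self.n_replicates)]


def silac_design(spec: SilacSimSpec) -> pd.DataFrame:
    """Replicate design table: which label the treated sample carries."""
    return pd.DataFrame(
        {
            "replicate": [f"rep{i + 1}" for i in range(spec.n_replicates)],
            "treated_is_heavy": spec.treated_is_heavy,
        }
    )


def gen_silac_tables(spec: SilacSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Evidence table, protein-groups table and truth for the SILAC design.

    Per site and replicate the latent log2 treated/control difference is
    ``true_log2fc`` (hits) or 0 (nulls) plus Normal(0, replicate_sd)
    noise. The H/L ratio of a row is treated/control when the treated
    sample is heavy and its reciprocal when flipped; row intensities and
    ratios are jointly consistent (channel intensities sum to the total
    and their ratio equals the H/L ratio). The protein table carries
    null protein-level changes.
    """
    rng = np.random.default_rng(spec.seed)
    flips = spec.treated_is_heavy

    proteins = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    site_protein = rng.choice(proteins, size=spec.n_sites)
    sequences, seen = [], set()
    while len(sequences) < spec.n_sites:
        pep = _random_tryptic_peptide(rng)
        sty = [i for i, a in enumerate(pep) if a in "STY"]
        if not sty or pep in seen:
            continue
        seen.add(pep)
        sequences.append(pep)
    is_true = np.zeros(spec.n_sites, dtype=bool)
    is_true[rng.choice(spec.n_sites, size=spec.n_true_hits, replace=False)] = True

    rows = []
    truth_sites = []
    for s in range(spec.n_sites):
        pep = sequences[s]
        sty = [i for i, a in enumerate(pep) if a in "STY"]
        mod_pos = int(rng.choice(sty))
        mods = f"{pep[mod_pos]}{mod_pos + 1}:Phospho"
        key = f"{pep}|{mods}"
        prot_pos = int(rng.integers(10, 1000))
        base_intensity = float(rng.lognormal(mean=np.log(5e6), sigma=1.0))
        lfc = spec.true_log2fc if is_true[s] else 0.0
        n_detected = 0
        for rep in range(spec.n_replicates):
            d = lfc + (rng.normal(0, spec.replicate_sd) if spec.replicate_sd > 0 else 0.0)
            control = base_intensity / 2.0
            treated = control * 2.0**d
            ratio_rep = treated / control if flips[rep] else control / treated
            detected = False
            for exp in ("Ti", "IM"):
                if rng.random() < spec.missing_rate:
                    continue
                detected = True
                for frac in range(1, spec.n_fractions + 1):
                    r_row = ratio_rep * (
                        np.exp(rng.normal(0, spec.ratio_noise_cv))
                        if spec.ratio_noise_cv > 0
                        else 1.0
                    )
                    i_row = (control + treated) / spec.n_fractions
                    rows.append(
                        (
                            pep,
                            mods,
                            1,
                            site_protein[s],
                            False,
                            False,
                            i_row,
                            r_row,
                            exp,
                            frac,
                            f"rep{rep + 1}",
                            str(prot_pos),
                            f"raw_{exp}_rep{rep + 1}_f{frac}",
                        )
                    )
            n_detected += int(detected)
        truth_sites.append(
            {
                "key": key,
                "protein": str(site_protein[s]),
                "true_log2fc": float(lfc),
                "is_true_hit": bool(is_true[s]),
                "n_replicates_detected": n_detected,
            }
        )

    # nuisance rows exercising the filters: non-phospho, contaminants, decoys
    n_extra = int(spec.n_sites * (spec.nonphospho_rate + spec.contaminant_rate + spec.decoy_rate))
    for _ in range(n_extra):
        pep = _random_tryptic_peptide(rng)
        kind = rng.random()
        contaminant = kind < spec.contaminant_rate / max(
            spec.nonphospho_rate + spec.contaminant_rate + spec.decoy_rate, 1e-9
        )
        decoy = (not contaminant) and rng.random() < 0.3
        phospho = 0 if (not contaminant and not decoy) else 1
        rows.append(
            (
                pep,
                "" if phospho == 0 else "S1:Phospho",
                phospho,
                "CON_KRT1" if contaminant else ("REV_P0001" if decoy else "P9999"),
                contaminant,
                decoy,
                float(rng.lognormal(np.log(1e6), 1.0)),
                float(np.exp(rng.normal(0, 0.3))),
                rng.choice(["Ti", "IM"]),
                1,
                f"rep{int(rng.integers(1, spec.n_replicates + 1))}",
                "",
                "raw_extra",
            )
        )

    evidence = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )

    # protein-level table: null changes ("no protein changed significantly")
    prot_rows = []
    for p in proteins:
        base = float(rng.lognormal(np.log(1e8), 1.0))
        row: dict = {
            "protein_ids": p,
            "peptide_count": int(rng.integers(2, 30)),
            "is_contaminant": False,
            "is_decoy": False,
        }
        for rep in range(spec.n_replicates):
            d = rng.normal(0, spec.replicate_sd)
            control = base / 2.0
            treated = control * 2.0**d
            ratio = treated / control if flips[rep] else control / treated
            row[f"intensity_rep{rep + 1}"] = control + treated
            row[f"ratio_HL_rep{rep + 1}"] = ratio
        prot_rows.append(row)
    protein_groups = pd.DataFrame(prot_rows)

    truth = {
        "sites": truth_sites,
        "true_hit_keys": [t["key"] for t in truth_sites if t["is_true_hit"]],
        "design": {f"rep{i + 1}": bool(f) for i, f in enumerate(flips)},
        "true_log2fc": spec.true_log2fc,
    }
    return evidence, protein_groups, truth


# ---------------------------------------------------------------------------
# BioID
# ---------------------------------------------------------------------------


@dataclass
class BioidSimSpec:
    """Conditions of the BioID label-free simulation.

    True interactors gain ``true_log2fc`` in the bait condition.
    ``mnar_fraction`` of values go missing by detection-limit censoring:
    the probability of dropping a value falls off logistically above a
    per-column limit placed at the ``mnar_fraction`` quantile, so
    missingness concentrates at genuinely low abundances.
    ``mcar_fraction`` is the small fully-random component. Each protein
    carries a protein-specific preparation offset per block, shared by
    the bait and control sample of that preparation — the structure that
    makes the block factor of the differential model informative.
    ``replicate_sd`` is the residual log2 noise beyond the prep effect.
    """

    n_proteins: int = 1000
    n_true_interactors: int = 50
    true_log2fc: float = 2.0
    mnar_fraction: float = 0.15
    mcar_fraction: float = 0.02
    censoring_width: float = 0.4
    n_replicates: int = 3
    replicate_sd: float = 0.2
    block_sd: float = 0.3
    low_peptide_fraction: float = 0.05
    decoy_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.mnar_fraction, self.mcar_fraction):
            if not 0 <= f <= 1:
                raise ValueError("missingness fractions must be in [0, 1]")
        if self.n_true_interactors > self.n_proteins:
            raise ValueError("n_true_interactors must be <= n_proteins")


def bioid_design(spec: BioidSimSpec) -> pd.DataFrame:
    """Sample sheet: sample, sample_type, replicate, prep_block."""
    rows = []
    for stype in ("bait", "control"):
        for rep in range(1, spec.n_replicates + 1):
            rows.append((f"{stype}_rep{rep}", stype, f"rep{rep}", f"block{rep}"))
    return pd.DataFrame(rows, columns=["sample", "sample_type", "replicate", "prep_block"])


def gen_bioid_table(spec: BioidSimSpec) -> tuple[pd.DataFrame, dict]:
    """Protein-groups table with spiked interactors and MNAR/MCAR holes."""
    rng = np.random.default_rng(spec.seed)
    design = bioid_design(spec)
    samples = list(design["sample"])
    n = spec.n_proteins

    base = rng.normal(25.0, 2.0, size=n)
    is_interactor = np.zeros(n, dtype=bool)
    is_interactor[rng.choice(n, size=spec.n_true_interactors, replace=False)] = True
    # protein-specific preparation offsets, shared within each prep block
    block_offsets = {
        f"block{r}": rng.normal(0, spec.block_sd, size=n)
        for r in range(1, spec.n_replicates + 1)
    }

    log2 = np.empty((n, len(samples)))
    for j, (_, row) in enumerate(design.iterrows()):
        shift = np.where(is_interactor & (row.sample_type == "bait"), spec.true_log2fc, 0.0)
        log2[:, j] = (
            base + shift + block_offsets[row.prep_block] + rng.normal(0, spec.replicate_sd, size=n)
        )

    # MNAR: detection-limit censoring — drop probability decays
    # logistically above the per-column mnar_fraction quantile
    missing = np.zeros_like(log2, dtype=bool)
    if spec.mnar_fraction > 0:
        for j in range(log2.shape[1]):
            limit = np.quantile(log2[:, j], spec.mnar_fraction)
            prob = stats.logistic.cdf(limit - log2[:, j], scale=spec.censoring_width)
            missing[:, j] = rng.random(n) < prob
    missing |= rng.random(log2.shape) < spec.mcar_fraction

    low_pep = rng.random(n) < spec.low_peptide_fraction
    decoy = rng.random(n) < spec.decoy_rate

    table: dict = {
        "protein_ids": [f"REV_B{i + 1:04d}" if decoy[i] else f"B{i + 1:04d}" for i in range(n)],
        "peptide_count": np.where(low_pep, 1, rng.integers(2, 20, size=n)),
        "is_contaminant": np.zeros(n, dtype=bool),
        "is_decoy": decoy,
    }
    for j, sample in enumerate(samples):
        vals = np.power(2.0, log2[:, j])
        vals[missing[:, j]] = np.nan
        table[f"intensity_{sample}"] = vals
        pep = np.where(low_pep, 1, np.maximum(rng.poisson(5, size=n), 2))
        pep = pep.astype(float)
        pep[missing[:, j]] = np.nan
        table[f"peptides_{sample}"] = pep
    df = pd.DataFrame(table)

    truth = {
        "interactors": [
            f"B{i + 1:04d}" for i in range(n) if is_interactor[i] and not decoy[i]
        ],
        "true_log2fc": spec.true_log2fc,
        "low_peptide": [f"B{i + 1:04d}" for i in range(n) if low_pep[i] and not decoy[i]],
        "design": design.to_dict(orient="records"),
    }
    return df, truth


# ---------------------------------------------------------------------------
# Label-incorporation check
# ---------------------------------------------------------------------------


def gen_incorporation_peptides(
    target_efficiency: float,
    n_peptides: int = 300,
    seed: int = 0,
    noise_sd: float = 0.2,
    decoy_fraction: float = 0.15,
) -> tuple[pd.DataFrame, dict]:
    """Peptide table whose per-peptide labeled ratio modes at the target.

    Half of the valid peptides contain exactly one K, half exactly one R.
    Decoy peptides (0 or 2 K/R residues, or an extra non-SILAC
    modification) are included and truth-flagged for exclusion by the
    incorporation estimator. ``noise_sd`` jitters the per-peptide
    efficiency in percentage points (0 gives exact ratios).
    """
    if not 0 <= target_efficiency <= 100:
        raise ValueError("target_efficiency is a percentage in [0, 100]")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []

    def interior(n: int) -> str:
        return "".join(rng.choice(list(AMINO_ACIDS), size=n))

    for i in range(n_peptides):
        n_len = int(rng.integers(7, 26))
        residue = "K" if i % 2 == 0 else "R"
        seq = interior(n_len - 1) + residue
        eff = float(np.clip(target_efficiency + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0), 0, 100))
        total = float(rng.lognormal(np.log(1e7), 0.8))
        rows.append((seq, f"{residue}{n_len}:Label", total * eff / 100.0, total * (1 - eff / 100.0)))
        truth_rows.append({"sequence": seq, "residue_class": residue, "included": True})

    n_decoy = int(n_peptides * decoy_fraction)
    for i in range(n_decoy):
        kind = i % 3
        n_len = int(rng.integers(7, 26))
        if kind == 0:  # no K/R at all
            seq, mods = interior(n_len), ""
        elif kind == 1:  # two K/R (missed cleavage)
            seq = interior(n_len - 2) + "KR"
            mods = f"K{n_len - 1}:Label"
        else:  # extra non-SILAC modification
            seq = interior(n_len - 1) + "K"
            mods = f"K{n_len}:Label;M1:Oxidation"
        total = float(rng.lognormal(np.log(1e6), 0.8))
        rows.append((seq, mods, total * 0.5, total * 0.5))
        truth_rows.append({"sequence": seq, "residue_class": None, "included": False})

    table = pd.DataFrame(
        rows, columns=["sequence", "modifications", "intensity_labeled", "intensity_unlabeled"]
    )
    truth = {"target_efficiency": target_efficiency, "peptides": truth_rows}
    return table, truth
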