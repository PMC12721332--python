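"""SILAC phosphoproteomics workflow.

Starting from a MaxQuant-style evidence table the pipeline (i) keeps
rows with at least one phosphorylation, (ii) drops contaminant and
decoy peptides, (iii) groups rows on sequence + modifications per
replicate with the two phospho enrichments (TiO2 and IMAC) kept apart
— intensities summed, H/L ratios medianed, (iv) combines the two
enrichments of the same replicate (sum of intensities, median of raw
ratios), (v) reconstructs the heavy and light channel intensities from
the summed intensity and the combined ratio, (vi) log2-transforms and
loess-normalizes the channel matrix, and (vii) tests inhibitor vs
control per feature with a moderated paired t that honours the label
flip (which replicates carry the heavy label on the treated sample).

Hits follow the printed thresholds: volcano significance at
p < 0.01 and log2FC <= -1; bar categories red (p < 0.01 and
log2FC < -0.5), pink (log2FC < -0.5 only). The protein-level SILAC
variant runs the same reconstruction/normalization/test on the
protein-groups table with BH adjustment, and the incorporation check
estimates labeling efficiency per residue class as the mode of the
per-peptide modified-peptide ratio histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from quantpipes._stats import (
    ModeratedTestResult,
    benjamini_hochberg,
    loess_normalize,
    moderated_one_sample_t,
)
from quantpipes.formats_io import validate_evidence_table, validate_peptide_table
from quantpipes.thresholds import SignificanceThresholds

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Evidence filtering and grouping
# ---------------------------------------------------------------------------


def canonicalize_modifications(mods: str) -> str:
    """Order-insensitive canonical form of a modifications string."""
    if not isinstance(mods, str) or not mods.strip():
        return ""
    return ";".join(sorted(tok.strip() for tok in mods.split(";") if tok.strip()))


def filter_phospho_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Keep phosphorylated, non-contaminant, non-decoy evidence rows."""
    validate_evidence_table(evidence)
    keep = (
        (evidence["phospho_count"] >= 1)
        & ~evidence["is_contaminant"].astype(bool)
        & ~evidence["is_decoy"].astype(bool)
    )
    out = evidence.loc[keep].copy()
    if out.empty:
        warnings.warn("no evidence rows survive the phospho/contaminant filter", stacklevel=2)
    return out


def group_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Aggregate rows per (feature key, replicate, enrichment experiment).

    The feature key concatenates sequence and canonicalized
    modifications; intensities are summed over rows (fractions, raw
    files), ratios are medianed.
    """
    df = evidence.copy()
    df["key"] = df["sequence"].astype(str) + "|" + df["modifications"].map(canonicalize_modifications)
    grouped = (
        df.groupby(["key", "replicate", "experiment"], sort=True)
        .agg(
            intensity=("intensity_total", "sum"),
            ratio=("ratio_HL", "median"),
            proteins=("proteins", "first"),
            site_positions=("site_positions", "first"),
            sequence=("sequence", "first"),
        )
        .reset_index()
    )
    return grouped


def combine_enrichments(grouped: pd.DataFrame) -> pd.DataFrame:
    """Merge the Ti and IM enrichments of one replicate per feature.

    Combined intensity is the sum of the available enrichment
    intensities; the combined ratio is the median of the available
    enrichment ratios. A feature/replicate is present if at least one
    enrichment observed it.
    """
    combined = (
        grouped.groupby(["key", "replicate"], sort=True)
        .agg(
            intensity=("intensity", "sum"),
            ratio=("ratio", "median"),
            proteins=("proteins", "first"),
            site_positions=("site_positions", "first"),
            sequence=("sequence", "first"),
            n_experiments=("experiment", "nunique"),
        )
        .reset_index()
    )
    return combined


def reconstruct_channels(
    intensity: np.ndarray | float, ratio: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Split a summed intensity into (light, heavy) using the H/L ratio.

    L = I / (1 + r), H = I * r / (1 + r); exact round-trip L + H = I and
    H / L = r. Non-finite or non-positive ratios yield NaN channels (the
    feature is effectively dropped for that replicate).
    """
    i = np.asarray(intensity, dtype=float)
    r = np.asarray(ratio, dtype=float)
    valid = np.isfinite(i) & np.isfinite(r) & (r > 0) & (i >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        light = np.where(valid, i / (1.0 + r), np.nan)
        heavy = np.where(valid, i * r / (1.0 + r), np.nan)
    n_bad = int(np.sum(~valid & np.isfinite(i)))
    if n_bad:
        warnings.warn(f"{n_bad} feature/replicate ratios invalid; channels dropped", stacklevel=2)
    return light, heavy


@dataclass
class ChannelMatrix:
    """log2 channel intensities: features x (2 * replicates).

    Column ``j`` pairs: light of replicate k at ``2k``, heavy at
    ``2k + 1`` (see ``columns``). ``meta`` carries per-feature protein
    ids and site positions.
    """

    values: np.ndarray
    keys: list[str]
    replicates: list[str]
    columns: list[str]
    meta: pd.DataFrame

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def build_channel_matrix(combined: pd.DataFrame, replicates: Sequence[str]) -> ChannelMatrix:
    """Reconstruct channels and assemble the log2 matrix of all features."""
    light, heavy = reconstruct_channels(
        combined["intensity"].to_numpy(), combined["ratio"].to_numpy()
    )
    combined = combined.assign(light=light, heavy=heavy)
    keys = sorted(combined["key"].unique())
    key_index = {k: i for i, k in enumerate(keys)}
    rep_index = {r: i for i, r in enumerate(replicates)}
    values = np.full((len(keys), 2 * len(replicates)), np.nan)
    for row in combined.itertuples():
        if row.replicate not in rep_index:
            continue
        i, k = key_index[row.key], rep_index[row.replicate]
        with np.errstate(divide="ignore"):
            values[i, 2 * k] = np.log2(row.light) if row.light and row.light > 0 else np.nan
            values[i, 2 * k + 1] = np.log2(row.heavy) if row.heavy and row.heavy > 0 else np.nan
    meta = (
        combined.groupby("key")
        .agg(proteins=("proteins", "first"), site_positions=("site_positions", "first"),
             sequence=("sequence", "first"))
        .reindex(keys)
        .reset_index()
    )
    columns = [f"{ch}_{r}" for r in replicates for ch in ("L", "H")]
    return ChannelMatrix(
        values=values, keys=keys, replicates=list(replicates), columns=columns, meta=meta
    )


# ---------------------------------------------------------------------------
# Differential testing
# ---------------------------------------------------------------------------


def _design_flips(design: pd.DataFrame, replicates: Sequence[str]) -> list[bool]:
    mapping = dict(zip(design["replicate"].astype(str), design["treated_is_heavy"].astype(bool)))
    missing = [r for r in replicates if r not in mapping]
    if missing:
        raise ValueError(f"design table lacks replicates {missing}")
    return [mapping[r] for r in replicates]


def paired_differences(matrix: ChannelMatrix, design: pd.DataFrame) -> np.ndarray:
    """Per-replicate log2(treated) - log2(control) honouring the flip.

    A replicate contributes only where both channels were reconstructed.
    """
    flips = _design_flips(design, matrix.replicates)
    diffs = np.full((len(matrix.keys), matrix.n_replicates), np.nan)
    for k, treated_is_heavy in enumerate(flips):
        light = matrix.values[:, 2 * k]
        heavy = matrix.values[:, 2 * k + 1]
        treated, control = (heavy, light) if treated_is_heavy else (light, heavy)
        diffs[:, k] = treated - control
    return diffs


def paired_differential_test(
    matrix: ChannelMatrix,
    design: pd.DataFrame,
    moderated: bool = True,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Moderated (or plain) paired test of treated vs control per feature.

    Features with fewer than ``min_replicates`` complete replicates keep
    their log2FC but get no p-value (flagged via ``n_reps``).
    """
    diffs = paired_differences(matrix, design)
    res: ModeratedTestResult = moderated_one_sample_t(
        diffs, moderated=moderated, min_replicates=min_replicates
    )
    out = pd.DataFrame(
        {
            "key": matrix.keys,
            "log2fc": res.effect,
            "t": res.t,
            "p": res.p,
            "n_reps": res.n_used,
        }
    )
    return out.merge(matrix.meta, on="key", how="left")


def call_hits(
    results: pd.DataFrame, thresholds: SignificanceThresholds | None = None
) -> pd.DataFrame:
    """Apply the printed cut-offs: volcano significance and bar category.

    Also reports the mirror check — features *increasing* at the same
    stringency — in the ``increased`` column (expected empty when the
    perturbation only removes phosphorylation).
    """
    th = thresholds or SignificanceThresholds()
    out = results.copy()
    p = out["p"].to_numpy()
    fc = out["log2fc"].to_numpy()
    sig_p = np.isfinite(p) & (p < th.volcano_p)
    out["volcano_significant"] = sig_p & (fc <= th.volcano_log2fc)
    out["increased"] = sig_p & (fc >= -th.volcano_log2fc)
    category = np.full(len(out), "none", dtype=object)
    category[fc < th.bar_log2fc] = "pink"
    category[(fc < th.bar_log2fc) & sig_p] = "red"
    out["bar_category"] = category
    return out


def run_phospho_pipeline(
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    thresholds: SignificanceThresholds | None = None,
    moderated: bool = True,
    normalize: bool = True,
) -> dict:
    """End-to-end phosphopeptide workflow; returns results and the matrix."""
    filtered = filter_phospho_evidence(evidence)
    grouped = group_evidence(filtered)
    combined = combine_enrichments(grouped)
    replicates = sorted(design["replicate"].astype(str))
    matrix = build_channel_matrix(combined, replicates)
    if normalize:
        matrix.values = loess_normalize(matrix.values)
    results = call_hits(paired_differential_test(matrix, design, moderated=moderated), thresholds)
    return {
        "results": results,
        "matrix": matrix,
        "n_rows_filtered": len(evidence) - len(filtered),
        "n_features": len(matrix.keys),
    }


# ---------------------------------------------------------------------------
# Protein-level SILAC
# ---------------------------------------------------------------------------


def protein_level_pipeline(
    protein_groups: pd.DataFrame,
    design: pd.DataFrame,
    moderated: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Protein-level SILAC: channel reconstruction, loess, paired test, BH.

    Expects wide per-replicate ``intensity_<rep>`` and ``ratio_HL_<rep>``
    columns; decoy and contaminant rows are removed first.
    """
    df = protein_groups.loc[
        ~protein_groups["is_contaminant"].astype(bool) & ~protein_groups["is_decoy"].astype(bool)
    ].reset_index(drop=True)
    replicates = sorted(design["replicate"].astype(str))
    values = np.full((len(df), 2 * len(replicates)), np.nan)
    for k, rep in enumerate(replicates):
        light, heavy = reconstruct_channels(
            df[f"intensity_{rep}"].to_numpy(), df[f"ratio_HL_{rep}"].to_numpy()
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            values[:, 2 * k] = np.where(light > 0, np.log2(light), np.nan)
            values[:, 2 * k + 1] = np.where(heavy > 0, np.log2(heavy), np.nan)
    matrix = ChannelMatrix(
        values=values,
        keys=list(df["protein_ids"]),
        replicates=replicates,
        columns=[f"{ch}_{r}" for r in replicates for ch in ("L", "H")],
        meta=pd.DataFrame({"key": df["protein_ids"]}),
    )
    if normalize:
        matrix.values = loess_normalize(matrix.values)
    res = paired_differential_test(matrix, design, moderated=moderated)
    res = res.rename(columns={"key": "protein_ids"})
    res["p_adj"] = benjamini_hochberg(res["p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# Per-protein summaries and motif analysis
# ---------------------------------------------------------------------------


def protein_phospho_summary(
    results: pd.DataFrame, min_replicates: int = 2
) -> pd.DataFrame:
    """Per-protein bar table: >= min_replicates detections, sorted by log2FC.

    Mirrors the published per-protein phosphopeptide graphs: features
    identified in at least two replicates, ordered ascending by log2
    fold-change, with the bar category attached.
    """
    if "bar_category" not in results.columns:
        results = call_hits(results)
    kept = results.loc[results["n_reps"] >= min_replicates].copy()
    kept = kept.sort_values(["proteins", "log2fc", "key"], kind="mergesort").reset_index(drop=True)
    cols = ["proteins", "key", "site_positions", "log2fc", "p", "n_reps", "bar_category"]
    return kept[[c for c in cols if c in kept.columns]]


AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")


def motif_matrix(
    sites: Sequence[tuple[str, int]],
    protein_sequences: Mapping[str, str],
    flank: int = 6,
) -> tuple[pd.DataFrame, float]:
    """Position frequency matrix of +/-flank windows around phospho-sites.

    ``sites`` holds (protein id, 1-based residue position) pairs. Windows
    at protein termini are padded with ``-`` (excluded from column
    frequencies). Returns the PFM (rows = amino acids, columns =
    -flank..+flank) and the fraction of windows with proline at +1 — the
    proline-directed consensus expected of CDK substrates.
    """
    counts = np.zeros((len(AA_ORDER), 2 * flank + 1))
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    n_windows = 0
    n_pro_plus1 = 0
    for protein, pos in sites:
        seq = protein_sequences.get(protein)
        if seq is None or not (1 <= pos <= len(seq)):
            warnings.warn(f"site {protein}:{pos} outside sequence; skipped", stacklevel=2)
            continue
        n_windows += 1
        center = pos - 1
        for offset in range(-flank, flank + 1):
            idx = center + offset
            if 0 <= idx < len(seq):
                aa = seq[idx]
                if aa in aa_index:
                    counts[aa_index[aa], offset + flank] += 1
        if center + 1 < len(seq) and seq[center + 1] == "P":
            n_pro_plus1 += 1
    pfm = pd.DataFrame(counts, index=AA_ORDER, columns=[str(o) for o in range(-flank, flank + 1)])
    fraction = n_pro_plus1 / n_windows if n_windows else np.nan
    return pfm, fraction


# ---------------------------------------------------------------------------
# Label-incorporation check
# ---------------------------------------------------------------------------


def _is_silac_only(mods: str) -> bool:
    """True if every modification token is SILAC-related (or none)."""
    canon = canonicalize_modifications(mods)
    if not canon:
        return True
    return all(tok.endswith(":Label") for tok in canon.split(";"))


def incorporation_efficiency(
    peptides: pd.DataFrame, bin_width: float = 0.5
) -> dict[str, float | None]:
    """Labeling efficiency per residue class from the ratio histogram mode.

    Keeps peptides with exactly one K xor one R and no non-SILAC
    modification, computes the modified-peptide ratio
    labeled / (labeled + unlabeled) * 100 per peptide, histograms it with
    ``bin_width`` percentage-point bins, and reports the modal bin's
    midpoint per class (ties resolved toward higher efficiency). Classes
    without peptides report None.
    """
    validate_peptide_table(peptides)
    out: dict[str, float | None] = {}
    seq = peptides["sequence"].astype(str)
    n_k = seq.str.count("K")
    n_r = seq.str.count("R")
    silac_only = peptides["modifications"].map(_is_silac_only)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    for residue, mask in (("K", (n_k == 1) & (n_r == 0)), ("R", (n_r == 1) & (n_k == 0))):
        sel = peptides.loc[mask & silac_only]
        if sel.empty:
            out[residue] = None
            continue
        labeled = sel["intensity_labeled"].to_numpy(dtype=float)
        unlabeled = sel["intensity_unlabeled"].to_numpy(dtype=float)
        total = labeled + unlabeled
        ratios = np.where(total > 0, labeled / np.where(total > 0, total, 1.0) * 100.0, np.nan)
        ratios = ratios[np.isfinite(ratios)]
        hist, _ = np.histogram(ratios, bins=edges)
        modal = len(hist) - 1 - int(np.argmax(hist[::-1]))  # ties -> higher bin
        out[residue] = float((edges[modal] + edges[modal + 1]) / 2.0)
    return out
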