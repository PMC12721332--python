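"""BioID label-free differential-enrichment workflow.

From a protein-groups table with per-sample intensities: (i) decoy and
contaminant groups are removed, (ii) intensities are log2-transformed,
(iii) loess-normalized, (iv) proteins not quantified in at least two
replicates of at least one sample type are filtered out, requiring also
at least two peptides in at least one replicate of a single sample
type, (v) remaining missing values are imputed per sample column with a
left-censored Gaussian draw (centered half a column-SD below the 1st
percentile, SD 0.3 column-SD — low-abundance missingness), and (vi)
enrichment of bait over control is tested per protein with a moderated
t on the condition coefficient of a fixed-effect linear model that
includes the sample-preparation block, BH-adjusted across proteins.
A protein is called enriched at adjusted p < 0.05 and log2FC >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from quantpipes._stats import benjamini_hochberg, loess_normalize, moderated_lm
from quantpipes.formats_io import validate_protein_group_table
from quantpipes.thresholds import SignificanceThresholds

logger = logging.getLogger(__name__)


def clean_protein_groups(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove decoy hits and contaminant protein groups."""
    validate_protein_group_table(table)
    keep = ~table["is_decoy"].astype(bool) & ~table["is_contaminant"].astype(bool)
    removed = int((~keep).sum())
    return table.loc[keep].reset_index(drop=True), removed


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "sample_type", "replicate", "prep_block"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns {sorted(missing)}")
    bad = set(design["sample_type"]) - {"bait", "control"}
    if bad:
        raise ValueError(f"sample_type must be bait or control, found {sorted(bad)}")
    return design


def log2_intensity_matrix(table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """log2 of ``intensity_<sample>`` columns, proteins x samples, NaN kept."""
    _check_design(design)
    cols = {s: f"intensity_{s}" for s in design["sample"]}
    missing = [c for c in cols.values() if c not in table.columns]
    if missing:
        raise ValueError(f"protein-groups table lacks sample columns {missing}")
    mat = pd.DataFrame(index=table["protein_ids"])
    for sample, col in cols.items():
        vals = table[col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            mat[sample] = np.where(vals > 0, np.log2(vals), np.nan)
    return mat


def presence_filter(
    table: pd.DataFrame, design: pd.DataFrame, matrix: pd.DataFrame | None = None
) -> np.ndarray:
    """Boolean keep-mask implementing the replicate/peptide presence rule.

    Keep a protein iff some sample type has it quantified in >= 2
    replicates AND some sample type has >= 2 peptides in at least one
    replicate.
    """
    _check_design(design)
    if matrix is None:
        matrix = log2_intensity_matrix(table, design)
    quant_ok = np.zeros(len(table), dtype=bool)
    pep_ok = np.zeros(len(table), dtype=bool)
    for stype, sub in design.groupby("sample_type"):
        samples = list(sub["sample"])
        n_quant = matrix[samples].notna().sum(axis=1).to_numpy()
        quant_ok |= n_quant >= 2
        pep_cols = [f"peptides_{s}" for s in samples if f"peptides_{s}" in table.columns]
        if pep_cols:
            peps = np.nan_to_num(
                np.column_stack([table[c].to_numpy(dtype=float) for c in pep_cols])
            )
            pep_ok |= peps.max(axis=1) >= 2
        else:
            # no per-sample peptide columns: fall back to the group-level count
            pep_ok |= table["peptide_count"].to_numpy(dtype=float) >= 2
    return quant_ok & pep_ok


def impute_missing(
    matrix: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-censored imputation per sample column, deterministic per seed.

    Missing cells of a column are drawn from
    Normal(q01 - 0.5 * sd, (0.3 * sd)^2) where q01 and sd are the
    column's observed 1st percentile and standard deviation. Returns the
    completed matrix and a boolean mask of imputed cells.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    mask = matrix.isna()
    for col in matrix.columns:
        vals = matrix[col].to_numpy(dtype=float)
        obs = vals[np.isfinite(vals)]
        if obs.size == 0:
            raise ValueError(f"sample column {col!r} is entirely missing; cannot impute")
        q01 = np.percentile(obs, 1.0)
        sd = obs.std(ddof=1) if obs.size > 1 else 1.0
        n_missing = int(mask[col].sum())
        if n_missing:
            draws = rng.normal(q01 - 0.5 * sd, 0.3 * sd, size=n_missing)
            out.loc[mask[col], col] = draws
    return out, mask


@dataclass
class BlockedDesign:
    """Design matrix of the blocked fixed-effect model."""

    matrix: np.ndarray
    coef_index: int
    columns: list[str]


def build_design_matrix(design: pd.DataFrame, samples: list[str]) -> BlockedDesign:
    """Intercept + bait indicator + block dummies (first block reference)."""
    d = _check_design(design).set_index("sample").loc[samples]
    bait = (d["sample_type"] == "bait").astype(float).to_numpy()
    blocks = sorted(d["prep_block"].unique())
    cols = [np.ones(len(samples)), bait]
    names = ["intercept", "bait"]
    for b in blocks[1:]:
        cols.append((d["prep_block"] == b).astype(float).to_numpy())
        names.append(f"block_{b}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("block factor is confounded with sample type")
    return BlockedDesign(matrix=X, coef_index=1, columns=names)


def blocked_differential(
    matrix: pd.DataFrame, design: pd.DataFrame, moderated: bool = True
) -> pd.DataFrame:
    """Per-protein moderated t on bait vs control adjusting for prep block."""
    samples = list(matrix.columns)
    bd = build_design_matrix(design, samples)
    res = moderated_lm(matrix.to_numpy(dtype=float), bd.matrix, bd.coef_index, moderated=moderated)
    out = pd.DataFrame(
        {
            "protein_ids": matrix.index,
            "log2fc": res.effect,
            "t": res.t,
            "p": res.p,
        }
    )
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def call_enriched(
    results: pd.DataFrame, thresholds: SignificanceThresholds | None = None
) -> pd.DataFrame:
    """Flag enriched proteins: adjusted p < 0.05 and log2FC >= 1.

    The fold-change boundary is inclusive by default (the >=1 log2
    convention); set ``bioid_log2fc_inclusive=False`` on the thresholds
    for the strict >2-fold reading.
    """
    th = thresholds or SignificanceThresholds()
    out = results.copy()
    fc = out["log2fc"].to_numpy()
    if th.bioid_log2fc_inclusive:
        fc_ok = fc >= th.bioid_log2fc
    else:
        fc_ok = fc > th.bioid_log2fc
    out["enriched"] = (out["p_adj"].to_numpy() < th.bioid_padj) & fc_ok
    return out


def run_bioid_pipeline(
    table: pd.DataFrame,
    design: pd.DataFrame,
    seed: int,
    thresholds: SignificanceThresholds | None = None,
    moderated: bool = True,
    normalize: bool = True,
) -> dict:
    """End-to-end BioID workflow; deterministic given the seed.

    Steps run in the published order: clean, log2, loess-normalize,
    presence filter, impute, blocked moderated test, enrichment call.
    """
    cleaned, n_removed = clean_protein_groups(table)
    matrix = log2_intensity_matrix(cleaned, design)
    if normalize:
        matrix.loc[:, :] = loess_normalize(matrix.to_numpy(dtype=float))
    keep = presence_filter(cleaned, design, matrix)
    cleaned = cleaned.loc[keep].reset_index(drop=True)
    matrix = matrix.loc[keep]
    imputed, imputed_mask = impute_missing(matrix, seed)
    results = call_enriched(blocked_differential(imputed, design, moderated=moderated), thresholds)
    return {
        "results": results,
        "matrix": imputed,
        "imputed_mask": imputed_mask,
        "n_decoy_contaminant_removed": n_removed,
        "n_presence_filtered": int((~keep).sum()),
    }
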