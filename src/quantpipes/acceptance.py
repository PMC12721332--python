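"""Self-contained acceptance suite: recompute headline quantities from scratch.

Each entry of the report re-runs one verification end to end on freshly
generated synthetic data — bin-scheme shape, brute-force coverage and
Wilcoxon oracles, null calibration and signal detection of the metagene
tests, SILAC channel round-trip and spike-in recovery, the labeling
efficiency estimator, BioID determinism and spike-in recovery, and the
shift-removal property of the loess normalizer. The oracles here are
deliberately naive re-implementations (per-base loops, exhaustive sign
enumeration), independent of the library code they check.

The report is a JSON-serializable dict ``{name: {"value": v, "n": n}}``.
"""

from __future__ import annotations

import itertools
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from quantpipes._stats import loess_normalize
from quantpipes.bioid_enrichment import run_bioid_pipeline
from quantpipes.formats_io import CoverageTrack, GenomicInterval, TranscriptModel
from quantpipes.metagene import (
    BinScheme,
    BinSchemeConfig,
    build_bin_scheme,
    compute_binned_coverage,
    filter_transcripts,
    run_metagene,
    wilcoxon_paired,
)
from quantpipes.silac_phospho import (
    incorporation_efficiency,
    reconstruct_channels,
    run_phospho_pipeline,
)
from quantpipes.synthetic_data import (
    BioidSimSpec,
    ChipSimSpec,
    SilacSimSpec,
    bioid_design,
    gen_annotation,
    gen_bioid_table,
    gen_chip_coverage,
    gen_incorporation_peptides,
    gen_silac_tables,
    silac_design,
)

logger = logging.getLogger(__name__)

_MOD = 2**31 - 1


def _subseed(seed: int, k: int) -> int:
    """Derived stream seed, kept within a 31-bit range."""
    return (seed * 1000003 + k) % _MOD


def _entry(value: float, n: int) -> dict:
    return {"value": float(value), "n": int(n)}


# ---------------------------------------------------------------------------
# Oracles (naive by design)
# ---------------------------------------------------------------------------


def brute_force_binned(track: CoverageTrack, scheme: BinScheme) -> np.ndarray:
    """Per-base loop version of compute_binned_coverage for one gene."""
    out = np.zeros(len(scheme))
    for i, (s, e) in enumerate(zip(scheme.starts, scheme.ends)):
        total = 0.0
        for pos in range(s, e):
            vals = track.values(scheme.transcript.chrom, pos, pos + 1)
            total += float(vals[0]) if len(vals) else 0.0
        out[i] = total / (e - s) * 1e6 / track.library_size
    return out


def enumerate_wilcoxon(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign flips."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n < 2:
        return 1.0
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product((0, 1), repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all, dtype=float)
    mean_w = n * (n + 1) / 4.0
    count = np.sum(np.abs(w_all - mean_w) >= np.abs(w_obs - mean_w) - 1e-9)
    return float(count) / len(w_all)


# ---------------------------------------------------------------------------
# Individual checks
# ---------------------------------------------------------------------------


def check_bin_scheme(seed: int) -> dict:
    spec = ChipSimSpec(n_genes=40, seed=_subseed(seed, 1))
    transcripts, _ = gen_annotation(spec)
    eligible = filter_transcripts(transcripts, BinSchemeConfig())
    counts = {"tss": set(), "body": set(), "tts": set()}
    for tx in eligible:
        scheme = build_bin_scheme(tx)
        parts = np.asarray(scheme.parts)
        counts["tss"].add(int((parts == "tss").sum()))
        counts["body"].add(int((parts == "body").sum()))
        counts["tts"].add(int((parts == "tts").sum()))
    n = len(eligible)

    def only(part: str) -> float:
        vals = counts[part]
        return float(vals.pop()) if len(vals) == 1 else float("nan")

    return {
        "bin_scheme_tss_bins": _entry(only("tss"), n),
        "bin_scheme_body_bins": _entry(only("body"), n),
        "bin_scheme_tts_bins": _entry(only("tts"), n),
    }


def check_binned_coverage_oracle(seed: int, n_tracks: int = 50) -> dict:
    rng = np.random.default_rng(_subseed(seed, 2))
    worst = 0.0
    config = BinSchemeConfig(
        tss_upstream=200,
        tss_downstream=100,
        tss_bin=50,
        tts_upstream=100,
        tts_downstream=200,
        tts_bin=50,
        body_bins=7,
        min_transcript_length=210,
        min_gene_distance=0,
    )
    for i in range(n_tracks):
        length = int(rng.integers(400, 900))
        start = int(rng.integers(0, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        tx = TranscriptModel(
            gene_id="g",
            transcript_id="t",
            interval=GenomicInterval("c", start, start + length, strand),
        )
        scheme = build_bin_scheme(tx, config)
        depth = rng.poisson(3.0, size=start + length + 300).astype(float)
        track = CoverageTrack(
            name=f"toy{i}", depths={"c": depth}, library_size=float(depth.sum())
        )
        fast = compute_binned_coverage(track, [scheme]).values[0]
        slow = brute_force_binned(track, scheme)
        worst = max(worst, float(np.max(np.abs(fast - slow))))
    return {"binned_coverage_max_abs_error": _entry(worst, n_tracks)}


def check_wilcoxon_oracle(seed: int, n_trials: int = 200) -> dict:
    rng = np.random.default_rng(_subseed(seed, 3))
    worst = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(2, 13))
        x = rng.normal(0, 1, size=n)
        y = rng.normal(0.3, 1, size=n)
        _, p, n_eff = wilcoxon_paired(x, y)
        if n_eff < 2:
            continue
        p_ref = enumerate_wilcoxon(x - y)
        worst = max(worst, abs(p - p_ref))
    return {"wilcoxon_exact_max_abs_error": _entry(worst, n_trials)}


def _metagene_run(seed: int, loss: float) -> pd.DataFrame:
    spec = ChipSimSpec(
        n_genes=200, n_replicates=2, inhibitor_loss_factor=loss, seed=seed
    )
    transcripts, _ = gen_annotation(spec)
    tracks, _ = gen_chip_coverage(transcripts, spec)
    res = run_metagene(
        transcripts,
        control_tracks=tracks["control"],
        treated_tracks=tracks["treated"],
        reference_tracks=tracks["control"],
    )
    return res["tests"]


def check_metagene_null(seed: int) -> dict:
    tests = _metagene_run(_subseed(seed, 4), loss=1.0)
    ok = ~tests["degenerate"]
    frac = float((tests.loc[ok, "p"] < 0.05).mean())
    return {"metagene_null_raw_p_lt_05_fraction": _entry(frac, int(ok.sum()))}


def check_metagene_signal(seed: int) -> dict:
    tests = _metagene_run(_subseed(seed, 5), loss=0.2)
    body = tests[tests["part"] == "body"]
    frac = float(body["category"].isin(["red", "orange", "yellow"]).mean())
    return {"metagene_signal_body_significant_fraction": _entry(frac, len(body))}


def check_silac_roundtrip(seed: int, n: int = 10_000) -> dict:
    rng = np.random.default_rng(_subseed(seed, 6))
    intensity = rng.lognormal(np.log(1e7), 1.5, size=n)
    ratio = rng.lognormal(0.0, 1.0, size=n)
    light, heavy = reconstruct_channels(intensity, ratio)
    err = np.maximum(
        np.abs((light + heavy) - intensity) / intensity,
        np.abs(heavy / light - ratio) / ratio,
    )
    return {"silac_roundtrip_max_rel_error": _entry(float(err.max()), n)}


def check_silac_spikein(seed: int) -> dict:
    spec = SilacSimSpec(seed=_subseed(seed, 7))
    evidence, _, truth = gen_silac_tables(spec)
    design = silac_design(spec)
    res = run_phospho_pipeline(evidence, design)["results"]
    true_keys = set(truth["true_hit_keys"])
    is_true = res["key"].isin(true_keys)
    sens = float(res.loc[is_true, "volcano_significant"].mean())
    fpr = float(res.loc[~is_true, "volcano_significant"].mean())
    return {
        "silac_spikein_sensitivity": _entry(sens, int(is_true.sum())),
        "silac_null_false_call_rate": _entry(fpr, int((~is_true).sum())),
    }


def check_incorporation(seed: int) -> dict:
    target = 99.5
    table, _ = gen_incorporation_peptides(
        target, noise_sd=0.0, seed=_subseed(seed, 8)
    )
    est = incorporation_efficiency(table)
    return {
        "incorporation_abs_error_K_pp": _entry(abs(est["K"] - target), 1),
        "incorporation_abs_error_R_pp": _entry(abs(est["R"] - target), 1),
    }


def check_bioid(seed: int) -> dict:
    spec = BioidSimSpec(seed=_subseed(seed, 9))
    table, truth = gen_bioid_table(spec)
    design = bioid_design(spec)
    run_seed = _subseed(seed, 10)
    first = run_bioid_pipeline(table, design, seed=run_seed)["results"]
    second = run_bioid_pipeline(table, design, seed=run_seed)["results"]
    identical = float(first.equals(second))
    tested = first["protein_ids"].isin(set(truth["interactors"]))
    sens = float(first.loc[tested, "enriched"].mean())
    return {
        "bioid_determinism_identical": _entry(identical, len(first)),
        "bioid_spikein_sensitivity": _entry(sens, int(tested.sum())),
    }


def check_loess_shift(seed: int) -> dict:
    rng = np.random.default_rng(_subseed(seed, 11))
    mu = rng.normal(20, 2, size=(500, 1))
    mat = mu + rng.normal(0, 0.05, size=(500, 6))
    mat[:, 2] += 1.0
    norm = loess_normalize(mat)
    others = np.delete(norm, 2, axis=1).mean(axis=1)
    residual = float(np.abs(np.median(norm[:, 2] - others)))
    return {"loess_shift_residual": _entry(residual, mat.shape[0])}


CHECKS: Sequence = (
    check_bin_scheme,
    check_binned_coverage_oracle,
    check_wilcoxon_oracle,
    check_metagene_null,
    check_metagene_signal,
    check_silac_roundtrip,
    check_silac_spikein,
    check_incorporation,
    check_bioid,
    check_loess_shift,
)


def run_acceptance(seed: int) -> dict:
    """Run every check and return the combined report dict."""
    report: dict = {}
    for check in CHECKS:
        logger.info("running %s", check.__name__)
        report.update(check(seed))
    return report


def write_report(report: dict, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
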