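"""SILAC phospho workflow: grouping, channels, testing, motifs, labeling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from quantpipes.silac_phospho import (
    build_channel_matrix,
    call_hits,
    canonicalize_modifications,
    combine_enrichments,
    filter_phospho_evidence,
    group_evidence,
    incorporation_efficiency,
    motif_matrix,
    paired_differences,
    protein_level_pipeline,
    protein_phospho_summary,
    reconstruct_channels,
    run_phospho_pipeline,
)
from quantpipes.synthetic_data import SilacSimSpec, gen_silac_tables, silac_design
from quantpipes.thresholds import SignificanceThresholds


class TestGrouping:
    def test_canonicalization_is_order_insensitive(self):
        a = canonicalize_modifications("S4:Phospho; K6:Label")
        b = canonicalize_modifications("K6:Label;S4:Phospho")
        assert a == b == "K6:Label;S4:Phospho"
        assert canonicalize_modifications("") == ""
        assert canonicalize_modifications(float("nan")) == ""

    def test_filter_drops_nonphospho_contaminants_decoys(self, evidence_table):
        df = evidence_table(
            [
                {},
                {"phospho_count": 0},
                {"is_contaminant": True},
                {"is_decoy": True},
            ]
        )
        kept = filter_phospho_evidence(df)
        assert len(kept) == 1

    def test_group_and_combine_match_naive_oracle(self, evidence_table):
        rng = np.random.default_rng(17)
        rows = []
        for _ in range(80):
            rows.append(
                {
                    "sequence": rng.choice(["AASPK", "TTSPR", "GGSPK"]),
                    "modifications": rng.choice(["S3:Phospho", "S3:Phospho; K5:Label"]),
                    "replicate": rng.choice(["rep1", "rep2"]),
                    "experiment": rng.choice(["Ti", "IM"]),
                    "fraction": int(rng.integers(1, 4)),
                    "intensity_total": float(rng.lognormal(14, 1)),
                    "ratio_HL": float(rng.lognormal(0, 0.3)),
                }
            )
        df = evidence_table(rows)
        grouped = group_evidence(filter_phospho_evidence(df))
        combined = combine_enrichments(grouped)

        # naive double group-by oracle with canonical keys
        naive = df.copy()
        naive["key"] = naive["sequence"].astype(str) + "|" + naive[
            "modifications"
        ].map(canonicalize_modifications)
        lvl1 = naive.groupby(["key", "replicate", "experiment"]).agg(
            intensity=("intensity_total", "sum"), ratio=("ratio_HL", "median")
        )
        lvl2 = lvl1.groupby(["key", "replicate"]).agg(
            intensity=("intensity", "sum"), ratio=("ratio", "median")
        )
        merged = combined.set_index(["key", "replicate"])[["intensity", "ratio"]]
        assert np.allclose(merged["intensity"], lvl2.loc[merged.index, "intensity"])
        assert np.allclose(merged["ratio"], lvl2.loc[merged.index, "ratio"])


class TestChannels:
    def test_roundtrip_identities_to_1e_12(self):
        rng = np.random.default_rng(4)
        i = rng.lognormal(np.log(1e7), 2, size=10_000)
        r = rng.lognormal(0, 1.5, size=10_000)
        light, heavy = reconstruct_channels(i, r)
        assert np.allclose(light + heavy, i, rtol=1e-12)
        assert np.allclose(heavy / light, r, rtol=1e-12)

    def test_invalid_ratio_yields_nan_with_warning(self):
        with pytest.warns(UserWarning, match="invalid"):
            light, heavy = reconstruct_channels(
                np.array([100.0, 100.0]), np.array([2.0, -1.0])
            )
        assert np.isfinite(light[0]) and np.isnan(light[1]) and np.isnan(heavy[1])

    def test_label_flip_sign_bookkeeping(self, evidence_table):
        # one site measured at ratio 4 in a treated=Heavy replicate and
        # ratio 1/4 in a flipped replicate encodes the same log2FC = +2
        df = evidence_table(
            [
                {"replicate": "rep1", "ratio_HL": 4.0},
                {"replicate": "rep2", "ratio_HL": 0.25},
            ]
        )
        combined = combine_enrichments(group_evidence(df))
        matrix = build_channel_matrix(combined, ["rep1", "rep2"])
        design = pd.DataFrame(
            {"replicate": ["rep1", "rep2"], "treated_is_heavy": [True, False]}
        )
        diffs = paired_differences(matrix, design)
        assert np.allclose(diffs, 2.0)


class TestCallHits:
    def make_results(self, fc, p):
        return pd.DataFrame({"key": [f"k{i}" for i in range(len(fc))], "log2fc": fc, "p": p})

    def test_volcano_boundaries_inclusive_fc_exclusive_p(self):
        res = call_hits(
            self.make_results(
                fc=[-1.0, -0.99, -1.5, -1.5, 1.2],
                p=[0.009, 0.009, 0.01, 0.0005, 0.001],
            )
        )
        assert list(res["volcano_significant"]) == [True, False, False, True, False]
        assert list(res["increased"]) == [False, False, False, False, True]

    def test_bar_categories_at_minus_half(self):
        res = call_hits(
            self.make_results(fc=[-0.4, -0.6, -0.6], p=[0.5, 0.5, 0.001])
        )
        assert list(res["bar_category"]) == ["none", "pink", "red"]


@pytest.fixture(scope="module")
def pipeline_run():
    spec = SilacSimSpec(seed=11)
    evidence, proteins, truth = gen_silac_tables(spec)
    design = silac_design(spec)
    res = run_phospho_pipeline(evidence, design)
    return spec, evidence, proteins, truth, design, res


class TestSpikeIn:
    def test_sensitivity_and_false_calls(self, pipeline_run):
        *_, truth, _, res = pipeline_run
        results = res["results"]
        is_true = results["key"].isin(set(truth["true_hit_keys"]))
        assert is_true.sum() == 30
        assert results.loc[is_true, "volcano_significant"].mean() >= 0.9
        assert results.loc[~is_true, "volcano_significant"].mean() <= 0.005

    def test_spiked_log2fc_recovered(self, pipeline_run):
        *_, truth, _, res = pipeline_run
        results = res["results"]
        is_true = results["key"].isin(set(truth["true_hit_keys"]))
        assert results.loc[is_true, "log2fc"].mean() == pytest.approx(-2.0, abs=0.25)

    def test_protein_level_is_null_with_bh_column(self, pipeline_run):
        spec, _, proteins, _, design, _ = pipeline_run
        res = protein_level_pipeline(proteins, design)
        assert "p_adj" in res.columns
        assert (res["p_adj"].dropna() >= res["p"].dropna()).all()
        assert (res["p_adj"].dropna() < 0.05).mean() < 0.01

    def test_protein_summary_sorted_and_filtered(self, pipeline_run):
        *_, res = pipeline_run
        summary = protein_phospho_summary(res["results"])
        assert (summary["n_reps"] >= 2).all()
        assert list(summary["proteins"]) == sorted(summary["proteins"])


class TestMotif:
    def test_pfm_counts_and_proline_fraction(self):
        seqs = {"P1": "AAAASPAAAAAA", "P2": "GGGGSPGGGGGG"}
        sites = [("P1", 5), ("P2", 5)]
        pfm, pro_frac = motif_matrix(sites, seqs, flank=3)
        assert pfm.shape[1] == 7
        assert pro_frac == 1.0  # both sites have P at +1
        assert pfm.loc["P", "1"] == 2  # +1 column holds two prolines
        assert pfm["0"].sum() == 2  # center column fully occupied

    def test_terminal_sites_truncate_window_and_bad_sites_warn(self):
        pfm, pro_frac = motif_matrix([("P1", 1)], {"P1": "SPAA"}, flank=3)
        assert pro_frac == 1.0
        assert pfm["-1"].sum() == 0  # nothing upstream of residue 1
        with pytest.warns(UserWarning, match="skipped"):
            _, frac = motif_matrix([("P1", 99)], {"P1": "SPAA"}, flank=3)
        assert np.isnan(frac)


class TestIncorporation:
    def test_noise_free_target_recovered_within_half_point(self):
        from quantpipes.synthetic_data import gen_incorporation_peptides

        table, _ = gen_incorporation_peptides(99.5, noise_sd=0.0, seed=2)
        est = incorporation_efficiency(table)
        assert abs(est["K"] - 99.5) <= 0.5
        assert abs(est["R"] - 99.5) <= 0.5

    def test_half_labeled_exact(self):
        table = pd.DataFrame(
            {
                "sequence": ["AAAK", "AAAR"],
                "modifications": ["K4:Label", "R4:Label"],
                "intensity_labeled": [50.0, 50.0],
                "intensity_unlabeled": [50.0, 50.0],
            }
        )
        est = incorporation_efficiency(table)
        assert est["K"] == pytest.approx(50.25)  # bin [50, 50.5) midpoint
        assert est["R"] == pytest.approx(50.25)

    def test_decoys_excluded_by_residue_and_modification_rules(self):
        table = pd.DataFrame(
            {
                "sequence": ["AAAK", "AAKR", "AAAA", "AAAK"],
                "modifications": ["K4:Label", "K3:Label", "", "K4:Label;M1:Oxidation"],
                "intensity_labeled": [99.0, 10.0, 10.0, 10.0],
                "intensity_unlabeled": [1.0, 90.0, 90.0, 90.0],
            }
        )
        est = incorporation_efficiency(table)
        # only the first row qualifies: one K, SILAC-only modifications
        assert est["K"] == pytest.approx(99.25)
        assert est["R"] is None

    def test_modal_tie_breaks_toward_higher_efficiency(self):
        table = pd.DataFrame(
            {
                "sequence": ["AAAK", "AAAK"],
                "modifications": ["K4:Label", "K4:Label"],
                "intensity_labeled": [90.1, 95.1],
                "intensity_unlabeled": [9.9, 4.9],
            }
        )
        est = incorporation_efficiency(table)
        assert est["K"] == pytest.approx(95.25)


class TestPipelinePlumbing:
    def test_plain_t_mode_differs_from_moderated(self):
        spec = SilacSimSpec(n_sites=200, n_true_hits=5, seed=8)
        evidence, _, _ = gen_silac_tables(spec)
        design = silac_design(spec)
        p_mod = run_phospho_pipeline(evidence, design, moderated=True)["results"]["p"]
        p_plain = run_phospho_pipeline(evidence, design, moderated=False)["results"]["p"]
        assert not np.allclose(
            p_mod.dropna().to_numpy(), p_plain.dropna().to_numpy()
        )

    def test_thresholds_are_configurable(self):
        spec = SilacSimSpec(n_sites=200, n_true_hits=20, seed=9)
        evidence, _, _ = gen_silac_tables(spec)
        design = silac_design(spec)
        strict = SignificanceThresholds(volcano_p=1e-10)
        res = run_phospho_pipeline(evidence, design, thresholds=strict)["results"]
        default = run_phospho_pipeline(evidence, design)["results"]
        assert res["volcano_significant"].sum() <= default["volcano_significant"].sum()
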