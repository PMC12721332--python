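"""Metagene binning, filtering, and the per-bin paired Wilcoxon tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from quantpipes.formats_io import CoverageTrack, GenomicInterval, TranscriptModel
from quantpipes.metagene import (
    BinSchemeConfig,
    build_bin_scheme,
    compute_binned_coverage,
    filter_transcripts,
    per_bin_paired_test,
    run_metagene,
    select_representative_transcript,
    wilcoxon_paired,
)
from quantpipes.thresholds import MetageneColorCodes


def tx(gene, tid, start, end, strand="+", chrom="chr1"):
    return TranscriptModel(gene, tid, GenomicInterval(chrom, start, end, strand))


SMALL = BinSchemeConfig(
    tss_upstream=200,
    tss_downstream=100,
    tss_bin=50,
    tts_upstream=100,
    tts_downstream=200,
    tts_bin=50,
    body_bins=7,
    min_transcript_length=210,
    min_gene_distance=100,
)


class TestBinScheme:
    def test_default_counts_are_90_180_215(self, toy_transcript):
        scheme = build_bin_scheme(toy_transcript)
        parts = np.asarray(scheme.parts)
        assert (parts == "tss").sum() == 90
        assert (parts == "body").sum() == 180
        assert (parts == "tts").sum() == 215
        assert len(scheme) == 485

    def test_body_tiles_interior_exactly_with_near_equal_bins(self):
        config = BinSchemeConfig()
        for length in [3180, 3181, 4001, 9999, 25000]:
            t = tx("g", "t", 50_000, 50_000 + length)
            scheme = build_bin_scheme(t, config)
            body = np.asarray(scheme.parts) == "body"
            starts, ends = scheme.starts[body], scheme.ends[body]
            # contiguous tiling of [TSS+1500, TTS-1500)
            assert starts[0] == 50_000 + 1500
            assert ends[-1] == 50_000 + length - 1500
            assert (starts[1:] == ends[:-1]).all()
            lengths = ends - starts
            assert lengths.min() >= 1
            assert lengths.max() - lengths.min() <= 1
            assert lengths.sum() == length - 3000

    def test_body_remainder_goes_to_five_prime_end(self):
        # interior of 1005 bp over 7 body bins: 4 bins of 144, 3 of 143,
        # with the longer bins 5'-most
        t = tx("g", "t", 1000, 1000 + 1005 + 200, strand="+")
        config = BinSchemeConfig(
            tss_upstream=100,
            tss_downstream=100,
            tss_bin=50,
            tts_upstream=100,
            tts_downstream=100,
            tts_bin=50,
            body_bins=7,
            min_transcript_length=207,
            min_gene_distance=0,
        )
        scheme = build_bin_scheme(t, config)
        body_len = scheme.lengths[np.asarray(scheme.parts) == "body"]
        assert list(body_len) == [144, 144, 144, 144, 143, 143, 143]

    def test_minus_strand_mirrors_plus_strand(self):
        plus = build_bin_scheme(tx("g", "t", 10_000, 18_000, "+"))
        minus = build_bin_scheme(tx("g", "t", 10_000, 18_000, "-"))
        # bin 0 of the minus scheme covers the genomic interval of the
        # mirror image of bin 0 of the plus scheme around the locus
        assert len(plus) == len(minus)
        total = 10_000 + 18_000
        assert (minus.starts == (total - plus.ends)[::-1] - 0).all() or (
            np.sort(minus.starts) == np.sort(total - plus.ends)
        ).all()
        # 5'-most bin sits at the TSS side: highest coordinates on minus
        assert minus.starts[0] > minus.starts[-1]

    def test_too_short_transcript_rejected(self):
        with pytest.raises(ValueError):
            build_bin_scheme(tx("g", "t", 0, 3179))


class TestTranscriptFilter:
    def test_length_boundary_3180(self):
        txs = [tx("g1", "a", 10_000, 13_179), tx("g2", "b", 40_000, 43_180)]
        kept = filter_transcripts(txs)
        assert [t.gene_id for t in kept] == ["g2"]

    def test_gene_distance_boundary_4999_flags_both_neighbours(self):
        # two genes separated by 4999 nt, a third far away
        txs = [
            tx("g1", "a", 10_000, 20_000),
            tx("g2", "b", 24_999, 35_000),
            tx("g3", "c", 90_000, 100_000),
        ]
        kept = {t.gene_id for t in filter_transcripts(txs)}
        assert kept == {"g3"}

    def test_distance_measured_on_gene_spans_not_transcripts(self):
        # gene1 has a short isoform far from gene2 but a long isoform close
        txs = [
            tx("g1", "a", 10_000, 16_000),
            tx("g1", "a2", 10_000, 26_000),
            tx("g2", "b", 30_000, 40_000),
        ]
        kept = {t.gene_id for t in filter_transcripts(txs)}
        assert kept == set()  # span gap 4000 < 5000 removes both genes

    def test_single_gene_kept(self):
        assert len(filter_transcripts([tx("g", "t", 1000, 8000)])) == 1


class TestRepresentativeSelection:
    def make_tracks(self, depth):
        return [CoverageTrack(name="r", depths={"chr1": depth}, library_size=1e6)]

    def test_highest_tss_tts_coverage_wins(self):
        depth = np.zeros(60_000)
        depth[9_000:11_000] = 10.0  # boosts the isoform whose TSS is 10k
        txs = [tx("g", "low", 30_000, 38_000), tx("g", "high", 10_000, 18_000)]
        chosen = select_representative_transcript(txs, self.make_tracks(depth))
        assert chosen.transcript_id == "high"

    def test_tie_breaks_to_longer_then_lexicographic(self):
        txs = [tx("g", "bb", 10_000, 18_000), tx("g", "aa", 10_000, 19_000)]
        chosen = select_representative_transcript(txs, self.make_tracks(np.zeros(60_000)))
        assert chosen.transcript_id == "aa"  # longer wins the score tie
        txs = [tx("g", "bb", 10_000, 18_000), tx("g", "aa", 10_000, 18_000)]
        chosen = select_representative_transcript(txs, self.make_tracks(np.zeros(60_000)))
        assert chosen.transcript_id == "bb"  # same length: lexicographically last

    def test_coverage_mode_requires_reference(self):
        with pytest.raises(ValueError, match="reference coverage"):
            select_representative_transcript([tx("g", "t", 0, 5000)] * 2, None)


class TestBinnedCoverage:
    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            length = int(rng.integers(400, 900))
            start = int(rng.integers(0, 150))
            strand = "+" if trial % 2 == 0 else "-"
            t = tx("g", "t", start, start + length, strand)
            scheme = build_bin_scheme(t, SMALL)
            depth = rng.poisson(3.0, size=start + length + 250).astype(float)
            track = CoverageTrack(name="t", depths={"chr1": depth}, library_size=5e5)
            fast = compute_binned_coverage(track, [scheme]).values[0]
            slow = np.zeros(len(scheme))
            for i, (s, e) in enumerate(zip(scheme.starts, scheme.ends)):
                total = sum(
                    float(track.values("chr1", pos, pos + 1)[0])
                    for pos in range(s, e)
                )
                slow[i] = total / (e - s) * 1e6 / track.library_size
            assert np.allclose(fast, slow, atol=1e-9)

    def test_uniform_track_gives_flat_cpm_profile(self, toy_transcript, flat_track):
        scheme = build_bin_scheme(toy_transcript)
        vals = compute_binned_coverage(flat_track, [scheme]).values[0]
        assert np.allclose(vals, 4.0 * 1e6 / flat_track.library_size)


class TestWilcoxon:
    @staticmethod
    def enumerate_p(d):
        d = d[d != 0]
        n = len(d)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        mean_w = n * (n + 1) / 4.0
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((0, 1), repeat=n)
        ]
        ws = np.asarray(ws, dtype=float)
        return float(np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-9))

    def test_exact_p_equals_sign_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            x = rng.normal(0.2, 1, size=n)
            y = rng.normal(0, 1, size=n)
            _, p, n_eff = wilcoxon_paired(x, y)
            if n_eff < 2:
                continue
            assert p == pytest.approx(self.enumerate_p(x - y), abs=1e-12)

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 2.5, 3.0, 4.0])
        _, p, n_eff = wilcoxon_paired(x, y)
        assert n_eff == 3

    def test_degenerate_pairs_give_p_one(self):
        x = np.ones(5)
        _, p, n_eff = wilcoxon_paired(x, x)
        assert (p, n_eff) == (1.0, 0)

    def test_large_n_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.5, 1, size=60)
        y = rng.normal(0, 1, size=60)
        _, p, _ = wilcoxon_paired(x, y)
        ref = stats.wilcoxon(
            x - y, zero_method="wilcox", method="approx", correction=True
        ).pvalue
        assert p == pytest.approx(float(ref), rel=1e-12)


class TestPerBinTest:
    def make_matrices(self, rng, n_genes, n_bins, shift=0.0):
        from quantpipes.metagene import BinnedCoverageMatrix

        out = []
        for rep in ("1", "2"):
            vals = rng.gamma(4, 1, size=(n_genes, n_bins)) + shift
            out.append(
                BinnedCoverageMatrix(
                    values=vals,
                    gene_ids=[f"g{i}" for i in range(n_genes)],
                    condition="x",
                    replicate=rep,
                    sample=f"s{rep}",
                )
            )
        return out

    def test_bonferroni_factor_is_bin_count_and_categories_applied(self):
        rng = np.random.default_rng(21)
        control = self.make_matrices(rng, 30, 12)
        treated = self.make_matrices(rng, 30, 12, shift=-2.0)
        res = per_bin_paired_test(control, treated)
        assert len(res) == 12
        assert np.allclose(res["p_adj"], np.minimum(res["p"] * 12, 1.0))
        codes = MetageneColorCodes()
        assert (res["category"] == [codes.category(p) for p in res["p_adj"]]).all()

    def test_gene_mean_pairing_averages_replicates(self):
        rng = np.random.default_rng(22)
        control = self.make_matrices(rng, 10, 5)
        treated = self.make_matrices(rng, 10, 5)
        res = per_bin_paired_test(control, treated, pair_on="gene_mean")
        assert (res["n_pairs"] <= 10).all()
        res_rep = per_bin_paired_test(control, treated, pair_on="replicate")
        assert (res_rep["n_pairs"] <= 20).all()

    def test_mismatched_gene_sets_rejected(self):
        rng = np.random.default_rng(23)
        control = self.make_matrices(rng, 10, 5)
        treated = self.make_matrices(rng, 12, 5)
        with pytest.raises(ValueError):
            per_bin_paired_test(control, treated)


class TestRunMetagene:
    def test_end_to_end_shapes_and_parts(self):
        from quantpipes.synthetic_data import ChipSimSpec, gen_annotation, gen_chip_coverage

        spec = ChipSimSpec(n_genes=30, seed=3)
        transcripts, _ = gen_annotation(spec)
        tracks, _ = gen_chip_coverage(transcripts, spec)
        res = run_metagene(
            transcripts,
            control_tracks=tracks["control"],
            treated_tracks=tracks["treated"],
            reference_tracks=tracks["control"],
        )
        assert len(res["profile"]) == 485
        counts = res["tests"]["part"].value_counts()
        assert counts.to_dict() == {"tss": 90, "body": 180, "tts": 215}
        assert (res["profile"]["mean_control"] >= 0).all()

    def test_no_eligible_transcripts_is_an_error(self):
        with pytest.raises(ValueError, match="eligible"):
            run_metagene([tx("g", "t", 0, 2000)], [], [])
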