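# quantpipes

Three quantitative genomics/proteomics workflows, re-implemented as one
library with seeded synthetic data generators so every stage can be
exercised end-to-end offline against known ground truth:

1. **ChIP-seq metagene profiling** — transcript filtering (length ≥ 3180 bp,
   nearest-gene distance ≥ 5000 nt), a fixed 90/180/215 bin scheme around
   TSS / gene body / TTS, depth-normalized (CPM) binned coverage averaged
   gene-then-replicate, and a per-bin paired Wilcoxon signed-rank test with
   Bonferroni-coded significance (red ≤ 1e-15, orange ≤ 1e-10, yellow ≤ 1e-3).
2. **SILAC phosphoproteomics** — evidence filtering and grouping, merging of
   TiO2/IMAC enrichments, reconstruction of light/heavy channels from summed
   intensity and H/L ratio, cyclic-loess normalization, label-flip-aware
   paired differences, and an empirical-Bayes moderated t per site
   (volcano: p < 0.01 and log2FC ≤ −1). Includes the protein-level SILAC
   test (BH-adjusted) and the label-incorporation efficiency check.
3. **BioID enrichment** — decoy/contaminant cleaning, log2, loess
   normalization, replicate/peptide presence filtering, seeded left-censored
   imputation, and a blocked moderated t of bait vs control with BH
   adjustment (enriched: adjusted p < 0.05 and log2FC ≥ 1).

The moderated test re-implements the limma empirical-Bayes scheme
(moment-matched scaled-inverse-chi-square prior on variances) and is
verified against Bioconductor limma to ~1e-13 in the test suite.

## Quick start

Every pipeline is a plain function; the `examples/` scripts are narrative
walkthroughs. Running `python examples/metagene_profile.py` simulates a
200-gene chromosome where treatment removes 80% of gene-derived occupancy
and prints:

```
simulated 200 genes; 200 pass the length/distance filters
mean body CPM control 0.525, treated 0.125
 tss: 90 bins, 33% significant after Bonferroni
body: 180 bins, 100% significant after Bonferroni
 tts: 215 bins, 78% significant after Bonferroni
```

`python examples/silac_phospho_workflow.py` recovers a spike-in:

```
30 significant features at p<0.01 and log2FC<=-1; 30/30 spiked events recovered
mean log2FC of recovered hits: -1.91
incorporation efficiency: K 99.25%, R 99.75%
```

`python examples/bioid_enrichment_screen.py` runs the proximity-labeling
screen (`25/43 spiked interactors recovered`, zero false enrichments; see
*Known limitation* below).

The same pipelines are exposed as a thin CLI:

```bash
quantpipes simulate chip --seed 1 --loss-factor 0.2 --out sim/
quantpipes metagene run --annotation sim/annotation.bed \
    --control sim/control_rep1.bedgraph=2e7,sim/control_rep2.bedgraph=2e7 \
    --treated sim/treated_rep1.bedgraph=2e7,sim/treated_rep2.bedgraph=2e7 \
    --out results/
quantpipes silac phospho --evidence ev.tsv --design design.tsv --out out/
quantpipes bioid run --proteingroups pg.tsv --design design.tsv --seed 7 --out out/
```

Coverage inputs can be BAM/SAM (reads are MAPQ ≥ 20 filtered and
5'-coordinate deduplicated; the filtered count becomes the library size),
or bedGraph/bigWig with an explicit `path=LIBRARY_SIZE`.

## Tests and reproduction

```bash
python -m pytest -q tests/                      # unit, property and oracle tests
python scripts/acceptance.py --seed 1 --out report.json
```

The acceptance script re-runs every end-to-end verification from scratch
(brute-force binning oracle, exhaustive Wilcoxon sign enumeration, null
calibration, spike-in recoveries, determinism, normalization property) and
writes `{"name": {"value": ..., "n": ...}}` JSON. All outputs are
deterministic given `--seed`.

## Known limitation

`tests/test_acceptance.py::test_criterion_09b_bioid_spikein_recovery`
currently **fails by design**: with 3 + 3 samples, a 3-level preparation
block (2 residual df), realistic left-censored missingness and imputation,
the moderated test recovers ~65–83% of +2 log2FC spike-ins at the
enrichment thresholds, not the targeted ≥ 90%. The implementation matches
limma exactly; the shortfall is statistical power, analyzed in
`docs/methods.md` (*BioID statistical power*). We deliberately do not
weaken the generator or thresholds to force the bound.

## Layout

- `src/quantpipes/` — library (`formats_io`, `metagene`, `silac_phospho`,
  `bioid_enrichment`, `synthetic_data`, `thresholds`, `_stats`, `cli`,
  `acceptance`)
- `examples/` — runnable narrative walkthroughs
- `tests/` — unit, oracle, property and acceptance-criterion tests
- `scripts/acceptance.py` — standalone verification report
- `docs/methods.md` — models, parameter choices, numerical notes
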