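# rloopkit

Desk-scale analysis of **R-loop forming sequences (RLFS)** and their
association with differential gene expression, of the kind used to ask
whether the genes that respond to knocking down an R-loop helicase (such
as senataxin/SETX under hypoxia) are unusually R-loop prone.

R-loops are three-stranded nucleic-acid structures — an RNA/DNA hybrid
plus a displaced single strand — that form co-transcriptionally,
preferentially at G-rich sequences. `rloopkit` provides the full
computational arc around that question as a tested, reproducible Python
package:

1. **RLFS prediction** (`rloopkit.rlfs`): scan both strands of a genome
   for an R-loop initiation zone (RIZ: ≥3 G-tracts of ≥3 G, gaps ≤10 nt)
   followed within 50 nt by an elongation zone (REZ: 50–2000 nt with G
   fraction ≥0.4, sustained over every 100-nt sub-window), then merge
   hits that share ≥1 bp.
2. **Per-gene density metrics** (`rloopkit.metrics`): on 2 kb-flanked gene
   windows (promoter + terminator included), count co-transcriptional
   merged RLFS per kb and the percent of the window they cover, plus gene
   features (length, exon count, GC%, canonical G4 motifs
   `G≥3(N1–7G≥3)≥3`).
3. **Resampling enrichment** (`rloopkit.enrichment`): sample a
   differentially expressed gene set and the protein-coding background
   *n* times (default 100,000), drawing 20% of the set each iteration;
   compare the two distributions of means with a two-tailed t-test, and
   report effect sizes plus a calibrated raw-metric t-test alongside.
4. **Rank-product differential expression** (`rloopkit.diffexpr`):
   RP<sub>g</sub> = (∏<sub>c</sub> r<sub>gc</sub>)<sup>1/k</sup> over the
   fold-change ranks of k pairwise comparisons, with permutation-based
   pfp (proportion of false predictions), plus FPKM normalisation.
5. **Metagene signatures** (`rloopkit.signatures`): rescale each gene to
   median 1, score samples by the median of a gene panel (e.g. the
   six-gene hypoxic p53 panel *BTG2, CYFIP2, INPP5D, KANK3, PHLDA3,
   SULF2*), and correlate a query gene with the score by Spearman's ρ.
6. **Bench-assay formulas** (`rloopkit.assays`): DNA-fibre replication
   rates V = (x · 0.132 µm/px · 2.59 kb/µm)/t, ΔΔCt fold changes
   (2<sup>−ΔΔCt</sup>, 18S reference), and foci-positive cell fractions
   (strictly >5 foci per nucleus).
7. **Synthetic data with ground truth** (`rloopkit.simulate`): genomes
   with planted RLFS cassettes, gene models whose "responder" genes
   preferentially sit on planted loci, negative-binomial count matrices
   with knockdown-in-hypoxia effects, copula-coupled cohort tables, and
   assay tables — so every stage above is testable offline against known
   truth.

A pipeline (`rloopkit.pipeline` / the `rloop-enrich` CLI) chains all
stages from one YAML config, with per-stage seeds, checksummed outputs
and checksum-gated resume.

## Worked example

Run the bundled demo (one 200 kb chromosome, 300 genes, a 10× planted
enrichment effect, 1,000 resampling iterations):

```bash
rloop-enrich run --demo --out runs/demo --seed 7
```

The run takes a few seconds and writes every stage output under
`runs/demo/`. Highlights from `enrichment.json` (up- and down-regulated
sets vs the protein-coding background, metric RLFS per kb):

```
up:   test mean 0.256 vs genome mean 0.176,  t = 13.5,  p = 2.22e-16 (floored)
down: test mean 0.349 vs genome mean 0.172,  t = 42.6,  p = 2.22e-16 (floored)
```

Both differentially expressed sets carry roughly 1.5–2× more RLFS per kb
than random protein-coding genes; the resampled-means t-test saturates at
the double-precision floor 2.2e-16, which should be read as "off the
scale", not as a literal probability (see `docs/methods.md` — the result
object also carries Cohen's d, here 0.38 and 0.79, and a calibrated
raw-metric p-value, here 0.20 and 6.5e-4). The differential-expression
stage recovered 17 up- and 29 down-regulated genes at pfp < 0.05, and
`signature.json` shows the cohort arm recovering its simulated
correlation (target ρ = 0.6):

```json
{"spearman_rho": 0.653, "p_two_tailed": 6.3e-50, "n_samples": 400}
```

`assays.json` reports mean fork speeds of 2.24 kb/min (normoxia preset,
20 min pulse) vs 0.52 kb/min (hypoxia preset, 60 min pulse) for the
simulated fibre tables.

Each module is equally usable on your own files — e.g.
`rloop-enrich predict-rlfs --fasta genome.fa --out hits.bed --merged merged.bed`,
`rloop-enrich metrics ...`, `rloop-enrich de ...`, `rloop-enrich enrich ...`;
see `--help` on any subcommand.

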