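# Methods

This note documents the models, statistics and numerical choices behind
`rloopkit`, what the synthetic-data generator does and does not emulate,
and the known limitations of each procedure.

## RLFS prediction model

The scanner implements the two-zone structure common to quantitative
R-loop-forming-sequence predictors: an **R-loop initiation zone (RIZ)**
of clustered G-tracts, followed after a short linker by an **R-loop
elongation zone (REZ)** of sustained G-richness on the same strand. The
concrete thresholds (all fields of `RlfsModel`) are:

| parameter | default | meaning |
|---|---|---|
| `min_g_tract` | 3 nt | minimum consecutive G per tract |
| `min_tracts` | 3 | tracts needed to form a RIZ |
| `max_tract_gap` | 10 nt | maximum gap between tracts within a RIZ |
| `max_riz_rez_gap` | 50 nt | how far downstream the REZ may start |
| `min_rez_length` / `max_rez_length` | 50 / 2000 nt | REZ length bounds |
| `rez_g_min` | 0.40 | minimum G fraction, overall and per sub-window |
| `rez_window` | 100 nt | sub-window over which G-richness must be sustained |

RIZ candidates are the *maximal* clusters of G-tracts (hence disjoint);
for each, REZ starts are tried left-to-right from the RIZ end up to the
linker bound and the first workable start is kept, growing the longest
window that satisfies both the overall and the per-100-nt G-fraction
conditions. `N` bases break tracts and terminate REZ growth
(conservative). Minus-strand hits are defined as plus-strand hits of the
reverse complement with coordinates mapped back, which makes strand
symmetry structural rather than incidental; a chunked scanning mode with
overlap padding reproduces whole-sequence results exactly at the padding
documented in `find_rlfs_chunked`.

This is a desk-scale approximation, not a byte-for-byte reimplementation
of any published tool; published quantitative predictors additionally
weight G-clustering and hybrid thermodynamics. Users matching a specific
parameterisation should set `RlfsModel` fields accordingly.

Coordinates are 0-based half-open everywhere in memory and BED on disk.

## Merging and per-gene metrics

Merging joins hits sharing **at least 1 bp**; book-ended intervals
(`[0,10)` + `[10,20)`) share zero bases and stay separate, which is why
the merge is implemented directly on sorted arrays rather than delegated
to tools whose defaults join adjacent intervals. Merging is per
chromosome and strand, with a strand-collapsed view derived on demand.
Correctness is asserted against a per-base boolean-bitmap oracle.

Gene windows add 2 kb on both sides of the gene span (promoter and
terminator regions), clamped at contig edges with the truncation
recorded. Two metrics per gene:

* `rlfs_per_kb` — merged intervals overlapping the window by ≥1 bp per kb
  of window. An interval partially overlapping counts fully (event
  count); an interval overlapping two genes counts for both.
* `pct_coverage` — percent of window bases covered (clipped; a length
  measure).

The density denominator includes the flanks by default, matching a
workflow that adds flanks before quantification; whether the flanks
belong in the denominator is genuinely ambiguous in such workflows, so
`include_flanks_in_denominator=False` switches to the unflanked gene
length. Co-transcriptional filtering keeps only hits on the gene's
transcribed strand, applied by scoring each gene against the merged view
of its own strand.

G4 motifs use the canonical quadruplex pattern `G{3,}([ACGT]{1,7}G{3,}){3,}`,
counted as non-overlapping matches independently on each strand; GC% is
computed on the unflanked gene body over ACGT bases.

## Resampling enrichment and its interpretation

The procedure follows the resampled-means design: draw
`round(0.2 · |test set|)` genes without replacement from the test set and
from the protein-coding background, record each draw's mean, repeat
(default 100,000 iterations), and compare the two mean distributions with
a two-tailed t-test (Welch by default; pooled-variance optional).

**This p-value is not calibrated and cannot be.** The two mean
distributions concentrate around the *fixed* sample means of the test set
and the background at rate 1/√draw_size·√n_iterations, so any difference
between the two population means — including the chance difference of a
randomly chosen subset — becomes "significant" as iterations grow: under
a random-subset null the t statistic has variance ≈ d·n_iter/(2m) (d the
draw size, m the test-set size), about 100 at the defaults. A reported
floor value of 2.220446049250313e-16 (the double-precision epsilon
familiar from statistical software output) means "off the scale".
Accordingly `EnrichmentResult` always also reports:

* the difference of mean-of-means and **Cohen's d** on the raw per-gene
  metrics (effect sizes unaffected by the iteration count), and
* a **raw-metric Welch t-test** on the per-gene values themselves
  (`raw_t`, `raw_p`), which *is* approximately calibrated under the
  random-subset null (very slightly conservative, since the subset is
  contained in the background sample). `mode="raw"` promotes it to the
  headline statistic.

Calibration claims in the test suite therefore attach to the raw-metric
p-value; power claims (a planted enrichment detected with p < 0.01) use
the resampled-means test, which is faithful to the procedure as
practised. Sampling is without replacement within an iteration,
iterations are independent, and one seeded generator per run makes
results bit-reproducible. A display helper draws the n = 500 background
sample used for violin/box companions.

## Rank-product differential expression

For groups A and B, fold changes are computed for k pairwise comparisons
(all replicate pairs by default, `mode="paired"` for positional pairs),
genes are ranked within each comparison (average ranks on ties; rank 1 =
strongest change in the direction under test), and
RP<sub>g</sub> = exp(mean log rank). Expression must be strictly
positive; the pipeline adds a 0.5 pseudocount to counts. Rank products
run on counts by default — ranking is within-sample, so gene length
cancels from between-sample fold changes only when lengths are shared
across samples, which they are; FPKM
(`counts / ((length/10³)·(total/10⁶))`) is computed for reporting.

pfp (proportion of false predictions): with c<sub>g</sub> the number of
null rank products ≤ RP<sub>g</sub> pooled over permutations,
E<sub>g</sub> = c<sub>g</sub>/n_permutations and
pfp<sub>g</sub> = E<sub>g</sub>/rank(RP<sub>g</sub>). Two nulls:

* **rank-shuffle** (default; the classic rank-product null): independent
  uniform ranks per comparison. Exact when comparisons are independent —
  true in paired mode, where measured top-gene pfp < 0.05 occurs in 5.0%
  of null runs. In all-pairs mode the comparisons reuse samples, ranks
  correlate, and this null overstates significance (measured 97.5% of
  null runs at α=0.05): treat all-pairs pfp as a ranking score, or use
  paired mode when calibration matters.
* **sample-permutation**: group labels permuted over pooled samples, rank
  products recomputed on group-mean-centred log expression. Honest to the
  correlation (top-gene pfp ≈ 4–8% under the all-pairs null) but
  conservative when many genes are truly differential, because permuted
  data lets null genes occupy the top ranks the responders hold in the
  observed ranking.

No cutoff is canonical for pfp; the default 0.05 is configurable. Gene
sets are disjoint by construction: a gene passing both directions (only
possible at permissive cutoffs) is assigned to the smaller rank product,
ties going up. Columns are processed in canonical sorted order so that
swapping the group labels swaps the up/down outputs exactly.

## Metagene signatures

Cohort tables are rescaled per gene to median 1 (genes with non-positive
median cannot be rescaled and are dropped with a warning); the per-sample
score is the median rescaled expression of the panel genes; the query
gene is correlated with the score by average-rank Spearman ρ. The
two-tailed p uses exact enumeration of all rank permutations for n ≤ 9
and the t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df above that.
Rescaling is per input table; cohorts to be analysed separately (e.g. per
cancer type) should be passed as separate tables. Panels are user
supplied; the six-gene hypoxic p53 panel ships as a convenience default
for the simulator's cohort arm.

## Bench-assay formulas

* Fibre rate: V (kb/min) = (x px · 0.132 µm/px · 2.59 kb/µm)/t min. The
  constants are overridable; pulse durations come from named presets
  (normoxia 20 min, hypoxia 60 min second-label pulse) so the two
  labelling schemes cannot be silently mixed.
* ΔΔCt: fold = 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_treated −
  (Ct_target − Ct_ref)_control; replicates are aggregated by mean Ct
  before differencing (standard Livak usage).
* Foci: percent of cells with count strictly greater than the threshold
  (default >5 per nucleus).

## Synthetic data: what it emulates, and what it does not

The generator produces, from one config and seed (per-stage child
streams; identical config+seed ⇒ byte-identical files):

* **Genome**: uniform-composition background (25% each base — chosen to
  isolate the planted signal for sensitivity testing) with planted
  cassettes: a RIZ-like seed `GGG N1–5 GGG N1–5 GGG`, a 0–40 nt linker,
  and a 300 nt extension at 45% G. The linker is capped at 40 nt so that
  every planted cassette is detectable under the default scanner model
  (REZ search reaches 50 nt); cassette counts are Poisson at
  `planted_rlfs_rate` per 100 kb, placed uniformly with overlap
  rejection and strand chosen at random.
* **Annotation**: non-overlapping stranded genes (gamma-distributed
  lengths, exponential-gap layout so dense configs place
  deterministically), exon counts 1+Poisson(4), a small non-coding
  fraction. Responders are drawn with odds multiplied by
  `rlfs_enrichment_effect` for genes whose flanked window overlaps a
  same-strand planted cassette, each with a random true direction.
* **Counts**: negative binomial parameterised by mean and dispersion
  (`size = 1/dispersion`), base means lognormal, size factors fixed at 1
  (normalisation is deliberately not under test), responders shifted by
  `de_log2fc` only in the knockdown-hypoxia group. The dispersion (0.05)
  and library scale are stand-ins chosen as typical for a well-behaved
  cell-line RNA-seq experiment; no public per-dataset values are matched.
* **Cohort**: a bivariate Gaussian copula couples the query gene's latent
  score to one latent panel score at Pearson r = 2·sin(π·ρ_S/6), the
  inverse of ρ_S = (6/π)·asin(r/2); each panel gene is a lognormal
  (monotone) transform of the panel score, so the induced rank
  correlation hits the target exactly in expectation and exactly at
  |ρ|=1. Per-gene latent noise is available (`cohort_panel_noise_sd`)
  but defaults to 0; with noise, recovered ρ attenuates by
  ≈ 1/√(1+var(median noise)).
* **Assays**: gamma-distributed fibre pixel lengths per condition, Ct
  values with planted ΔΔCt = −log₂(fold) and Gaussian noise (0 noise ⇒
  exact recovery), and foci counts constructed so that positive cells
  (planted fraction) are exactly the cells with >5 foci.

Not emulated: read-level sequencing artefacts, alignment, GC/length
biases, batch effects, isoform structure, real genomic base composition
(isochores, CpG islands), and inter-gene correlation in expression.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under its stated assumptions — not performance
on real genomes, where RLFS prevalence, composition heterogeneity and
expression covariance all differ.

## Numerical choices

* p-values are floored at 2.220446049250313e-16 and flagged when floored.
* Ties: average ranks throughout (fold changes, Spearman, pfp ranks).
* Degenerate inputs raise rather than guess: empty foci tables, zero
  pulse times, constant vectors in correlation, draws exceeding the
  population, non-positive expression in rank products, genes without a
  usable strand in the co-transcriptional filter.
* All stochastic stages take either a `numpy.random.Generator` or a seed;
  the pipeline derives per-stage sub-seeds (< 2³¹) from the run seed via
  `SeedSequence`, and records seeds and SHA-256 checksums of every input
  and output in `manifest.json`. A stage is skipped on re-run only when
  its recorded input checksums still match and its outputs exist.

## Problem sizes

Defaults used by the test suite and the acceptance script: a 2 × 250 kb
genome, 400 genes, 3 replicates per group, 100 rank-product permutations;
resampling runs use 1,000 iterations for calibration experiments (200
replicate runs) and 10,000 for power, versus the 100,000 default a
full-scale analysis would use; the demo pipeline uses one 200 kb
chromosome and 300 genes. These sizes were chosen so the whole suite and
the acceptance script each complete in well under a minute on one CPU
while every statistical property under test remains measurable at its
stated tolerance.
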