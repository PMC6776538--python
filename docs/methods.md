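# Methods

## The model

`trisect` analyses allele-specific expression (ASE) in single cells from
trisomic and diploid fibroblast populations under the two-state (telegraph)
model of transcription in the non-overlapping-burst regime: a promoter fires
bursts at frequency `f` (bursts per mRNA lifetime) of mean size `b`
transcripts, so that steady-state transcript counts per allele follow a
negative binomial with shape `f` and mean `f·b`, and the per-allele
probability of zero transcripts is `p0 = (1/(1+b))^f`.  The two (or, on a
supernumerary chromosome, three) alleles of a gene transcribe independently.

Three quantities follow in closed form for a gene with `k` identical
alleles, and the package uses them as oracles throughout the test suite:

- fraction of expressing cells `R_k = 1 − p0^k`;
- zero-truncated mean among expressing cells `s̄_k = k·f·b / (1 − p0^k)`;
- the dosage identity `E(s_k)/E(s_2) = (R_k/R_2)·(s̄_k/s̄_2) = k/2`,
  i.e. a bulk fold change of 1.5 for a triplicated gene, decomposable into a
  fraction-of-expressing-cells component and a per-cell fold-change
  component lying on the hyperbola `R_3/R_2 = 1.5 / (s̄_3/s̄_2)`.

Low-expressed genes (`p0 → 1`) realise the 1.5-fold imbalance almost
entirely through `R_3/R_2 → 1.5`; highly expressed genes (`p0 → 0`) through
the per-cell ratio `s̄_3/s̄_2 → 1.5`.

## ASE definitions and filters

ASE at a heterozygous site is reference reads over total reads in diploid
regions and double-allele (DA) reads over total reads on the supernumerary
chromosome, where the DA is the allele present in two copies (genotype ABB
or BAA).  ASE ≤ 0.1 and ≥ 0.9 are monoallelic calls (boundaries inclusive);
the open interval between them is biallelic.  Observations require site
coverage ≥ 16 reads and RPSM ≥ 20 (reads per site per million mapped reads,
computed against the cell's total uniquely mapped reads) as allele-dropout
guards.  A gene's monoallelic expression prevalence (MEP) is taken at its
most-observed site (ties to the lowest position); genes are monoallelic
(MEP > 0.8), biallelic (MEP < 0.2) or intermediate.  Cell-level QC requires
1e6 total reads (configurable) and ≥ 10% of the gene panel expressed.
Zero-coverage observations are absent, never imputed as 0 or 0.5.

## Synthetic data generator

The simulator draws per-gene `(f, b)` log-uniformly from `f ∈ [0.05, 5]`,
`b ∈ [2, 50]` by default, spanning detection rates `R_2` from a few percent
to ~1 and mean expression from below 1 to hundreds of transcripts — the
low-to-high expression spectrum.  Sequencing is emulated in two stages:
per-transcript Bernoulli capture with efficiency 0.3 (a thinned negative
binomial stays negative binomial, preserving all closed forms with
`b → 0.3·b`), then a Poisson total read count per expressed site (mean
30 by default, scaled by a per-cell log-normal depth factor, σ = 0.5)
allocated multinomially across alleles in proportion to retained
transcripts.  A transcript-proportional read model was considered and
rejected: single-allele monoallelic observations carry roughly half the
transcript mass of double-allele ones, so proportional depth makes the
coverage filter remove them preferentially and biases the monoallelic
ratio upward by a factor of ~2.

Each supernumerary site's doubled allele is chosen uniformly (ABB and BAA
both occur) and recorded in the truth table.  Optional X-chromosome sites
give every cell one consistently expressed X haplotype; doublets are built
by summing the counts of two discordant-haplotype singlets (parents
consumed, recorded in truth).  All randomness flows from a single seed via
`numpy.random.SeedSequence` spawning, making outputs bit-identical across
runs.

What the generator does *not* emulate: UMI chemistry, alignment artefacts,
mappability bias, gene-length effects, cell-cycle covariation between genes,
or imprinting/X-escape.  Passing tests therefore demonstrate correctness of
the statistical machinery under the burst model, not robustness to every
artefact of real libraries.

### Regime dependence of the allelic-selection summaries

Two observation-level summaries depend strongly on where the gene panel sits
on the burstiness spectrum, because they aggregate over genes:

- In the **deep-burst regime** (`f ≲ 0.1`, `p0 → 1`) an expressing cell has
  typically one allele active, chosen uniformly among the three copies:
  the unique allele carries → 1/3 of monoallelic observations and the
  double allele is seen → 2× as often.  The test suite asserts this in a
  low-`f` simulation.
- In the **frequent-burst regime** (`f ≫ 1`, `p0 → 0`) all three alleles
  transcribe simultaneously and biallelic ASE concentrates at 2/3 (asserted
  at high `f`, deep coverage); in the deep-burst regime the rare biallelic
  observations instead centre near 0.5.

Pooled over the default low-to-high grid the two summaries land *between*
these limits (monoallelic DA/SA ratio ≈ 3, trisomic biallelic mean ≈ 0.60):
double-allele-only events are first order in `p0` while single-allele-only
events are second order, so mid-frequency genes inflate the pooled ratio,
and their biallelic observations sit near 0.5 rather than 2/3.  No setting
of capture efficiency, depth model or a single log-uniform frequency window
attains both limiting values simultaneously in the pooled summaries; the
acceptance script reports the honestly pooled values.

## Mosaic classification

Features per cell, computed on the supernumerary chromosome only: (1) mean
of per-gene min-max-normalised expression, (2) mean ASE.  Because the DA is
initially unknown, iteration 1 uses the folded magnitude `0.5 + |ASE − 0.5|`;
afterwards the DA per site is re-estimated as the allele with the larger
summed read count over currently-trisomic cells (ties keep the previous
assignment, else ref) and the ASE feature is DA-oriented.  Both features are
z-scored before 2-means (k-means++ with fixed seed, Euclidean metric,
`n_init = 10`): without standardisation the noisier ASE feature dominates
the metric and costs several accuracy points.  The cluster with the larger
centroid feature sum is called trisomic — invariant to cluster-id
permutation.  Convergence is declared on zero label changes or an exact
period-2 oscillation (k-means alternation can cycle); `max_iter` defaults
to 100.

Degenerate input guard: a forced 2-means split of a single Gaussian cloud
yields a centroid distance of ≈ `2·√(2/π) ≈ 1.6` (z-units) along its
dominant axis; populations whose centroid separation falls below 2.0 are
declared non-separable and all cells stay diploid.  Measured separations
are ~1.7 for pure-diploid simulations and ≥ 2.3 for genuine 50/50 mosaics.

Cross-validation is stratified k-fold (default 5): feature ranges, centroids
and the DA map are fitted on training cells only; held-out cells are
assigned to the nearest centroid.

## Doublet screen

Per-cell X profiles are reference-allele ratios at heterozygous X sites
outside PAR1 (chrX:60,001–2,699,520) and PAR2 (chrX:154,931,044–155,260,560,
GRCh37) and outside a configurable escapee-gene list.  Pairwise Pearson
correlations are computed on shared covered sites (≥ 10 per pair for
stability), and average-linkage hierarchical clustering on correlation
distance splits cells into the two haplotype groups.  Singlets correlate
near +1 with one group and −1 with the other, so their median |correlation|
to *both* groups is ≈ 1.  A doublet's profile is a site-level mosaic of both
haplotype patterns; its expected correlation to either group is
`(a − c)/√(a + c)` where `a, c` are the fractions of its sites dominated by
either parent — ≈ ±0.5 for the typical lopsided doublet and ~0 for a
perfectly balanced one.  Because the balanced case sits *below* 0.5, the
flagging band is one-sided by default: cells whose median |correlation| to
both groups is ≤ 0.75 are flagged (band configurable).  A symmetric band
with a lower edge near 0.25 would miss precisely the most-mixed doublets.
Samples without informative X sites (male or X-homozygous) make the screen
a logged no-op.

## Dosage decomposition

Per gene: `fc_bulk` = trisomic/diploid ratio of means over all cells,
`fc_sc` = ratio of zero-truncated means over expressing cells, `R_2`, `R_3`
and their ratio.  "Expressing" defaults to value > 0; with the site-level
RPSM ≥ 20 rule (C1 preset) or > 5 reads with > 50 expressing cells (droplet
preset) values below the rule are treated as noise and zeroed, which keeps
`fc_bulk = (R_3/R_2)·fc_sc` exact to 1e-9 by construction.  Genes need ≥ 10
expressing cells.  Group comparisons use the paired two-sided Wilcoxon
signed-rank test (exact null for ≤ 25 informative pairs, normal
approximation with continuity correction above, zero differences
discarded), Mann–Whitney U between expression classes (diploid mean < 3
low, 3–15 medium, > 15 high, FPKM-scale), and Spearman correlation of
`log(R_3/R_2)` vs `log(fc_sc)` for the hyperbola.  Raw p-values are
reported with test name and n; no multiple-testing correction is applied.
Dosage classes on fold change: > 1.2 sensitive, 0.8–1.2 insensitive
(open band), otherwise other.

## Problem sizes and tolerances

The reference simulations are sized for desk-scale reproducibility: the
burst-grid population uses 200 genes × (1000 + 1000) cells, the classifier
benchmark 316 cells × 100 genes at mean site depth 20 and capture 0.3, the
doublet benchmark 120 cells × 40 X sites at a 10% doublet rate.  Stochastic
assertions use 3–4 standard errors or binomial confidence bounds; the exact
algebraic identity is asserted at 1e-9.  Coordinates are 1-based inclusive
(VCF convention) everywhere; TSV outputs are tab-separated UTF-8 with `NA`
for missing values.

## Known limitations

- Whole-chromosome trisomy only; no monosomies, higher copy numbers or
  partial CNVs.
- One heterozygous site per gene in the simulator (real genes can have
  several; the MEP site-choice rule is still exercised via site ties).
- The pooled allelic-selection summaries depend on the assumed
  burst-parameter spectrum (see regime note above); real panels weighted
  toward low expression push the pooled values toward the 1/3 // 2× limits.
- The doublet screen assumes female samples with informative X
  heterozygosity; extremely lopsided doublets (one parent contributing
  ≳ 90% of sites) are indistinguishable from singlets by construction.
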