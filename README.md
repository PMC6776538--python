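# trisect

Allele-specific expression (ASE) and gene-dosage analysis of trisomic single
cells.

Trisomies are classically described by a 1.5-fold bulk overexpression of the
genes on the supernumerary chromosome.  At single-cell resolution that fold
change decomposes: with `R_k` the fraction of cells expressing a gene with
`k` copies and `s̄_k` the mean expression among those expressing cells,

    E(s_3) / E(s_2) = (R_3 / R_2) · (s̄_3 / s̄_2) = 3/2,

so dosage imbalance of low-expressed, bursty genes is carried mostly by
*more cells expressing them* (`R_3/R_2 → 1.5`), while highly expressed genes
are overexpressed *within* each cell (`s̄_3/s̄_2 → 1.5`), the two components
trading off along the hyperbola `R_3/R_2 = 1.5/(s̄_3/s̄_2)`.  This follows
from the two-state burst model of transcription, under which per-allele
transcript counts are negative binomial (shape = burst frequency `f`, mean
`f·b`) and alleles fire independently — so each heterozygous site of a
trisomic cell carries a "double allele" (present twice) whose reads are
expected twice as often as the unique allele's.

The package is aimed at people analysing single-cell RNA-seq of aneuploid
or mosaic samples with matched genotypes, and provides:

- `trisect.simulate` — a generative model of per-allele bursty
  transcription, site-read sampling with allele dropout, mosaic
  populations, X-haplotype structure and doublets, with full ground truth;
- `trisect.ase` — the diploid (REF-based) and trisomic (double-allele-based)
  ASE formulas, RPSM ≥ 20 / coverage ≥ 16 dropout guards, monoallelic calls
  and per-gene monoallelic expression prevalence (MEP) classes;
- `trisect.classifier` — `MosaicTrisomyClassifier`, an iterated 2-means
  classifier of diploid vs trisomic cells on (mean min-max-normalised
  supernumerary expression, mean ASE), alternating with per-site
  double-allele re-estimation until label stability, plus stratified
  cross-validation;
- `trisect.doublets` — `XHaplotypeDoubletDetector`, flagging doublets in
  female samples by correlation of X-haplotype expression profiles
  (PAR regions and escapee genes excluded);
- `trisect.dosage` — the Eq.-above decomposition: `fc_bulk`, `fc_sc`,
  `R_2`, `R_3`, expression/dosage/MEP stratification, paired Wilcoxon and
  Mann–Whitney tests, hyperbola fit;
- `trisect.io` / the `trisect` CLI — TSV/VCF/MatrixMarket readers and
  writers, YAML configuration and a reproducible pipeline driver
  (`simulate`, `qc`, `doublets`, `classify`, `ase`, `dosage`, `report`).

## Worked example

Simulate a 316-cell half-trisomic mosaic population at realistic coverage,
recover the trisomic cells without using the truth labels, and decompose the
dosage imbalance:

```python
from trisect import (SimConfig, simulate_population, classify_mosaic,
                     decompose_genes, hyperbola_fit, compute_observations,
                     filter_observations, ase_histogram_summary)

cfg = SimConfig(n_genes=100, n_cells_diploid=158, n_cells_trisomic=158,
                mean_site_depth=20.0, capture_efficiency=0.3, rng_seed=11)
sim = simulate_population(cfg)

clf = classify_mosaic(sim.counts, sim.expression, sim.sites, "chr21", seed=0)
acc = (clf.labels_ == sim.truth.cell_labels).mean()
print(f"classifier: {int((clf.labels_ == 'trisomic').sum())} trisomic cells, "
      f"converged in {clf.n_iter_} iterations, accuracy vs truth {acc:.3f}")

tri = clf.labels_.index[clf.labels_ == "trisomic"]
obs = compute_observations(sim.counts.subset_cells(tri), sim.sites,
                           double_allele=clf.double_allele_map_,
                           supernumerary_chromosome="chr21")
s = ase_histogram_summary(filter_observations(obs[obs["chrom"] == "chr21"]))
print(f"trisomic ASE: {100*s['fraction_monoallelic']:.1f}% monoallelic, "
      f"biallelic mean {s['mean_biallelic_ase']:.3f}")

summary = decompose_genes(sim.expression, clf.labels_)
fit = hyperbola_fit(summary)
print(f"dosage: median fc_bulk {summary['fc_bulk'].median():.2f}, "
      f"median R3/R2 {summary['r_ratio'].median():.2f}, "
      f"hyperbola Spearman rho {fit['rho']:.2f} (p = {fit['pvalue']:.1e}, "
      f"n = {fit['n']})")
```

Output:

```
classifier: 158 trisomic cells, converged in 3 iterations, accuracy vs truth 0.975
trisomic ASE: 42.0% monoallelic, biallelic mean 0.603
dosage: median fc_bulk 1.47, median R3/R2 1.04, hyperbola Spearman rho -0.65 (p = 1.9e-13, n = 100)
```

Reading it: the unsupervised classifier recovers the 50/50 mosaic at 97.5%
accuracy while estimating which allele is doubled at every site; trisomic
ASE observations skew toward the double allele (biallelic mean above 0.5);
the median bulk fold change of triplicated genes sits near the expected 1.5
while the per-cell and cell-fraction components are inversely correlated
along the hyperbola.

The same stages are available from the shell:

```sh
trisect simulate --outdir sim --genes 100 --diploid 158 --trisomic 158 --seed 11
trisect classify --counts sim/allele_counts.tsv --totals sim/cell_totals.tsv \
        --sites sim/sites.vcf --expr sim/expression.tsv --outdir out
```

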