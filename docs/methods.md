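# Methods

This note records the statistical model behind each `striatax` module, the
default parameters and why they were chosen, the scope of the synthetic
generator, and known limitations. Parameter names refer to the dataclasses in
`striatax.config`; all defaults are serialized in
`src/striatax/data/default.toml`.

## 1. Synthetic data generator (`striatax.synthetic`)

### Count model

Each cell belongs to one planted population. For a cell in population *p*
with library size *L*:

- *L* ~ Gamma with mean `mean_library_size` (35,000) and coefficient of
  variation `library_size_dispersion` (0.25), matching typical snRNA-seq
  depth spread.
- Gene counts are Gamma–Poisson (negative binomial) around `L · r_p`, with
  gene-wise rate vector `r_p` and dispersion `nb_dispersion` (0.25), the
  standard overdispersed model for UMI counts.

The rate vector combines:

- **Filler genes**: log-rates drawn N(0, 1²) shared across populations, plus
  a heterogeneity term `heterogeneity_sigma` (1.2) split √0.6/√0.4 between a
  *correlation-block* component shared by populations in the same block and
  a population-private component. Blocks are what the class-merging stage is
  expected to recover: populations in one block correlate strongly in their
  mean profiles; populations in different blocks do not.
- **Marker genes**: each population owns a marker set expressed *only* in its
  owners, at `marker_baseline_rate` (2×10⁻⁵ of the filler rate mass) times
  `exp(marker_log_fold)` (fold 6). Non-owned named genes are exactly zero:
  the generator emulates ambient-corrected input (as produced by droplet
  decontamination tools), so no soup leakage is modeled. This is a scope
  decision, not an approximation — see Limitations.
- **Gradients**: selected populations modulate 40 dedicated genes by
  `exp(strength · z · w)` with latent z ~ U(−1, 1) and unit-norm weights w;
  the truth table records z per cell for factor-recovery checks.
- **Planted regional DE**: per-population (gene, region, log-fold) triples
  multiply the rate in one region only.

Doublets are injected by summing the counts of two same-sample parents;
`doublet_rate` (0.05) of cells are appended and flagged in the truth table.

The bundled default configuration plants 14 interneuron populations in 8
correlation blocks, plus MSN and glial populations, across 3 CN + 3 Pu
samples of 800 cells each (6,000 genes, 4 mitochondrial).

### Scope and limits

The generator is deliberately simple where the pipeline does not test the
corresponding behavior: no batch effects beyond sample-level multinomial
sampling, no ambient RNA, no gene–gene correlation beyond the block
structure, no empty droplets. Spatial fields (`generate_spatial`) place
cells uniformly and implement co-localization by moving a fraction
`strength/(1+strength)` of one label near partners with Gaussian offsets of
2% of the field side; enrichment z-scores therefore grow with cell count.

## 2. Quality control (`striatax.qc`)

Cascade order: consensus doublet removal → count filters → polynomial
gene/UMI outliers → multi-identity filter → regional marker filter. The
funnel is conserved: cells_in − removed = cells_out at every stage.

**Doublet consensus.** Per sample and per run, simulated doublets (2:1
simulated:observed) are mixed with the data, embedded with a 30-component
truncated SVD, and each observed cell is scored by the fraction of simulated
doublets among its k nearest neighbors. The threshold is the deepest valley
between the two lowest substantial modes of the *simulated* score histogram
(40 bins, Gaussian smoothing σ = 2.5, modes > 5% of the max). If the
simulated scores are unimodal there is no doublet mode to separate, and the
threshold falls back to the (1 − expected_rate) quantile of the *simulated*
scores; a quantile of the observed scores would flag a fixed share of cells
on doublet-free data, and because those flags repeat across runs they would
defeat the consensus vote. A cell is discarded only if flagged in strictly
more than 10% of `n_doublet_runs` (15) independent runs.

**Count filters.** Minimum UMIs/genes and maximum mitochondrial fraction
(`QCThresholds`); a quadratic genes-vs-UMIs fit flags cells whose residual
exceeds `poly_outlier_sd` standard deviations.

**Identity filters.** Marker scores per broad cell type; a two-Gaussian
mixture (components ordered by mean) sets per-type positivity thresholds at
μ_low + 4σ_low. Cells positive for more than one identity, or expressing
markers of the wrong region, are removed.

## 3. Taxonomy (`striatax.taxonomy`)

Normalization: counts per 10,000 + log1p. HVGs: dispersion z-scored within
20 mean-quantile bins (mitochondrial/sex-linked/riboprotein genes excluded).
Clustering: PCA → kNN (k = 15) → Louvain. The classification funnel is
iterative: broad clusters are labeled by marker panels; neuron clusters are
re-filtered on depth (≥ 5,000 UMIs, 3,000–12,000 genes, neurons being larger
nuclei) and re-clustered; interneuron clusters must pass a positive gate
(GAD1/GAD2/CHAT mean > 0.25) and a negative gate (all of
PPP1R1B/DRD1/DRD2/MEIS2/RORB < 0.1) to exclude MSNs. Interneurons are
re-clustered (1,500 HVGs, 20 PCs, resolution 1.0) into subclasses; Wilcoxon
rank-sum (tie-corrected normal approximation) ranks markers per subclass.

**Class merging.** Subclass mean profiles are correlated (Pearson);
subclasses connected by r strictly > 0.49 are merged (connected components
by default, greedy cliques optionally). Classes are named after their
largest member subclass. Average linkage on 1 − r gives the dendrogram
(Newick). The 0.49 threshold sits between within-block profile correlations
(driven by the shared block component, ≈ 0.6 of heterogeneity variance) and
across-block correlations.

## 4. Composition (`striatax.composition`)

Per-sample class fractions are centered log-ratios: counts + 0.5
pseudocount, refit to fractions, log, minus the per-sample log geometric
mean. CLR rows sum to zero, removing the unit-sum constraint. Per class,
CN vs Pu CLR values are compared by a two-sided unpaired Wilcoxon rank-sum
(exact null when the regions together have ≤ 25 samples and no ties),
BH-adjusted across classes.

## 5. Pseudobulk DE (`striatax.de`)

Counts are summed per (class, sample, region), dropping groups with fewer
than `de_min_cells` (10) cells. Per gene, a negative-binomial GLM with log
link and region effect is fit by alternating Newton steps; dispersion is
estimated by maximizing the Cox–Reid adjusted profile likelihood and shrunk
50/50 (in log space) toward the gene-wise geometric mean. Offsets are
median-ratio size factors rescaled by the mean log library size. Regional
significance is a 1-df likelihood-ratio chi-square; log2 fold changes use a
prior count of 0.5 on the aggregated counts. DEGs require BH-adjusted
p < 0.05 and |log2FC| strictly > 0.5. Over-representation of gene sets uses
the hypergeometric upper tail P(X ≥ k), BH across terms, with terms reported
at p < 0.1.

## 6. Gradients (`striatax.gradients`)

Within one subclass and region, expression over up to 1,200 HVGs is centered
and fit with a single-factor Gaussian factor-analysis model (LAPACK SVD
solver). The sign convention makes the largest-|weight| gene positive so
runs are comparable. Gene subsets (e.g. receptor families) are selected by
case-insensitive prefixes plus explicit gene lists, preserving universe
order.

## 7. Spatial (`striatax.spatial`)

Cells on a targeted panel are gated hierarchically on raw counts: neuron
(GAD1 ≥ 3, OLIG1 < 1, MOBP < 1) → interneuron (LHX6 or SST ≥ 3, MEIS2 < 1) →
subclass by the most specific satisfied marker rule (rules with markers
missing from the panel degrade to their present markers, with a warning).
Neighbor graphs are Delaunay triangulations with edges above the 99th length
percentile pruned (k-NN union as fallback for degenerate geometry).
Label-pair enrichment is a permutation z-score of observed shared edges
against `n_perm` label shuffles; pairs whose permutation distribution is
degenerate (sd = 0) are reported with z = 0 and flagged.

## 8. Numerical choices

- All randomness flows through `numpy.random.default_rng` seeded from one
  per-run seed; per-sample doublet runs derive seeds as
  `[seed, run, crc32(sample)]` so results are independent of sample order.
- Exact tests (Wilcoxon, hypergeometric) are used wherever sample sizes
  permit; otherwise tie-corrected normal approximations.
- Dispersion shrinkage and log-space averaging avoid the instability of
  moment estimators at 3 samples per region.
- BH adjustment is the standard step-up with a running minimum, vectorized.

## 9. Limitations

- The generator's ambient-free marker model means the pipeline's negative
  marker gates are tested in a clean regime; on real, uncorrected data the
  gate thresholds (0.25 positive / 0.1 negative on log-normalized means)
  assume prior ambient-RNA removal.
- Pseudobulk DE with 3 samples per region has limited power; the calibration
  and sensitivity contracts are stated at 6 + 6 samples.
- The spatial module starts from per-cell panel counts; segmentation and
  transcript decoding are out of scope.
- Class merging by connected components can chain: A–B and B–C correlations
  above threshold merge A and C even if their direct correlation is below
  it. The clique mode avoids this at the cost of order dependence.
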