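# Methods

## The analysis model

Whole-blood methylation scores are modeled as proportion-weighted mixtures
of cell-type-specific signals.  For sample *i* and CpG *j*:

    m_ij = Σ_k p_ik α_kj + Σ_k (p_ik x_i) β_kj + γ_j' z_i + ε_ij

with `p_ik` the proportion of cell type *k* (six neonatal blood cell types:
B, granulocyte, monocyte, NK, Tc, Th), `x_i` the binary treatment, and
`z_i` measured covariates.  The cell-type-specific MWAS fits this regression
per CpG and tests each proportion-by-treatment interaction coefficient
`β_k` — the treatment effect within cell type *k*.  Key choices:

- **No global intercept.**  The K proportion main effects span the
  intercept because proportions sum to one; including both would make the
  design singular.  This is the standard full-rank parameterization of the
  mixture regression (the CellDMC-style interaction design).
- **Bulk model.**  The whole-blood MWAS uses `[1, x, covariates, K−1
  proportions, PCs]`; the last declared cell type's proportion is dropped to
  avoid collinearity with the intercept.  With a single cell type whose
  proportion is 1, the cell-type model reduces exactly to the bulk model
  (tested to 1e-8 on the treatment t statistic).
- **Degrees of freedom and effect size.**  `df = n − rank(design)`; the
  two-sided p comes from the t distribution and the reported effect size is
  the partial correlation `r = t/√(t² + df)`, which is invariant to the
  (arbitrary) scale of the methylation scores.
- **Latent confounders.**  After residualizing measured covariates, per-CpG
  standardized residuals feed a sample-space PCA; the fixed default of two
  components enters the design (an elbow mode — the count maximizing the
  second difference of the eigenvalue curve — is available).
- **Multiplicity.**  Benjamini–Hochberg q-values are computed within each
  analysis unit; methylome-wide significance is q < 0.1 and suggestive
  significance p < 1e-6.  CpGs with zero variance (or an unstable design,
  condition number > 1e8) are reported with undefined p, a reason code, and
  are excluded from the BH denominator.
- **Calibration diagnostic.**  The genomic inflation factor λ is the median
  of squared normal quantiles of p/2 divided by the χ²(1 df) median
  (≈0.4549).

## Replication and enrichment testing

Look-up replication retests every discovery-significant CpG in the
replication results of the same analysis unit, with Bonferroni control at
α = 0.05 over the joint family (all significant CpGs across units and
treatments).  A locus fully replicates when all of its CpGs do.

The circular-permutation enrichment test matches two result sets by exact
(chrom, pos) within an analysis unit, orders them genome-wide (declared
chromosome order 1..22, X, Y, then position), binarizes at p-value
thresholds (suggestive 1e-6 for the primary side, nominal 0.05 for the
replication side; 1e-6 on both sides for cross-treatment overlap), and
compares the observed 2×2 odds ratio with the distribution over B random
circular shifts d ∈ {1..N−1} of the secondary vector (drawn uniformly with
replacement; B = 10,000 by default).  The p-value uses the add-one rule
(#{OR_perm ≥ OR_obs}+1)/(B+1), so it is never zero, and the continuity
correction adds 0.5 to all four cells whenever any cell is zero.  Shift
overlap counts for all N offsets are computed at once by FFT
cross-correlation and verified against explicit rolls in the tests.

*Validity domain.*  The shift null is exact when the relative genomic phase
of the two indicator vectors is exchangeable under rotation.  This holds
for autocorrelated but mutually independently placed signals — the
situation the test exists for — and the type-I error on such nulls sits at
the nominal level while a naive label permutation, which destroys the run
structure, inflates it several-fold.  If both vectors share one fixed
correlation grid (e.g. indicator blocks aligned to identical boundaries in
both datasets), rotation exchangeability is violated and the test can be
anticonservative; this is a property of shift tests generally, not of this
implementation.

## GO analysis

A CpG links to a gene when it lies in the gene body [start, end] or within
10,000 bp upstream of the TSS (before `start` on '+', after `end` on '−';
1-based inclusive coordinates; multi-gene links allowed).  The CpGs feeding
the analysis are those suggestive in any primary analysis unit whose
replication p in the same unit is below 0.05 (presence-only mode available).
Term enrichment keeps the permutation at the CpG level: the selection
indicator is circularly shifted along the genome-ordered CpG universe and
genes are re-linked at every shift, preserving gene-length and CpG-density
biases in the null.  The gene universe is every annotated gene with at
least one term membership.  Significant terms (p < 0.05, ≥3 overlapping
genes) form a graph weighted by shared overlapping-gene counts (Jaccard
optional) and are clustered with Louvain modularity optimization
(resolution 1.0, fixed seed); a gene is *defining* for the cluster whose
terms contain it most often, ties broken toward the cluster holding its
most significant term.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing process.  Defaults are the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| n_treated / n_untreated | 35 / 77 | primary exposure group vs untreated controls (48/77 for the second treatment; 31 treated in replication datasets) |
| dirichlet_means | (.08, .39, .18, .05, .15, .15) | neonatal whole-blood cell-type means (B, granulocyte, monocyte, NK, Tc, Th) |
| dirichlet_concentration | 35 | implied per-type SDs ≈ 0.03–0.08, matching observed spread |
| gestational age | 277 ± 15 d | observed mean/SD; sex ~ Bernoulli(0.5); birth years 1975–1989; 3 batches; assay covariates (enrichment efficiency 0.70 ± 0.05, % aligned 95 ± 2) |
| noise_sd | 1.0 | score scale is arbitrary (partial correlations are scale-free) |
| ar1_phi | 0.3 | AR(1) noise along position within chromosomes, so adjacent CpGs carry correlated statistics and the shift test is exercised on realistic data |
| locus_size_range | 2–10 CpGs | planted effects occupy runs of adjacent CpGs sharing one affected cell type (multi-CpG loci) |
| effect_partial_r | 0.5 | planted effect scale; 0.54 in monocyte-recovery experiments |

Planted coefficients are *calibrated*: for each locus, β is chosen so that
the expected t statistic of the interaction test on the realized design
(proportions, treatment, covariates) equals the t implied by the target
partial r at the design's df.  Refitting the generating model across 50
simulations recovers the target within ±0.1 (tested).

Randomness is split by scope from integer seeds
(`SeedSequence(seed, spawn_key)`): *genome* quantities (CpG positions,
baseline profiles, annotation, gene sets, covariate loadings) derive from
`genome_seed`, so two treatments can share one genome while planting
different loci; *study* quantities (loci) derive from `seed`; *sample*
quantities (proportions, covariates, noise) additionally key on
`replicate_id`, so replication datasets share loci with their primary
dataset but draw independent samples.

**What the generator does not emulate:** MBD-seq read counts, coverage,
enrichment-efficiency artifacts, genuine unmeasured confounders, population
structure, or the bounded scale of array-style beta values.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed mixture model, not robustness to assay-level artifacts.

## Finite-genome effects (and the problem sizes used)

Two artifacts of desk-scale genomes matter and are handled explicitly:

1. **PCs can absorb dense planted signal.**  With tens of thousands of CpGs
   and a planted-signal density of ~1%, the treatment-interaction direction
   competes with the top noise eigenvalues and the confounder PCs partially
   absorb it, attenuating power (at 24 million CpGs with a few hundred
   signal CpGs this is negligible).  Recovery experiments therefore use
   50,000-CpG genomes with 8 loci (~0.1% density), where the full
   PC-adjusted pipeline retains its power; the FDR experiment, which plants
   10% non-null CpGs by construction, fits without PCs (the generator
   contains no latent confounders, so nothing is lost).
2. **Errors-in-variables attenuation.**  Proportion-estimation error scales
   like 1/√(panel size) and biases the interaction tests toward zero.  The
   pipeline's simulated reference panel therefore uses 500 marker CpGs per
   cell type by default; the cell-type recovery experiments use the
   generating proportions directly, emulating the near-exact estimation
   achievable from methylome-scale data.

Problem sizes: FDR control uses 20 datasets of 50,000 CpGs at n = 120
(~10% non-null); null calibration uses 10 datasets of 20,000 CpGs; monocyte
recovery uses 50 datasets of 50,000 CpGs at n = 125; circular-test
calibration uses 200 block-autocorrelated null pairs (blocks of 10,
independent random phases) at B = 1,000; gene linking is checked against an
exhaustive scan on 1,000 random configurations; proportion recovery uses
100 noisy mixtures on a 300-CpG panel.

## Numerical choices

- Proportion estimation: scipy NNLS per sample on the CpG keys shared with
  the panel, then sum-to-one renormalization; an SLSQP simplex-constrained
  variant sits behind `method="qp"`.  An all-zero NNLS solution (degenerate
  input) falls back to uniform weights.  Estimates are invariant to affine
  rescaling of the scores only if the panel is rescaled identically.
- Rank deficiency is reported by naming the aliased columns (greedy QR
  scan); near-collinearity in the interaction design (condition number
  > 1e8) flags results unstable rather than reporting unreliable tests.
- BH q-values delegate to statsmodels' step-up implementation with NaN
  propagation added; the tests verify it against the closed-form step-up
  formula.
- Chromosome order for all genome-wide orderings is the natural order
  1..22, X, Y (configurable); internal coordinates are 1-based inclusive,
  converted at the BED boundary (GFF3 needs no conversion).
- Louvain clustering labels are renumbered by first appearance in table row
  order, making cluster assignments reproducible for a fixed seed and
  invariant (as a partition) to row order.

## Known limitations

- The exact deconvolution estimator and the supplementary model description
  of the original analysis are not public; the interaction regression here
  is the declared standard form, and NNLS + renormalization is the declared
  stand-in for the proportion estimator.
- Under a global null, BH at q < 0.1 still produces at least one discovery
  in ~10% of families; a pipeline run contains 14 (treatment, unit)
  families, so occasional isolated null "findings" are expected behavior,
  not a defect.
- The GO permutation operates on CpG-level shifts; gene-level label
  shifting is not implemented.
- Logistic outcomes, mixed models, and batch correction beyond
  covariates + PCs are out of scope.
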