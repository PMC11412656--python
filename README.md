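# ctmwas

Cell-type-specific methylome-wide association testing for studies that
profile bulk blood methylation but need to know *which* blood cell type
carries a treatment effect.  The package implements the full analysis chain
used in neonatal blood-spot studies of obstetric analgesia exposure:
reference-based estimation of cell-type proportions, bulk and per-cell-type
MWAS with covariate and latent-confounder control, FDR and look-up
replication, position-preserving circular-permutation enrichment tests, and
gene-ontology enrichment with Louvain term clustering — plus a synthetic-data
generator that plants known cell-type effects so every stage can be validated
end to end.

## The model

Whole-blood methylation is a mixture over cell types.  For sample *i* and
CpG *j*, with cell-type proportions *p<sub>ik</sub>* (six neonatal blood cell
types: B cells, granulocytes, monocytes, NK cells, cytotoxic T, T-helper)
and binary treatment *x<sub>i</sub>*:

```
m_ij = Σ_k p_ik α_kj  +  Σ_k (p_ik x_i) β_kj  +  γ' z_i  +  ε_ij
```

The deconvolution MWAS fits this interaction regression per CpG with no
global intercept (the proportion main effects span the intercept because
Σ<sub>k</sub> p<sub>ik</sub> = 1); each interaction coefficient
β<sub>k</sub> is the treatment effect *within cell type k* and is tested
with a t statistic at df = n − rank(design).  Effect sizes are reported as
partial correlations r = t/√(t² + df).  Covariates *z* (sex, birth year,
gestational age, batch, assay covariates) enter additively, together with
two principal components computed from covariate-residualized methylation to
capture unmeasured confounders.  Multiplicity is controlled per analysis
unit by Benjamini–Hochberg q-values (methylome-wide significance q < 0.1,
suggestive significance p < 10⁻⁶), and calibration is monitored with the
genomic inflation factor λ.

Replication uses (a) Bonferroni look-up of all discovery-significant CpGs
and (b) a circular-permutation enrichment test: both result sets are matched
by genomic position, binarized at p-value thresholds, and the observed
2×2 odds ratio is compared with the distribution obtained by randomly
rotating one indicator vector along the genome — a null that preserves the
local correlation of test statistics.  The same machinery drives
cross-treatment overlap testing and GO term enrichment (CpGs link to a gene
when they fall in its body or ≤10 kb upstream of its TSS, strand-aware);
significant terms (p < 0.05, ≥3 overlapping genes) are clustered by shared
genes with Louvain community detection and each gene is assigned a single
"defining" cluster.

## Worked example

Run the complete pipeline on a simulated two-treatment study (35 and 48
treated newborns vs 77 untreated; 31-sample replication groups; effects
planted in monocytes at partial r ≈ 0.54):

```python
from ctmwas.io import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    output_dir="demo_run",
    seed=7,
    n_permutations=1000,
    simulation=dict(
        n_cpgs=20_000,
        n_signal_loci=8,
        signal_cell_types=("monocyte",),
        effect_partial_r=0.54,
    ),
)
out = run_pipeline(cfg)
```

which writes, per treatment, the MWAS tables (bulk + six cell types), the
look-up replication table, the replication enrichment table, the GO tables,
and a manifest.  Inspecting treatment A:

```python
import pandas as pd
res = pd.read_csv(out / "treatmentA" / "mwas_primary.tsv", sep="\t")
sig = res[res["significant"] & (res["analysis_unit"] != "bulk")]
print(sig[["chrom", "pos", "analysis_unit", "partial_r", "p", "q"]].head(6))
```

```
       chrom      pos analysis_unit  partial_r             p         q
61066      2   360216      monocyte   0.432561  1.490331e-05  0.014194
61067      2   362493      monocyte   0.469628  2.044657e-06  0.003718
61068      2   364949      monocyte   0.376524  1.993541e-04  0.097246
61069      2   366298      monocyte   0.414217  3.666797e-05  0.029334
61070      2   371169      monocyte   0.397385  8.009539e-05  0.053397
61071      2   371201      monocyte   0.461089  3.299092e-06  0.005076
```

Of the 43 methylome-wide-significant cell-type-level CpGs, 41 fall in the
monocyte analysis unit at partial correlations near the planted 0.54 — the
deconvolution attributes the signal to the correct cell type even though
the pipeline works from *estimated* proportions.  The replication
enrichment table shows the monocyte unit's suggestive primary findings
strongly enriched among nominal replication findings:

```
analysis_unit   a  b    c     d  odds_ratio   p_perm
         bulk  11  0 1062 18927  409.724706 0.000999
     monocyte   7  0 1087 18906  260.779310 0.000999
  granulocyte   0  0  990 19010   19.192832 1.000000
```

while `cross_treatment_overlap.tsv` shows no overlap between the two
treatments, whose planted loci are disjoint.

A command-line interface mirrors the stages
(`ctmwas simulate|proportions|mwas|replicate|overlap|go|all`).

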