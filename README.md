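# mirpair

Integrated miRNA–mRNA expression analysis for paired case–control
microarray studies, modelled on the design used in ulcerative colitis (UC)
mucosal profiling: a miRNA platform and an mRNA platform run on
overlapping subjects, with the goal of finding miRNAs whose dysregulation
plausibly drives the dysregulation of their predicted target genes.

## Who this is for

Bioinformaticians who have normalized log2 expression matrices from two
platforms (plus per-database miRNA→gene target predictions and curated
clinical gene sets) and want a tested, reproducible implementation of the
classic integration recipe — or who want to study that recipe's operating
characteristics on synthetic data with known ground truth.

## The method

1. **Differential expression** per comparison (active UC vs control,
   inactive UC vs control, active UC vs inactive UC) with an
   empirical-Bayes moderated t-statistic. Per feature *g*, the pooled
   two-group variance s²_g on d = n_A+n_B−2 degrees of freedom is shrunk
   toward a prior s₀²:

       s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
       t_g = (x̄_A − x̄_B) / (s̃_g·√(1/n_A + 1/n_B)),  t_g ~ t(d₀ + d),

   with (d₀, s₀²) estimated by method of moments on log s². Features are
   *biologically significant* when |log2FC| > 1 (fold change > 2) and the
   Benjamini–Hochberg FDR < 0.05.
2. **Unsupervised clustering** of samples and features (complete linkage,
   Euclidean distance) on the top-20 most variable features, exported as
   an ordered heat-map matrix plus dendrograms.
3. **Consensus target prediction**: a (miRNA, gene) pair survives when at
   least 3 of 5 databases (miRanda, miRDB, miRWalk, RNA22, TargetScan)
   predict it; alternative mature miRNAs covered only by miRanda/miRWalk
   use a 2-of-3 rule with DIANA-microT added.
4. **Inverse-correlation screening**: pairs whose members are both
   significantly differentially expressed with opposite fold-change signs
   are restricted to clinically curated gene sets (UC susceptibility,
   barrier, cell-adhesion, anti-microbial), then tested by Spearman rank
   correlation ρ across subjects profiled on both platforms
   (p two-sided via t = ρ·√((n−2)/(1−ρ²)) on n−2 df), with B–H FDR over
   the tested pairs. A pair is called at p < 0.05 with ρ < 0.
5. **qPCR-style validation**: 2^−ΔΔCT relative quantification against a
   reference assay and calibrator group, Mann–Whitney group comparison,
   and direction-concordance checks against the array fold changes.

A seeded synthetic-study generator reproduces the paired design
(10/7/10 subjects on the miRNA platform, 7/6/8 of them on the mRNA
platform) with planted fold changes, planted negatively correlated
miRNA–target pairs, imperfect prediction databases and companion Ct
tables, so the whole pipeline is testable against known truth.

## Worked example

```python
from mirpair import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(outdir="out", seed=1))
r = manifest["report"]
print(r["n_clinical_pairs"], r["n_significant_pairs"])
print(r["recovery_sensitivity"], r["recovery_precision"])
print(r["top_pairs"][0])
```

prints

```
49 49
0.98 1.0
{'mirna_id': 'hsa-miR-1002-5p', 'gene_symbol': 'GENE0043',
 'category': 'Anti-microbial peptide', 'rho': -0.9357142857142857,
 'p': 3.010645621400716e-07, 'fdr': 1.3246840734163152e-05}
```

i.e. of the 50 planted repressive pairs, 49 reach the final clinically
filtered list and all 49 called pairs are true plants (sensitivity 0.98,
precision 1.0); the strongest call is a planted pair with sample Spearman
ρ = −0.94 over the 15 matched subjects. The same run writes the per-stage
TSVs (DE tables per comparison, ordered heat-map matrices, the ranked
pair table, 2^−ΔΔCT quantities and group tests) plus `report.json` and a
`manifest.json` with file hashes — rerunning with the same seed
reproduces every file byte for byte.

The kernels also reproduce published summary statistics directly, e.g.

```python
from mirpair.stats_core import spearman_p_tapprox, chi_square_rxc
spearman_p_tapprox(-0.918, 15)                      # 1.40e-06
chi_square_rxc([[6, 4, 2, 1, 5], [4, 3, 3, 4, 5]])  # p = 0.64
```

The same pipeline runs from the shell:

```bash
mirpair all --seed 1 --outdir out
```

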