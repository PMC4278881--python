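# Methods

## Statistical kernels

**Ranking and Spearman correlation.** Ranks are 1-based with average-tie
assignment, so they always sum to n(n+1)/2; Spearman ρ is the Pearson
correlation of the two rank vectors. Significance uses the t
approximation t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom,
two-sided; |ρ| = 1 returns p = 0 by convention. This choice matches the
published top-pair table at n = 15 to within the rounding of the printed
ρ (3 decimals ⇒ ~5 % relative slack on p in this range). An exact
permutation p (full enumeration of n! permutations, refused for n > 8)
is provided as an independent small-n oracle; at n = 7 on tie-free data
the two agree within a factor of 2, which is the documented quality of
the approximation there.

**Multiple testing.** Benjamini–Hochberg step-up, adj₍ᵢ₎ = min over
j ≥ i of m·p₍ⱼ₎/j capped at 1, returned in input order. The family size
m defaults to the number of p-values but can be set larger. At the
correlation stage the family is exactly the set of pairs entering the
call — the published FDR column is consistent with an effective family
near the size of the clinically filtered list, and no fixed m is
hard-coded.

**Mann–Whitney U.** U counts (x, y) pairs with x > y (ties ½). Exact
two-sided p by the partition-count recursion when min(n) ≤ 8 and the
pooled sample is tie-free; otherwise the normal approximation with tie
correction and a 0.5 continuity correction (comparable to mainstream
statistics packages). Two-sided exact p is 2·min(P(U≤u), P(U≥u)) capped
at 1.

**Categorical tests.** Pearson χ² for r×c tables without continuity
correction (df = (r−1)(c−1)); Fisher's exact test for 2×2 tables with
the point-probability two-sided rule (sum of tables whose probability
does not exceed the observed one, with a 1+1e−7 relative tolerance
against float ties). The caller chooses between χ² and Fisher; there is
no automatic small-count switch. Both conventions reproduce the cohort
table (χ² p = 0.64 for sex×group; Fisher p = 1.0 for disease extent).

## Differential expression

Input is an already-normalized log2 matrix; probe-level summarization is
out of scope (an optional quantile normalization — columns mapped onto
the mean of sorted columns, ties receiving interpolated reference values
— is available and idempotent). The two-group fit gives log2FC =
mean(A)−mean(B), the pooled variance, and df = n_A+n_B−2. Hyperparameters
(d₀, s₀²) follow the method of moments on log s²: with
e_g = log s²_g − ψ(d/2) + log(d/2), solve ψ′(d₀/2) = Var(e) − ψ′(d/2) by
Newton inversion of the trigamma function and set
s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)). A non-positive moment estimate falls
back to d₀ = ∞ (complete pooling; p-values from the normal limit) with a
warning — on homoscedastic data, including this package's own generator
defaults, that branch is the statistically correct outcome, not a
failure. Zero sample variances are excluded from moment estimation but
still receive posteriors. With d₀ = 0 the moderated t reduces exactly to
the ordinary pooled two-sample t (tested to 1e−10 against an independent
implementation).

Biological significance requires both gates: |log2FC| > log2(fc) with
fc = 2, and B–H FDR < 0.05. Printed fold changes use the signed linear
convention sign(log2FC)·2^|log2FC| (a 0.5× ratio prints as −2).

## Clustering

Complete-linkage agglomeration on Euclidean distances over raw log2
values (no feature scaling), restricted to the k = 20 features with the
largest sample variance (variance ties broken lexicographically by
feature ID). Merge heights under complete linkage are monotone and are
validated against an O(n³) brute-force agglomerator in the tests;
tie-breaking among equidistant merges follows the linkage
implementation's deterministic order, and only the (tie-break-invariant)
heights are part of the tested contract. Leaf order is the standard
left-first recursive traversal; the heat-map export only permutes the
matrix.

## Target integration

The screen chains four filters: (1) consensus prediction (≥3 of the 5
standard databases; DIANA-microT votes are ignored for standard miRNAs
and only count toward the 2-of-3 rule for alternative mature miRNAs);
(2) a differential-expression gate — both members significant in the
case–control comparison with opposite fold-change signs, which is how
"inverse co-expression" is interpreted at this stage (the explicit
negative-ρ requirement is enforced later, at significance calling);
(3) clinical gene-set restriction, with all matching categories recorded
and the display label taken in the fixed priority order UC
susceptibility → barrier → CAM → AMP; (4) Spearman screening over
subjects profiled on both platforms in the active UC and control groups
(15 in the default design), B–H over exactly the tested pairs, and a
final call at p < 0.05 with ρ < 0. Genes with several probe sets are
represented by the probe with the smallest DE p (ties broken
lexicographically). Filters (2) and (3) commute, which the tests check.

## qPCR validation

Replicate Cts are averaged arithmetically per sample, ΔCT = Ct_target −
Ct_reference, ΔΔCT subtracts the calibrator group's mean ΔCT (so the
calibrator's geometric-mean relative quantity is exactly 1), and
rq = 2^−ΔΔCT. The quantity is invariant to per-sample Ct shifts that
move target and reference together. Group comparisons use Mann–Whitney
on per-sample rq; the reported fold change is the ratio of group means
under the signed convention. Concordance with the array compares
directions only. Amplification-efficiency correction and undetermined-Ct
modelling are out of scope (undetectable assays are excluded, not
imputed).

## Synthetic-study generator

The generator emulates the paired design: subjects A01–A10 (active UC),
I01–I07 (inactive UC), C01–C10 (control) on the miRNA platform, with the
first 7/6/8 of them re-profiled on the mRNA platform, giving 15 matched
active+control subjects for the correlation stage. Defaults: 300 miRNAs
and 2000 genes (scaled down from ~1100 mature-miRNA probe sets and ~20k
genes for desk-scale runtime, with paper-like DE fractions: 20 DE
miRNAs, 150 DE genes), baseline log2 intensities uniform on [4, 12],
planted |log2FC| = 1.5 in the active group only, within-group noise sd
0.5, 50 planted repressive pairs at population Spearman ρ = −0.85, five
prediction databases at sensitivity 0.9 with a 2 % false-prediction rate
per (miRNA, gene, database), 5 % of genes carrying a duplicate probe
set, and a clinical catalog containing every planted target gene
(round-robin over the four categories) plus ~10 % of background genes —
so the clinical filter is exercised without by itself deciding recovery.

**Correlation planting.** A planted pair's population ρ is defined over
the population the screen actually samples: the active+control mixture
of matched subjects. Part of the correlation is contributed by the
opposite planted fold changes themselves; the remainder comes from a
per-subject latent severity factor, one independent factor per planted
miRNA, loaded with opposite signs on the miRNA and its target genes. The
loading is carved out of the configured noise variance, so planted
features keep the same marginal within-group sd as every other feature
(as on a real array, where a feature's variance does not advertise its
regulatory role); the split is calibrated once by bisection on a large
fixed-seed Monte Carlo population of the mixture. If the requested ρ
cannot fit inside the noise budget the latent variance is added on top
instead, with a warning. One latent factor per miRNA (rather than one
global factor) keeps sampling fluctuations independent across pairs.

**Ct companion tables.** Ct values are the inverse transform of the
expression matrix (Ct = 32 − log2 expression plus N(0, 0.1) replicate
noise, constant reference Ct 20, duplicate reactions), so the 2^−ΔΔCT
pipeline recovers the matrix's empirical group fold changes to within
the Ct noise.

**What the generator does not emulate:** probe-level hybridization
artifacts, batch effects, heteroscedastic or intensity-dependent noise,
miRNA family/seed structure (database errors are independent across
pairs, unlike real prediction algorithms which err systematically on
families), correlated false predictions, or missing values. Passing the
recovery tests therefore demonstrates that the pipeline's logic and
statistics behave as designed under the declared generative model — not
that real GEO data would yield the published pair counts, which depend
on the original raw arrays, the 2010–2013 database snapshots and
unpublished gene lists.

## Pipeline and problem sizes

The orchestrated run executes simulate/load → (optional) normalize → DE
per comparison → clustering → integration → qPCR validation → report,
writing TSV/JSON per stage and a manifest of SHA-256 hashes; identical
seed and configuration reproduce identical bytes. Report numbers are all
recomputable from the shipped stage outputs. The acceptance script uses
the default study dimensions (300×27 and 2100×21 matrices), 1000 planted
pairs for the consensus-recall check, and 20 independent unplanted
studies for the null control — sizes chosen to keep a full
reproduction run under a minute on one CPU while leaving the binomial
and FDR expectations tight.

## Known limitations

- Single-factor two-group designs only; no paired-sample or multi-factor
  models, no batch correction.
- The moderated fit assumes a scaled-F variance model; heavy-tailed
  variance outliers are not robustified (no trend or robust options).
- The exact Mann–Whitney branch requires tie-free data; discrete data of
  small size fall back to the tie-corrected normal approximation.
- The alternative-miRNA 2-of-3 consensus rule is exercised by unit tests
  but not by the default generator, which plants only standard-rule
  predictions.
- Live prediction-database queries, probe-level normalization (RMA),
  array QC and pathway analysis are out of scope.
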