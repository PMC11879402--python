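# Methods

## Model

Each gene is modeled independently per cohort.  Let *y* be the gene's
expression across *n* samples after preprocessing, and let the predictor
universe be partitioned into six regulator classes: miRNA expression, TF
expression, lncRNA expression, methylation (M-values), gene-level copy
number, and SNP dosages.  For every non-empty class subset *S* (63 when
all six classes have admissible features) we fit

    min_b  (1/2n) Σᵢ (yᵢ − b₀ − xᵢᵀb)²  +  λ (α‖b‖₁ + (1−α)/2 ‖b‖₂²)

with mixing α = 0.5, i.e. the ℓ₁ and squared-ℓ₂ terms carry weights
0.5 λ and 0.25 λ.  This penalty convention is implemented bit-exactly in
`_solver.py` (the coordinate update divides the soft-thresholded
covariance by `C_jj/n + λ(1−α)`), and agrees with scikit-learn's
`ElasticNet(alpha=λ, l1_ratio=0.5)`, which the test-suite uses as an
independent oracle.

### Feature admission

- Positional classes (methylation probes, SNPs, lncRNAs) are admitted
  within a cis-window of ±1 Mb around the gene's boundaries, *inclusive*
  at exactly ±1,000,000 bp (the boundary case is fixture-tested).
  lncRNAs whose interval intersects the gene body are excluded so a gene
  is never predicted by its own overlapping transcript.
- TFs and miRNAs are admitted through explicit regulator→gene target
  maps; a gene absent from a map simply loses that class.
- CNV contributes one column: the gene's own copy-number value.
- A spec is only fitted when **every** member class contributes at least
  one column; otherwise it would duplicate a smaller spec's design and
  bias the paired-difference gains.  Skips are recorded with reasons and
  excluded pairs are reflected in the gain's reported denominator.

### Scoring: leave-one-out PRESS R²

λ is selected once per (gene, spec) by 10-fold cross-validation over a
descending log-spaced path (30 values, λ_max down to 10⁻³ λ_max, where
λ_max is the smallest λ with an all-zero solution), then held fixed while
each sample is left out and the model refit to convergence on the
remaining n−1.  PRESS R² = 1 − SSE/TSS with SSE = Σᵢ(yᵢ − ŷ₋ᵢ)².
Holding λ fixed across folds is ~10× cheaper than nested selection; the
optimism it can introduce is precisely what the deflation correction and
the negative null baseline guard against, and the exactness of the
refits themselves is verified against brute-force per-fold refits from
scratch to 1e-8.

The refits use centered Gram-matrix downdates: the full-data moments
(XᵀX, Xᵀy, column sums) are computed once and each leave-one-out or
leave-fold-out subproblem is a rank-one/few correction, solved by
warm-started coordinate descent (tolerance 1e-10 on the max coefficient
change).  Subsets are re-centered but not re-scaled: the penalty applies
on the cohort-wide standardized scale, matching the fixed-λ contract.

### Deflation

The null distribution of PRESS R² is not centered at 0: even the
intercept-only model scores 1 − (n/(n−1))² < 0.  Per gene we draw
ŷ₋ᵢ ~ Normal(mean₋ᵢ, sd₋ᵢ) (moments of the sample without i, n−1
denominator) and average the resulting PRESS R² over `deflation_runs`
Monte-Carlo replicates; the expectation is
E[SSE] = (n/(n−1))²·TSS + Σᵢ sd₋ᵢ², ≈ −1 for standardized y.  Values > 0
are subtracted from every model's score; one deflation value is shared
by all 63 specs and the null baseline of a (gene, cohort), since it
depends only on y — and because gains are paired differences, this
uniform application provably cannot change any gain.  The default is
1000 runs (configurable up to 10,000): at 1000 runs the Monte-Carlo
standard error of the deflation value is ~0.005 for n = 100, far below
the gains it corrects.

### Per-class gains

gain(c) = mean over all subsets *S* of the remaining classes (including
the empty set, scored by the null baseline) of press(S ∪ {c}) −
press(S); 32 paired differences for six classes.  This is the Banzhaf
value of the set function press(·) and recovers each class's weight
exactly when the ensemble is additive (tested to 1e-12 by brute force
over all 64 subsets).  Gains are computed on **deflated** scores; since
deflation is uniform per gene this equals the raw-score gain, and both
are available.  Conditional gains restrict backgrounds to those
containing (`include`) or avoiding (`exclude`) given classes; the
pair-count-weighted average of the two halves of any partition
reconstructs the unconditional gain exactly.

### Transfer

Tumor-trained coefficients are applied unchanged (no refitting, no
leave-one-out) to the preprocessed tumor-adjacent cohort; transfer R² is
the plain out-of-sample 1 − SSE/TSS.  Model features missing from the
adjacent cohort contribute zero, i.e. their mean on the standardized
scale.  Adjacent-tissue gains use the same paired-difference mean on
transfer scores, with the null baseline transferring as the training
mean.  A (gene, class) pair is classified `both` / `tumor_only` /
`adjacent_only` / `neither` by comparing the tumor and adjacent gains to
a threshold, default strictly > 0 ("non-zero prediction"); an epsilon
threshold is available.

## Preprocessing

Every matrix follows the same recipe: optional log(x+1) (expression
counts), per-feature z-score (n−1 denominator throughout), OLS
residualization against the covariate design, re-standardization.
Tumor cohorts are corrected for sex, batch, the first two genotype
principal components, tumor purity, age and histology jointly in one
linear model per feature; tumor-adjacent cohorts use the reduced design
(sex, batch, PC1, PC2) in a separate model.  The joint (rather than
sequential) OLS is a design choice; residualization is idempotent and
leaves residuals orthogonal to the design to 1e-8.  Methylation beta
values are clipped to [1e-6, 1 − 1e-6] and mapped to
M = log₂(β/(1−β)) before standardization.

SNP quality control applies, in order: SNP missingness > 0.1 removed,
sample missingness > 0.05 removed, Hardy–Weinberg 1-df chi-square
p < 1e-5 removed, minor allele frequency < 0.05 removed (strict
inequality: MAF exactly 0.05 survives).  The "call rate" wording for the
missingness thresholds is ambiguous in common usage; both the literal
reading (implemented as default) and the PLINK-conventional reading sit
behind `interpret_call_rate`.  Sample outliers are removed beyond 6
standard deviations on any of the first five principal components, with
one recomputation after removal; the final top-2 PCs feed the covariate
table.

## Synthetic cohorts

The generator emulates the *structure* of a TCGA-like cohort, not its
biology.  Per gene, expression is Σ_c √share_c · u_c + covariate term +
noise, where u_c is an empirically standardized linear combination of
that gene's causal features (Gaussian weights — a modeling convenience,
not a claim about real effect-size distributions) and shares + noise sum
to 1.  Causal sets are disjoint across classes and draws independent, so
realized shares match the configured truth to within sampling error
(±0.03 at n = 1000 over 20 replicates, by test); an optional shared
latent factor produces correlated regulators instead.  SNP dosages are
binomial(2, MAF) with MAF ~ U(0.05, 0.5) — the post-QC universe, under
Hardy–Weinberg, with no linkage disequilibrium.  Methylation is emitted
on the beta scale through the inverse M-transform so the conversion is
exercised.  A per-sample confounder score (built only from covariates
the correction model of that tissue can see) enters both features and
expression, making residualization consequential.  Tissue-specific
classes contribute zero variance in the other tissue, their share moving
to noise.  Default shares (TF 0.20, METH 0.15, others 0.05, noise 0.45)
reflect the typical ordering in multi-omic expression modeling: TF
co-expression strongest, methylation next, the rest minor.

What passing tests on these cohorts show: the estimator recovers known
additive variance shares under confounding, and transfer classification
separates shared from tissue-specific signal.  What they cannot show:
behaviour under LD, cell-type composition shifts, non-linear regulation
or heavy-tailed counts — on real data gains remain relative, not
absolute variance fractions.

## Clustering, labels, enrichment

Genes modelable in every cohort are clustered per cohort on their 63
deflated scores with Ward-linkage hierarchical clustering (deterministic;
a seeded k-means mode exists behind a flag; the choice of algorithm and
the use of deflated unscaled features are both configurable because
neither is forced by the method).  Candidate k values are scored by the
Dunn index (maximized) with connectivity (L = 10 nearest neighbours,
penalty 1/rank) as tie-breaker, each verified against brute-force O(n²)
computations; singleton-cluster diameters are floored at machine epsilon.
The default k is 20.  Cluster labels contain every class whose mean gain
over member genes is positive and ≥ half the top class's mean; labels are
grouped across cohorts as unordered sets.  Enrichment uses the
upper-tail hypergeometric probability of the overlap between a gene set
and the genes with gain strictly > 0.25 for a class, with
Benjamini–Hochberg adjustment; the universe defaults to the genes that
have gains, because gains are only defined there.

## Problem sizes and numerical choices

The test and acceptance suites run the method end to end at n = 120–500
samples and 8–50 genes — sizes at which the share-recovery and transfer
properties are already stable (Spearman ≈ 0.81 between true shares and
gains at 50 genes × n = 500; 100% of tumor-specific CNV pairs classified
tumor_only at 24 genes × n = 250).  Coordinate descent uses tolerance
1e-10 and warm starts along the λ path and across leave-one-out refits;
ties in cluster-label ordering break by the canonical class order
MIRNA < TF < LNCRNA < METH < CNV < SNP; degenerate inputs (constant
response, empty designs, singleton clusters, zero-variance gain vectors)
raise or return absent values explicitly rather than NaNs.

## Known limitations

- λ fixed from full-data CV across LOO refits (see above) is the largest
  deviation risk relative to a fully nested workflow.
- Gains of correlated regulator classes share variance; the
  decomposition reports, and conditional gains expose, but do not
  resolve, mediation direction.
- SNP gains are attenuated relative to their true share (discrete
  dosages + shrinkage), visible in the synthetic recovery runs; rank
  order is preserved.
- The transfer evaluation assumes feature scales are comparable after
  per-tissue standardization; missing features fall back to the mean.
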