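# imodest

Which regulatory layer actually explains a gene's expression — the
transcription factors binding it, the miRNAs targeting it, nearby
methylation, its copy number, cis-SNPs, or neighbouring lncRNAs?
`imodest` answers this per gene by fitting predictive models of
expression from **every combination of six regulator classes** and
decomposing out-of-sample accuracy into per-class gains.

It is aimed at computational biologists working with paired multi-omic
cohorts (expression + miRNA + methylation + CNV + genotypes from the same
samples, TCGA-style) who want a gene-level map of regulatory drivers, and
ships a synthetic multi-omic cohort generator with known ground-truth
variance shares so the entire pipeline is testable without any
controlled-access data.

## The method

For each gene *g* with standardized, covariate-corrected expression *y*:

1. **Feature admission.** Methylation probes, SNPs and lncRNAs within
   ±1 Mb of the gene's boundaries (lncRNAs overlapping the gene body are
   excluded); TFs and miRNAs with curated target evidence for *g*; the
   gene's own copy-number value.
2. **Model ensemble.** For every non-empty subset *S* of the six classes
   (2⁶ − 1 = 63 models), fit an elastic net with mixing parameter 0.5;
   the penalty λ is chosen by 10-fold cross-validation and then held
   fixed.
3. **Scoring.** Leave-one-out PRESS R² = 1 − SSE/TSS, where each sample
   is predicted by a model exactly refit without it.  The intercept-only
   null scores 1 − (n/(n−1))² < 0.
4. **Deflation.** Random predictions ŷ₋ᵢ ~ N(mean₋ᵢ, sd₋ᵢ) define a
   per-gene deflation value (mean PRESS R² over 1000 Monte-Carlo runs);
   positive deflation values are subtracted, so scores > 0 indicate
   genuine signal.
5. **Per-class gain.** The gain of class *c* is the mean of
   press(S ∪ {c}) − press(S) over all 32 subsets *S* of the other
   classes — a Banzhaf-style group value that is exact for additive
   ensembles.  Conditional gains restrict the backgrounds (e.g. "SNP
   gain given methylation is already in the model") and expose mediation.
6. **Transfer.** Tumor-trained coefficients applied unchanged to
   tumor-adjacent samples give a transfer R² per model; gene–class pairs
   are classified as transferring to `both` tissues, `tumor_only`,
   `adjacent_only` or `neither`.
7. **Clustering & enrichment.** Genes are Ward-clustered on their 63
   scores, clusters labeled by every class reaching half the top class's
   mean gain, and well-predicted genes (gain > 0.25) tested for gene-set
   over-representation (hypergeometric + Benjamini–Hochberg).

## Worked example

```python
from imodest import SimulationConfig
from imodest.model import RegulatorDecomposition

cfg = SimulationConfig(n_samples=200, n_genes=8, seed=11)
res = RegulatorDecomposition.from_simulation(cfg, deflation_runs=500).fit()
print(res.summary())
```

```
Regulator decomposition of expression variance
cohort: tumor   genes: 8   samples: 200
------------------------------------------------------------------------
class      mean gain  median gain    mean adj    r(T,N)  n pairs
MIRNA         0.0293       0.0303      0.0400    -0.031       32
TF            0.1756       0.1815      0.2101     0.426       32
LNCRNA        0.0415       0.0454      0.0434    -0.030       32
METH          0.1213       0.1209      0.1040     0.107       32
CNV           0.0573       0.0600      0.0251    -0.347       32
SNP           0.0215       0.0156     -0.0026     0.387       32
------------------------------------------------------------------------
gain: mean PRESS R² increase when the class joins every background model
```

The default generator gives every gene true variance shares of
TF = 0.20, METH = 0.15 and 0.05 for the other classes: the fitted mean
gains (TF 0.18, METH 0.12, others 0.02–0.06) recover that ordering, with
SNP gains attenuated by the discreteness of dosages.  `mean adj` is the
same gain computed from the transfer R² on the paired tumor-adjacent
cohort; `res.transfer().summary` tabulates, per class, the percentage of
genes whose predictive signal transfers to both tissues.

The same stages are available from the shell:

```bash
imodest simulate --config configs/small.yaml --out sim/ --seed 1
imodest fit --cohort sim/tumor --adjacent sim/adjacent --seed 1 --out fits/
imodest decompose --fits fits/scores_tumor.tsv --out dec/
imodest run --config configs/small.yaml --out run/ --seed 1   # everything
```

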