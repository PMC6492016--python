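# prsvm

Polygenic risk scores versus kernel support vector machines for
case–control classification from SNP genotypes.

## The problem

For highly polygenic disorders such as schizophrenia, the standard
predictor is the **polygenic risk score** — a weighted sum of risk-allele
counts,

```
PRS_i = Σ_j β_j · g_ij
```

where `g_ij ∈ {0,1,2}` counts the effect allele of SNP *j* in individual
*i* and `β_j` is that SNP's log odds ratio estimated by univariable
logistic regression on a training sample (or taken from GWAS summary
statistics).  Soft-margin SVMs offer a multivariate alternative: a linear
kernel (hyperparameter `C`) mirrors an additive model, while an RBF kernel
(`C`, `γ`) can represent SNP×SNP interactions that single-SNP tests cannot
see — for example XOR two-locus models, which carry risk with *exactly
null* marginal effects when each locus's carrier probability is ½
(MAF `1 − √½ ≈ 0.293`).

`prsvm` implements the full comparison pipeline as a reusable library:

- **`prsvm.cohort`** — case–control simulator with a logistic liability
  model, additive and XOR-epistatic architectures, retrospective
  (draw-until-quota) sampling and MCAR missingness, with the intercept
  solved so the population prevalence hits a target `K`;
- **`prsvm.io` / `prsvm.qc`** — a PLINK-`.raw`-style dialect plus a GWAS
  QC stack: probability hard-calling (> 0.9), missingness < 2 %,
  MAF ≥ 10 %, Hardy–Weinberg χ² p ≥ 1e-4 in controls, MHC exclusion
  (chr6:25–34 Mb), association-aware LD pruning (500 kb window, r² > 0.1)
  and multinomial imputation;
- **`prsvm.prs` / `prsvm.svm`** — per-SNP logistic weights, weighted-allele
  scoring with allele-orientation resolution, midrank AUC-ROC, and SVM
  training with train-side standardization, stratified 4-fold CV and a
  Monte-Carlo hyperparameter search (`C ~ Exp(mean 1)`,
  `γ ~ Exp(mean 0.01)`);
- **`prsvm.experiment`** — repeated stratified 75/25 splits *shared across
  methods*, AUC distributions and Welch t-test comparisons;
- **`prsvm.twosnp`** — the ascertainment study: independent risk SNPs
  become positively correlated in a case–control sample, and the 1-df PRS
  test systematically out-powers the k-df multivariate regression.

## Worked example

`examples/05_ascertainment_correlation.py` (all examples run in seconds):

```
mean Pearson r between two INDEPENDENT risk SNPs (100 sims/cell):
 or_value  mean_r_all  mean_r_cases  mean_r_controls
      1.0     -0.0016       -0.0028          -0.0004
      2.0      0.0504       -0.0026          -0.0034
      3.0      0.1197       -0.0127          -0.0063
      4.0      0.1781       -0.0244          -0.0101
-> near zero within cases and within controls, but the combined
   case/control sample shows r growing with OR.

PRS p-value smaller than the 2-df multivariate p-value in 97% of
simulations (median log10 ratio -0.79)
```

The two SNPs are simulated independently, yet retrospective sampling at 1 %
prevalence enriches both risk alleles among cases, inducing a combined-sample
correlation that grows with the odds ratio while within-group correlations
stay near zero.  Because selected SNPs share this disease-driven direction,
summing them into one score concentrates the signal: the PRS p-value beats
the joint regression in ~97 % of simulations.

The other examples cover cohort simulation (`01`), the QC stack (`02`), the
three-way PRS/SVM-linear/SVM-RBF comparison on additive data (`03`, where
PRS edges out the linear kernel and the RBF kernel gains nothing), and XOR
epistasis (`04`, where a tuned RBF kernel scores AUC ≈ 0.68 while marginal
tests and the linear kernel see nothing, gap ≈ +0.16).

A thin CLI mirrors the library (`prsvm simulate-cohort`, `qc`, `prs`,
`svm-tune`, `compare`, `twosnp-grid`, `twosnp-pvalues`); every stage is
byte-deterministic given `--seed`.

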