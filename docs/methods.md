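# Methods

## Disease model

An individual with genotype vector `g` (allele counts) is a case with
probability

```
P(case | g) = expit( β0 + Σ_j β_j g_j + Σ_(a,b) θ_ab · XOR(b_a, b_b) )
```

with dominant carrier indicators `b_j = 1(g_j ≥ 1)`.  Effects are additive
on the log-odds scale because the quantities of interest throughout the
package are odds ratios; a liability-threshold parameterization is out of
scope.  Genotypes are independent Binomial(2, MAF) draws — Hardy–Weinberg
proportions in expectation, no linkage disequilibrium — reflecting the
LD-pruned marker panels the comparison is designed for.

The intercept `β0` is solved so that the *population* mean penetrance
equals the prevalence `K`: the expectation is computed by exact enumeration
of the genotype grid at the active loci (all loci with nonzero `β` or in an
XOR pair) whenever `3^m ≤ 60 000`, i.e. up to ten active loci, and
otherwise by Monte Carlo with a fixed 400 000-draw sample and fixed
internal seed; Brent root-finding then drives the residual below 1e-12.
The enumeration bound is generous rather than the minimal "few loci" case
simply because the exact path is cheap up to `3^10` and removes Monte-Carlo
noise from the ten-SNP power study.

### Retrospective sampling

Cohorts are drawn the way case–control panels are actually assembled:
individuals are sampled from the population model and retained until exact
case and control quotas are met.  This enriches risk alleles among cases
relative to `K` and is the mechanism behind the package's central
phenomenon — independent risk SNPs acquiring a positive correlation in the
combined sample.  The attempt budget is `50 × (n_cases/K +
n_controls/(1−K))` draws by default; exceeding it (vanishing `K`) raises a
diagnostic error rather than returning a short cohort.

### Prevalence default

`K = 0.01` throughout (CohortSpec and TwoSnpConfig).  Two reasons.  First,
1 % is a realistic lifetime prevalence for a schizophrenia-like disorder.
Second, the regime matters qualitatively: at 1 % the penetrance stays far
from logistic saturation even at OR = 4, so conditioning on case status
induces only a small "explaining-away" (collider) correlation *within*
cases — the regime in which within-group correlations are approximately
zero while the combined sample is strongly correlated, and in which the
ascertainment-induced correlation among selected SNPs gives the PRS its
systematic edge over multivariate fits.  At K = 0.1 the within-case
collider correlation at OR = 4 (≈ −0.13) would exceed the combined-sample
correlation and the PRS/linear-SVM ordering on additive cohorts becomes a
coin flip.  `K` is a plain config field; nothing depends on the default
beyond these regimes.

### XOR architecture

XOR pairs use dominant carrier coding.  The default MAF for XOR loci is
`1 − √½ ≈ 0.2929`, which makes the carrier probability exactly ½: the XOR
indicator is then independent of each single locus, so marginal per-SNP
effects are *exactly* null while the pair carries full interaction risk.
At any other MAF the marginals leak — supported and tested, but documented
as a property of the architecture, not an error.  Missingness is entrywise
independent (MCAR); no informative-missingness mechanism is modeled.

### Randomness

Each cohort derives every sub-draw (genotypes, phenotypes, row shuffle,
missingness) from one root seed via `numpy` `SeedSequence` spawning, so
cohorts are reproducible bit for bit and sub-streams are independent.

## QC stack

Order: hard-call → missingness → MAF → HWE → region exclusion → LD prune →
multinomial imputation.  Numerical conventions, chosen where the usual
practice leaves slack:

- hard-calling keeps a genotype only when its probability is **strictly**
  greater than the 0.9 threshold;
- the missingness filter removes SNPs at rate ≥ 2 % (i.e. "< 2 %" keeps);
- MAF is computed on non-missing entries and the 10 % boundary is
  **inclusive**;
- HWE is a 1-df χ² goodness-of-fit test computed in controls only
  (configurable to all samples); an exact test is deliberately not the
  default since only a p-value floor of 1e-4 is specified;
- excluded regions are closed intervals in 1-based base pairs, default
  chr6:25,000,000–34,000,000;
- LD pruning is greedy in ascending association p-value (keeping the most
  associated SNP of each correlated clique), ties broken deterministically
  by (p, chromosome, position, id), window ±500 kb, removal at r² > 0.1 on
  pairwise-complete genotypes;
- multinomial imputation draws each missing call from the SNP's observed
  genotype frequencies and never touches observed entries; a SNP with no
  observed calls is an error, not a silent fill.

Every step returns a report (n in, n out, removed ids) whose counts
reconcile exactly; the stack is idempotent on its own output.

## PRS and SVM protocol

PRS weights default to per-SNP univariable logistic betas fitted on the
training side of each split; external summary statistics can substitute
through the same table (SNP, effect allele, β or OR, SE, p).  Wald
p-values are used per SNP (cheap at scale; a likelihood-ratio variant
would change nothing material).  Perfect separation caps |β| at 20 with a
flag.  Scoring resolves allele orientation: if the target matrix counts
the other allele, `2 − g` is used; irreconcilable alleles are an error.
AUC-ROC uses the midrank convention — exactly the probability a random
case outranks a random control with ties counted half — and is computed
from continuous decision values, never hard class predictions.

SVMs standardize features to zero mean and unit variance with parameters
fitted on the training matrix only; zero-variance training columns are
dropped everywhere with a diagnostic.  Hyperparameters are proposed by
Monte-Carlo draws `C ~ Exponential(mean 1)` and, for RBF,
`γ ~ Exponential(mean 0.01)`, scored by stratified 4-fold CV AUC on
identical folds, ties broken toward smaller `C` then smaller `γ`.  The
exponential parameters are interpreted as **scale** (mean), not rate: only
mean-0.01 proposals concentrate on the small `γ` values (~0.02) that are
near-optimal for standardized SNP data, consistent with the observation
that smaller hyperparameters classify better here; a rate interpretation
is available by flag.  Tuning is two-phase — search on a 90 % split with
the 10 % holdout reporting an unbiased AUC for the selected config — and
tuned values are reused across the repeated evaluation splits rather than
re-tuned per split.

The comparison experiment draws stratified 75/25 train/test splits shared
by all methods (one split per replicate seed; `base_seed + r` for
replicate *r*, ledgered to disk by the CLI), fits everything on the
training side, and compares replicate AUC vectors with Welch's t-test by
default (Student and split-paired variants by flag — pairing is natural
here since splits are shared, but unpaired is the default to stay
conservative).

## Two-SNP study

Defaults: 10 000 individuals per simulation (5 000/5 000 balanced,
configurable), 1 000 simulations per cell, OR grid {1, 1.5, 2, 2.5, 3,
3.5, 4} (the spacing is a package choice), MAF ∈ {0.2, 0.3}, `K = 0.01`.
Pearson correlations are computed on raw allele counts overall, within
cases and within controls; a zero-variance genotype in a subset yields
`nan`, never a silent 0, and nan-aware averaging excludes such cells.

The power comparison at OR = 1.2, MAF = 0.3 defines `p_prs` as the Wald
test of the single score coefficient, the score being the true-β-weighted
allele sum (with equal ORs this equals the plain sum up to scale, to which
the p-value is invariant; at OR = 1 the weights would vanish, so unit
weights are used).  `p_multivariate` is the k-df likelihood-ratio test of
the joint model against intercept-only; per-coefficient Wald minima are
available but not the default since the joint LRT is the natural "all SNPs
as separate predictors" test.

## What the simulator does and does not emulate

It reproduces: HWE genotype sampling, case–control ascertainment and its
induced correlation, additive log-odds architectures with realistic ORs,
purely epistatic XOR pairs, MCAR missingness, and probability triples for
hard-calling.  It does **not** model LD between markers, haplotypes, sex
chromosomes, ancestry/batch structure, covariates, or informative
missingness.  Passing tests therefore demonstrate the statistical
machinery and the ascertainment phenomenon, not robustness to population
structure or array batch effects in real cohorts.

## Problem sizes

The test suite and the acceptance script run reduced but adequate sizes,
chosen so every Monte-Carlo comparison has comfortable margin over its
standard error: 200 simulations per grid cell (cell means have SE ≈ 0.001,
far below the effects measured), 20 evaluation splits per classifier
comparison, 100 replicates for effect-recovery bias, cohorts of 4 000 for
the classifier experiments.  The XOR RBF-vs-linear gap (~0.16) and the
induced-correlation ordering are order-of-magnitude robust to these
choices.

## Known limitations

- Within-group collider correlations are only *approximately* zero: at the
  grid extreme (OR = 4, MAF 0.2) the mean within-case r reaches ≈ −0.03,
  visible in the grid output; it remains several-fold smaller than the
  combined-sample correlation.
- On purely additive cohorts the tuned-RBF search correctly collapses
  toward the near-linear limit (tiny γ), so "plausible γ" checks are only
  meaningful on data containing interactions.
- Per-SNP logistic fits loop over SNPs via statsmodels; adequate for the
  panel sizes here (≤ thousands of SNPs), not for genome-wide use.
- The PRS-over-linear-SVM median AUC edge on additive data is real but
  small (≈ +0.001–0.004 at the default sizes); at prevalence 0.1 it
  disappears into split noise, as documented above.
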