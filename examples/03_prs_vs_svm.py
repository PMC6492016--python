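"""Compare PRS, linear-kernel SVM and RBF-kernel SVM on one cohort.

Runs the repeated shared-split protocol (stratified 75/25 splits, per-SNP
logistic weights and SVM models fitted on the training side only) on an
additive cohort, prints each method's AUC-ROC distribution summary and the
pairwise Welch t-tests on the replicate AUC vectors.
"""

import numpy as np

from prsvm import CohortSpec, compare_methods, run_experiment, sample_case_control
from prsvm.experiment import default_methods

spec = CohortSpec(
    n_cases=1000,
    n_controls=1000,
    n_snps=20,
    causal_betas=(float(np.log(1.3)),) * 20,
    seed=3,
)
cohort = sample_case_control(spec)

result = run_experiment(
    cohort.genotypes, cohort.phenotype, default_methods(), n_reps=20, base_seed=100
)
print("AUC-ROC over 20 stratified 75/25 splits (shared across methods):")
print(result.summary.round(4).to_string(index=False))

for a, b in [("prs", "svm-linear"), ("prs", "svm-rbf"), ("svm-linear", "svm-rbf")]:
    c = compare_methods(result.auc_vector(a), result.auc_vector(b))
    print(f"{a} vs {b}: mean diff {c.mean_diff:+.4f}, Welch t={c.t:.2f}, p={c.p:.3g}")
print("On additive data the PRS should edge out the linear SVM, and the "
      "RBF kernel gains nothing (no interactions to find).")
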