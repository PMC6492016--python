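"""Why PRS outperforms multivariate models on selected SNPs.

Two independent risk SNPs become positively correlated in a case-control
sample because both risk alleles are over-represented among the enriched
cases.  This script computes the induced correlation across an OR grid and
then compares the association p-value of the one-degree-of-freedom PRS
score against the joint two-predictor regression.
"""

import numpy as np

from prsvm import TwoSnpConfig, pvalue_comparison, run_correlation_grid

config = TwoSnpConfig(n_individuals=10_000, n_sims=100, maf_set=(0.3,), seed=1)
grid = run_correlation_grid(config).table
print("mean Pearson r between two INDEPENDENT risk SNPs (100 sims/cell):")
print(grid[["or_value", "mean_r_all", "mean_r_cases", "mean_r_controls"]]
      .round(4).to_string(index=False))
print("-> near zero within cases and within controls, but the combined "
      "case/control sample shows r growing with OR.\n")

table = pvalue_comparison(or_value=1.2, maf=0.3, config=config, n_snps=2)
frac = (table["p_prs"] < table["p_multivariate"]).mean()
ratio = np.median(np.log10(table["p_prs"] / table["p_multivariate"]))
print(f"PRS p-value smaller than the 2-df multivariate p-value in "
      f"{frac:.0%} of simulations (median log10 ratio {ratio:+.2f}):")
print("concentrating the shared signal in one score direction buys power.")
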