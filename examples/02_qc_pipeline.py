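"""Run the GWAS-style QC stack on a contaminated cohort.

Simulates a cohort with 1% missing calls, applies the full filter stack
(missingness < 2%, MAF >= 10%, HWE p >= 1e-4 in controls, MHC exclusion,
association-aware LD pruning, multinomial imputation) and prints the
per-step report: how many SNPs entered, survived, and which were removed.
"""

import numpy as np

from prsvm import CohortSpec, QcConfig, apply_qc, sample_case_control

spec = CohortSpec(
    n_cases=400,
    n_controls=400,
    n_snps=15,
    causal_betas=(float(np.log(1.5)),) * 5 + (0.0,) * 10,
    maf_range=(0.05, 0.5),  # some SNPs will fail the 10% MAF filter
    missing_rate=0.01,
    seed=7,
)
cohort = sample_case_control(spec)
print(f"input: {cohort.genotypes.n_snps} SNPs, "
      f"{np.isnan(cohort.genotypes.values).mean():.3%} missing calls")

clean, reports = apply_qc(cohort.genotypes, cohort.phenotype, QcConfig(), seed=1)
for r in reports:
    removed = ",".join(r.removed_ids) if r.removed_ids else "-"
    print(f"  {r.step:<12} {r.n_in:>3} -> {r.n_out:>3}  removed: {removed}")
print(f"output: {clean.n_snps} SNPs, "
      f"{np.isnan(clean.values).mean():.3%} missing calls (imputation fills all)")
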