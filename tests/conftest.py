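import numpy as np
import pytest

from prsvm import CohortSpec, sample_case_control

LOG_OR_13 = float(np.log(1.3))
LOG_OR_20 = float(np.log(2.0))


@pytest.fixture(scope="session")
def additive_cohort():
    """Small case-control cohort: 4 causal SNPs (OR 2) + 4 null SNPs."""
    spec = CohortSpec(
        n_cases=400,
        n_controls=400,
        n_snps=8,
        causal_betas=(LOG_OR_20,) * 4 + (0.0,) * 4,
        mafs=(0.3,) * 8,
        seed=1234,
    )
    return sample_case_control(spec)


@pytest.fixture(scope="session")
def xor_cohort():
    """Cohort driven purely by two XOR pairs (marginal-nulling MAF) + nulls."""
    spec = CohortSpec(
        n_cases=500,
        n_controls=500,
        n_snps=12,
        epistatic_pairs=((0, 1, 1.5), (2, 3, 1.5)),
        seed=4321,
    )
    return sample_case_control(spec)
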