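"""Case-control-induced correlation between independent risk SNPs, and the
power comparison of PRS against multivariate logistic regression.

Two (or more) SNPs are simulated independently under Hardy-Weinberg
proportions, each raising disease risk additively on the log-odds scale.  A
retrospective case-control sample over-represents cases relative to the
population prevalence; because both risk alleles are enriched in cases, the
SNPs become positively correlated in the combined sample even though they
are independent in the population and approximately uncorrelated within
cases and within controls separately.  The same machinery compares the
association p-value of a single-score PRS predictor (1 df) against a joint
model with each SNP as its own predictor (k df likelihood-ratio test):
concentrating the signal in one direction buys the PRS systematic power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import linear_predictor, solve_intercept

__all__ = [
    "TwoSnpConfig",
    "CorrelationGridResult",
    "simulate_two_snp_cohort",
    "correlation_by_group",
    "run_correlation_grid",
    "pvalue_comparison",
]

DEFAULT_OR_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class TwoSnpConfig:
    n_individuals: int = 10_000
    n_sims: int = 1_000
    or_grid: tuple[float, ...] = DEFAULT_OR_GRID
    maf_set: tuple[float, ...] = (0.2, 0.3)
    # Population prevalence of the simulated disease.  At 1% (a realistic
    # figure for schizophrenia) the logistic penetrance stays far from
    # saturation across the whole OR grid, so conditioning on case status
    # induces only a negligible within-group (collider) correlation — the
    # regime in which within-case and within-control correlations are
    # approximately zero while the combined sample is strongly correlated.
    prevalence: float = 0.01
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_sims <= 0:
            raise ValueError("n_individuals and n_sims must be positive")
        if not self.or_grid or not self.maf_set:
            raise ValueError("or_grid and maf_set must be non-empty")
        if any(o < 1.0 for o in self.or_grid):
            raise ValueError("represent protective effects by allele flip; ORs must be >= 1")
        if not 0.0 < self.prevalence < 1.0 or not 0.0 < self.case_fraction < 1.0:
            raise ValueError("prevalence and case_fraction must lie in (0, 1)")


@dataclass
class CorrelationGridResult:
    """Mean within-group and combined-sample correlations per (OR, MAF) cell."""

    table: pd.DataFrame  # or_value, maf, mean_r_*, se_r_*, n_sims
    config: TwoSnpConfig


def _retrospective_sample(
    mafs: np.ndarray,
    betas: np.ndarray,
    beta0: float,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    prevalence: float = 0.1,
    max_batches: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw from the population until exact case/control quotas are filled."""
    k = float(np.clip(prevalence, 1e-3, 1 - 1e-3))
    batch = int(1.3 * max(n_cases / k, n_controls / (1.0 - k))) + 64
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_case = n_control = 0
    for _ in range(max_batches):
        if n_case >= n_cases and n_control >= n_controls:
            break
        g = rng.binomial(2, mafs, size=(batch, mafs.size)).astype(float)
        y = rng.random(batch) < expit(beta0 + linear_predictor(g, betas))
        if n_case < n_cases:
            take = g[y][: n_cases - n_case]
            cases.append(take)
            n_case += take.shape[0]
        if n_control < n_controls:
            take = g[~y][: n_controls - n_control]
            controls.append(take)
            n_control += take.shape[0]
    else:
        raise RuntimeError("case/control quotas not met within the attempt budget")
    genotypes = np.vstack(cases + controls)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)]
    )
    return genotypes, phenotype


def simulate_two_snp_cohort(
    or_value: float,
    maf: float,
    n: int = 10_000,
    prevalence: float = 0.01,
    case_fraction: float = 0.5,
    seed=0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One case-control sample with two independent equal-effect SNPs.

    Returns ``(g1, g2, phenotype)``: allele counts of each SNP and 0/1 case
    status, with ``round(n * case_fraction)`` cases.
    """
    g, y = _simulate_equal_effect_cohort(or_value, maf, n, 2, prevalence, case_fraction, seed)
    return g[:, 0], g[:, 1], y


def _simulate_equal_effect_cohort(
    or_value: float,
    maf: float,
    n: int,
    n_snps: int,
    prevalence: float,
    case_fraction: float,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.full(n_snps, float(maf))
    betas = np.full(n_snps, np.log(float(or_value)))
    beta0 = solve_intercept(mafs, betas, (), prevalence)
    n_cases = int(round(n * case_fraction))
    return _retrospective_sample(mafs, betas, beta0, n_cases, n - n_cases, rng, prevalence)


def correlation_by_group(
    g1: np.ndarray, g2: np.ndarray, phenotype: np.ndarray
) -> tuple[float, float, float]:
    """Pearson r of the two allele-count vectors overall, in cases, in controls.

    A zero-variance genotype within a subset leaves that correlation
    undefined; it is returned as nan rather than silently zero.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = np.asarray(phenotype)
    case_mask = y == 1
    if not case_mask.any() or case_mask.all():
        raise ValueError("both cases and controls are required")

    def _r(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0.0 or b.std() == 0.0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return (
        _r(g1, g2),
        _r(g1[case_mask], g2[case_mask]),
        _r(g1[~case_mask], g2[~case_mask]),
    )


def run_correlation_grid(config: TwoSnpConfig = TwoSnpConfig()) -> CorrelationGridResult:
    """Mean induced correlation per (OR, MAF) cell over repeated simulations.

    Each cell runs ``config.n_sims`` independent cohorts; results are exact
    functions of ``config.seed``.  Undefined (zero-variance) within-group
    correlations are excluded from that cell's mean via nan-aware averaging.
    """
    root = np.random.SeedSequence(int(config.seed))
    cells = [(o, m) for o in config.or_grid for m in config.maf_set]
    rows = []
    for child, (or_value, maf) in zip(root.spawn(len(cells)), cells):
        rng = np.random.default_rng(child)
        mafs = np.full(2, float(maf))
        betas = np.full(2, np.log(float(or_value)))
        beta0 = solve_intercept(mafs, betas, (), config.prevalence)
        n_cases = int(round(config.n_individuals * config.case_fraction))
        n_controls = config.n_individuals - n_cases
        r = np.empty((config.n_sims, 3))
        for s in range(config.n_sims):
            g, y = _retrospective_sample(
                mafs, betas, beta0, n_cases, n_controls, rng, config.prevalence
            )
            r[s] = correlation_by_group(g[:, 0], g[:, 1], y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-nan columns stay nan
            mean = np.nanmean(r, axis=0)
            se = np.nanstd(r, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(r), axis=0))
        rows.append(
            {
                "or_value": or_value,
                "maf": maf,
                "mean_r_all": mean[0],
                "se_r_all": se[0],
                "mean_r_cases": mean[1],
                "se_r_cases": se[1],
                "mean_r_controls": mean[2],
                "se_r_controls": se[2],
                "n_sims": config.n_sims,
            }
        )
    return CorrelationGridResult(table=pd.DataFrame(rows), config=config)


def _fit_pvalues(g: np.ndarray, y: np.ndarray, betas: np.ndarray) -> tuple[float, float]:
    """(1-df Wald p of the PRS score, k-df LRT p of the joint SNP model)."""
    score = g @ betas
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_prs = sm.Logit(y, sm.add_constant(score, has_constant="add")).fit(disp=0)
        p_prs = float(res_prs.pvalues[1])
        res_multi = sm.Logit(y, sm.add_constant(g, has_constant="add")).fit(disp=0)
        p_multi = float(res_multi.llr_pvalue)
    return p_prs, p_multi


def pvalue_comparison(
    or_value: float = 1.2,
    maf: float = 0.3,
    config: TwoSnpConfig = TwoSnpConfig(),
    n_snps: int = 2,
) -> pd.DataFrame:
    """Per-simulation association p-values: PRS score vs multivariate model.

    ``p_prs`` is the Wald test of the single score coefficient, the score
    being the true-beta-weighted allele sum (with equal ORs this is the
    plain allele sum up to scale, to which the p-value is invariant).
    ``p_multivariate`` is the likelihood-ratio test of the model with each
    SNP as a separate predictor against the intercept-only model (k df).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), n_snps, 0x2512]))
    betas = np.full(n_snps, np.log(float(or_value)))
    if not betas.any():
        # at OR=1 the true-beta weights vanish; the equal-weight convention
        # (plain allele sum) keeps the score defined, and the p-value is
        # scale-invariant anyway
        weights = np.ones(n_snps)
    else:
        weights = betas
    rows = []
    for s in range(config.n_sims):
        g, y = _simulate_equal_effect_cohort(
            or_value, maf, config.n_individuals, n_snps,
            config.prevalence, config.case_fraction, rng,
        )
        p_prs, p_multi = _fit_pvalues(g, y, weights)
        rows.append({"sim": s, "p_prs": p_prs, "p_multivariate": p_multi})
    return pd.DataFrame(rows)
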