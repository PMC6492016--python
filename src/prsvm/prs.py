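"""Polygenic risk scoring: per-SNP effect estimation, SNP selection,
weighted-allele scores, and AUC-based evaluation.

A polygenic risk score is the sum of an individual's risk-allele counts
weighted by per-SNP log odds ratios, PRS_i = sum_j beta_j g_ij.  Weights are
estimated here by univariable logistic regression per SNP on a training
split (external GWAS summary statistics can substitute through the same
table layout).  Classification accuracy is measured by AUC-ROC — the
probability a random case outranks a random control, ties counted half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .data import GenotypeMatrix

__all__ = [
    "PrsResult",
    "per_snp_logistic",
    "select_snps",
    "compute_prs",
    "compute_auc",
    "evaluate_prs",
]

#: |beta| cap applied when a SNP perfectly separates cases from controls.
BETA_CAP = 20.0


@dataclass
class PrsResult:
    scores: np.ndarray
    auc: float
    logistic_p: float
    logistic_beta: float
    flag: str | None = None


def _logit_fit(y: np.ndarray, x: np.ndarray):
    """Intercept + single-covariate logistic fit; returns (beta, se, p, flag)."""
    X = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:
            return np.nan, np.nan, np.nan, "fit_failed"
    beta = float(res.params[1])
    se = float(res.bse[1])
    p = float(res.pvalues[1])
    if not np.isfinite(beta) or abs(beta) > BETA_CAP or not np.isfinite(se):
        return float(np.clip(beta, -BETA_CAP, BETA_CAP)), np.nan, np.nan, "separation"
    return beta, se, p, None


def per_snp_logistic(genotypes, phenotype: np.ndarray) -> pd.DataFrame:
    """Univariable logistic regression of case status on each SNP.

    Returns the SnpStats frame (snp_id, effect_allele, beta, se, p, flag)
    with Wald p-values; the effect allele is the counted allele of the
    genotype matrix.  Requires complete (imputed) genotypes.
    """
    if isinstance(genotypes, GenotypeMatrix):
        values = genotypes.values
        snp_ids = genotypes.snp_meta["snp_id"].to_numpy()
        alleles = genotypes.snp_meta["effect_allele"].to_numpy()
    else:
        values = np.asarray(genotypes, dtype=float)
        snp_ids = np.array([f"snp{j + 1:04d}" for j in range(values.shape[1])])
        alleles = np.array(["A"] * values.shape[1])
    y = np.asarray(phenotype)
    if y.shape[0] != values.shape[0]:
        raise ValueError("phenotype not aligned to genotype rows")
    if np.isnan(values).any():
        raise ValueError("genotypes contain missing values; impute before fitting")

    rows = []
    for j in range(values.shape[1]):
        beta, se, p, flag = _logit_fit(y, values[:, j])
        rows.append((snp_ids[j], alleles[j], beta, se, p, flag))
    return pd.DataFrame(rows, columns=["snp_id", "effect_allele", "beta", "se", "p", "flag"])


def select_snps(
    stats: pd.DataFrame, p_threshold: float = 1.0, max_snps: int | None = None
) -> pd.DataFrame:
    """Keep SNPs with p <= threshold, then the ``max_snps`` smallest p.

    Ties are broken deterministically by (p, snp_id).  An empty selection is
    returned as an empty frame (callers decide whether that is fatal).
    """
    kept = stats[stats["p"] <= p_threshold].copy()
    kept = kept.sort_values(["p", "snp_id"], kind="mergesort").reset_index(drop=True)
    if max_snps is not None:
        kept = kept.head(int(max_snps)).reset_index(drop=True)
    return kept


def compute_prs(genotypes_target: GenotypeMatrix, stats: pd.DataFrame) -> np.ndarray:
    """Weighted allele sum per individual, resolving allele orientation.

    For each scored SNP the count of the stats effect allele is used: if the
    target matrix counts the other allele, the count is reflected as 2 - g.
    Every stats SNP must be present in the target with reconcilable alleles.
    """
    meta = genotypes_target.snp_meta.set_index("snp_id")
    missing = [s for s in stats["snp_id"] if s not in meta.index]
    if missing:
        raise KeyError(f"SNPs absent from target matrix: {missing}")
    col_of = {s: j for j, s in enumerate(genotypes_target.snp_meta["snp_id"])}

    scores = np.zeros(genotypes_target.n_samples)
    for snp, allele, beta in zip(stats["snp_id"], stats["effect_allele"], stats["beta"]):
        row = meta.loc[snp]
        g = genotypes_target.values[:, col_of[snp]]
        if np.isnan(g).any():
            raise ValueError(f"SNP {snp} has missing genotypes; impute before scoring")
        if allele == row["effect_allele"]:
            aligned = g
        elif allele == row["other_allele"]:
            aligned = 2.0 - g
        else:
            raise ValueError(
                f"SNP {snp}: effect allele {allele!r} matches neither target allele "
                f"({row['effect_allele']!r}/{row['other_allele']!r})"
            )
        scores = scores + float(beta) * aligned
    return scores


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC with the midrank tie convention.

    Equals the probability that a uniformly chosen case scores above a
    uniformly chosen control, ties counted one half.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both cases and controls")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def evaluate_prs(scores_test: np.ndarray, phenotype_test: np.ndarray) -> PrsResult:
    """Score-on-status logistic regression plus AUC on a test split."""
    scores = np.asarray(scores_test, dtype=float)
    y = np.asarray(phenotype_test)
    auc = compute_auc(scores, y)
    if np.ptp(scores) == 0.0:
        return PrsResult(scores=scores, auc=auc, logistic_p=np.nan, logistic_beta=np.nan,
                         flag="constant_scores")
    beta, _, p, flag = _logit_fit(y, scores)
    return PrsResult(scores=scores, auc=auc, logistic_p=p, logistic_beta=beta, flag=flag)
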