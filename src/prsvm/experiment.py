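"""Repeated-split comparison of PRS against linear- and RBF-kernel SVMs.

Each replicate draws one stratified 75/25 train/test split that is shared by
every method: PRS weights are per-SNP logistic betas fitted on the training
side; SVMs are trained on training features standardized with training-side
parameters.  Held-out AUC-ROC per method is collected over replicates, and
methods (or sample sizes) are compared by a t-test on the AUC distributions
(Welch by default; Student and split-paired variants by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import train_test_split

from .data import GenotypeMatrix
from .prs import compute_auc, compute_prs, per_snp_logistic, select_snps
from .svm import SvmConfig, standardize, train_svm

__all__ = [
    "PrsMethod",
    "SplitResult",
    "ExperimentResult",
    "ComparisonResult",
    "default_methods",
    "run_split",
    "run_experiment",
    "compare_methods",
    "compare_sample_sizes",
]


@dataclass(frozen=True)
class PrsMethod:
    """PRS settings inside the comparison: SNP selection on training p-values."""

    p_threshold: float = 1.0
    max_snps: int | None = None


def default_methods() -> dict[str, PrsMethod | SvmConfig]:
    """The three compared classifiers with near-optimal SVM hyperparameters
    (linear C=1; rbf C=0.5, gamma=0.02)."""
    return {
        "prs": PrsMethod(),
        "svm-linear": SvmConfig(kernel="linear", C=1.0),
        "svm-rbf": SvmConfig(kernel="rbf", C=0.5, gamma=0.02),
    }


@dataclass
class SplitResult:
    aucs: dict[str, float]
    test_ids: np.ndarray
    split_seed: int


@dataclass
class ExperimentResult:
    """Per-replicate AUC table plus boxplot-style summaries per method."""

    replicates: pd.DataFrame  # columns: replicate, method, auc
    summary: pd.DataFrame  # per method: median, q1, q3, min, max, mean, n
    base_seed: int
    split_seeds: list[int] = field(default_factory=list)

    def auc_vector(self, method: str) -> np.ndarray:
        sel = self.replicates[self.replicates["method"] == method]
        if sel.empty:
            raise KeyError(f"no replicates for method {method!r}")
        return sel.sort_values("replicate")["auc"].to_numpy()


@dataclass
class ComparisonResult:
    mean_diff: float
    t: float
    p: float


def _summarize(replicates: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for method, grp in replicates.groupby("method", sort=True):
        a = grp["auc"].to_numpy()
        rows.append(
            {
                "method": method,
                "median": float(np.median(a)),
                "q1": float(np.percentile(a, 25)),
                "q3": float(np.percentile(a, 75)),
                "min": float(a.min()),
                "max": float(a.max()),
                "mean": float(a.mean()),
                "n": int(a.size),
            }
        )
    return pd.DataFrame(rows)


def run_split(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    methods: Mapping[str, PrsMethod | SvmConfig],
    split_seed: int,
    test_fraction: float = 0.25,
) -> SplitResult:
    """Evaluate every method on ONE shared stratified train/test split.

    Requires complete (imputed) genotypes.  Everything fitted — per-SNP
    betas, standardization parameters, SVM models — uses the training side
    only; AUC is computed on the held-out side.
    """
    y = np.asarray(phenotype)
    if np.isnan(genotypes.values).any():
        raise ValueError("genotypes contain missing values; run QC/imputation first")
    idx_train, idx_test = train_test_split(
        np.arange(genotypes.n_samples),
        test_size=test_fraction,
        stratify=y,
        random_state=int(split_seed),
    )
    g_train = genotypes.take_samples(idx_train)
    g_test = genotypes.take_samples(idx_test)
    y_train, y_test = y[idx_train], y[idx_test]

    aucs: dict[str, float] = {}
    train_stats = None
    for name, method in methods.items():
        if isinstance(method, PrsMethod):
            if train_stats is None:
                train_stats = per_snp_logistic(g_train, y_train)
            usable = train_stats[train_stats["p"].notna()]
            chosen = select_snps(usable, method.p_threshold, method.max_snps)
            if chosen.empty:
                raise RuntimeError("PRS selection kept no SNPs at the given threshold")
            scores = compute_prs(g_test, chosen)
            aucs[name] = compute_auc(scores, y_test)
        elif isinstance(method, SvmConfig):
            (Xtr, Xte), _ = standardize(g_train.values, g_test.values)
            model = train_svm(Xtr, y_train, method)
            aucs[name] = compute_auc(model.decision_function(Xte), y_test)
        else:
            raise TypeError(f"unknown method spec for {name!r}: {type(method)}")
    return SplitResult(aucs=aucs, test_ids=g_test.sample_ids.copy(), split_seed=int(split_seed))


def run_experiment(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    methods: Mapping[str, PrsMethod | SvmConfig],
    n_reps: int = 100,
    base_seed: int = 0,
    test_fraction: float = 0.25,
) -> ExperimentResult:
    """Repeat :func:`run_split` over ``n_reps`` seeds ``base_seed + r``.

    The per-method summary reports the boxplot statistics (median, quartiles
    and extremes) of the replicate AUC distributions.
    """
    rows = []
    seeds = []
    for r in range(n_reps):
        seed = int(base_seed) + r
        seeds.append(seed)
        result = run_split(genotypes, phenotype, methods, seed, test_fraction)
        for name, auc in result.aucs.items():
            rows.append({"replicate": r, "method": name, "auc": auc})
    replicates = pd.DataFrame(rows)
    return ExperimentResult(
        replicates=replicates,
        summary=_summarize(replicates),
        base_seed=int(base_seed),
        split_seeds=seeds,
    )


def compare_methods(
    auc_vector_a: np.ndarray,
    auc_vector_b: np.ndarray,
    equal_var: bool = False,
    paired: bool = False,
) -> ComparisonResult:
    """t-test for a difference in mean AUC between two replicate vectors.

    Welch's unequal-variance test by default; ``equal_var=True`` gives the
    Student test and ``paired=True`` pairs replicates by split.
    ``mean_diff`` is ``mean(a) - mean(b)``.
    """
    a = np.asarray(auc_vector_a, dtype=float)
    b = np.asarray(auc_vector_b, dtype=float)
    mean_diff = float(a.mean() - b.mean())
    if paired:
        t, p = sps.ttest_rel(a, b)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(mean_diff=mean_diff, t=float(t), p=float(p))


def compare_sample_sizes(
    result_small: ExperimentResult,
    result_large: ExperimentResult,
    method: str,
    equal_var: bool = False,
) -> ComparisonResult:
    """Welch test of one method's AUC across two cohort sizes
    (``mean_diff`` is large minus small)."""
    return compare_methods(
        result_large.auc_vector(method), result_small.auc_vector(method), equal_var=equal_var
    )
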