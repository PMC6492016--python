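"""Quality-control stack for hard-called SNP genotype matrices.

The pipeline applies, in order: hard-calling of genotype probabilities,
per-SNP missingness filter, minor-allele-frequency filter, Hardy-Weinberg
goodness-of-fit filter (in controls by default), exclusion of fixed genomic
regions (defaults to the extended MHC, chr6:25-34 Mb), association-aware
greedy LD pruning, and finally multinomial imputation of the remaining
missing calls.  Every step returns the filtered matrix together with a
machine-readable report of what it removed.

Defaults mirror common GWAS practice: missing rate < 2%, MAF >= 10% (boundary
inclusive), HWE p >= 1e-4 on a 1-df chi-square test, hard-call probability
strictly > 0.9, LD window 500 kb with r^2 threshold 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import GenotypeMatrix

__all__ = [
    "QcConfig",
    "FilterReport",
    "hard_call",
    "filter_missingness",
    "filter_maf",
    "filter_hwe",
    "exclude_region",
    "ld_prune",
    "impute_missing_multinomial",
    "hwe_test",
    "apply_qc",
]


@dataclass(frozen=True)
class QcConfig:
    max_missing_rate: float = 0.02
    min_maf: float = 0.10
    hwe_alpha: float = 1e-4
    excluded_regions: tuple[tuple[int, int, int], ...] = ((6, 25_000_000, 34_000_000),)
    hard_call_threshold: float = 0.9
    prune_window: int = 500_000
    prune_r2: float = 0.1
    hwe_controls_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must lie in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not 0.0 <= self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must lie in [0, 1]")
        if not 0.0 < self.hard_call_threshold < 1.0:
            raise ValueError("hard_call_threshold must lie in (0, 1)")
        if self.prune_window < 0 or not 0.0 <= self.prune_r2 <= 1.0:
            raise ValueError("invalid LD pruning parameters")


@dataclass
class FilterReport:
    """What one QC step did: counts reconcile as n_in - n_removed = n_out."""

    step: str
    n_in: int
    n_out: int
    removed_ids: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in - len(self.removed_ids) != self.n_out:
            raise ValueError(f"{self.step}: report counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "n_in": self.n_in,
                "n_out": self.n_out,
                "removed_ids": ",".join(self.removed_ids) or ".",
            },
            index=[0],
        )


def _drop(matrix: GenotypeMatrix, remove: np.ndarray, step: str, **details):
    keep = ~remove
    removed_ids = matrix.snp_meta.loc[remove, "snp_id"].tolist()
    report = FilterReport(
        step=step,
        n_in=matrix.n_snps,
        n_out=int(keep.sum()),
        removed_ids=removed_ids,
        details=details,
    )
    return matrix.take_snps(keep), report


# ---------------------------------------------------------------------------
# hard-calling
# ---------------------------------------------------------------------------


def hard_call(
    prob_triples: np.ndarray,
    snp_meta: pd.DataFrame,
    sample_ids: np.ndarray,
    threshold: float = 0.9,
) -> GenotypeMatrix:
    """Convert genotype probability triples to most-probable genotypes.

    ``prob_triples`` has shape ``(n_samples, n_snps, 3)``; each triple must
    sum to 1 within 1e-6.  An entry becomes the argmax genotype only when its
    probability strictly exceeds ``threshold``; otherwise it is missing.
    """
    probs = np.asarray(prob_triples, dtype=float)
    if probs.ndim != 3 or probs.shape[2] != 3:
        raise ValueError("prob_triples must have shape (n_samples, n_snps, 3)")
    sums = probs.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        i, j = np.argwhere(~np.isclose(sums, 1.0, atol=1e-6))[0]
        raise ValueError(f"probability triple at sample {i}, SNP {j} sums to {sums[i, j]!r}")
    best = probs.argmax(axis=2).astype(float)
    best[probs.max(axis=2) <= threshold] = np.nan
    return GenotypeMatrix(values=best, snp_meta=snp_meta, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# per-SNP filters
# ---------------------------------------------------------------------------


def filter_missingness(matrix: GenotypeMatrix, max_missing_rate: float = 0.02):
    """Remove SNPs whose missing fraction is >= the threshold."""
    rate = matrix.missing_rate()
    return _drop(matrix, rate >= max_missing_rate, "missingness", threshold=max_missing_rate)


def filter_maf(matrix: GenotypeMatrix, min_maf: float = 0.10):
    """Remove SNPs with minor allele frequency below the threshold (inclusive keep)."""
    maf = matrix.maf()
    remove = ~(maf >= min_maf)  # also removes all-missing columns (maf nan)
    return _drop(matrix, remove, "maf", threshold=min_maf)


def hwe_test(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-square goodness of fit of genotype counts to HWE proportions."""
    n = n0 + n1 + n2
    if n == 0:
        return 0.0, 1.0
    p = (2 * n2 + n1) / (2 * n)  # frequency of the counted allele
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    return stat, float(chi2.sf(stat, df=1))


def filter_hwe(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray | None = None,
    hwe_alpha: float = 1e-4,
    controls_only: bool = True,
):
    """Remove SNPs departing from Hardy-Weinberg equilibrium (p < alpha).

    By default counts come from controls only (``phenotype == 0``); pass
    ``controls_only=False`` (or no phenotype) to test on all samples.
    """
    if controls_only and phenotype is not None:
        values = matrix.values[np.asarray(phenotype) == 0]
    else:
        values = matrix.values
    pvals = np.empty(matrix.n_snps)
    for j in range(matrix.n_snps):
        col = values[:, j]
        col = col[~np.isnan(col)]
        _, pvals[j] = hwe_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    return _drop(matrix, pvals < hwe_alpha, "hwe", alpha=hwe_alpha)


def exclude_region(matrix: GenotypeMatrix, regions: Sequence[tuple[int, int, int]]):
    """Remove SNPs inside any closed (chromosome, start, end) interval."""
    chrom = matrix.snp_meta["chrom"].to_numpy()
    pos = matrix.snp_meta["pos"].to_numpy()
    remove = np.zeros(matrix.n_snps, dtype=bool)
    for c, start, end in regions:
        remove |= (chrom == c) & (pos >= start) & (pos <= end)
    return _drop(matrix, remove, "region", regions=list(map(tuple, regions)))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of ``x`` with each column of ``y``,
    computed on pairwise-complete observations."""
    out = np.zeros(y.shape[1])
    for k in range(y.shape[1]):
        valid = ~np.isnan(x) & ~np.isnan(y[:, k])
        if valid.sum() < 2:
            continue
        xv, yv = x[valid], y[valid, k]
        sx, sy = xv.std(), yv.std()
        if sx == 0.0 or sy == 0.0:
            continue
        r = np.corrcoef(xv, yv)[0, 1]
        out[k] = r * r
    return out


def ld_prune(
    matrix: GenotypeMatrix,
    snp_pvalues: np.ndarray,
    prune_window: int = 500_000,
    prune_r2: float = 0.1,
):
    """Greedy association-aware LD pruning.

    SNPs are visited in ascending p-value order (ties broken by chromosome,
    position, then id).  Each retained SNP removes every not-yet-retained
    SNP on the same chromosome within +/- ``prune_window`` base pairs whose
    genotype r^2 with it exceeds ``prune_r2``.
    """
    p = np.asarray(snp_pvalues, dtype=float)
    if p.shape[0] != matrix.n_snps:
        raise ValueError("snp_pvalues not aligned to SNP columns")
    meta = matrix.snp_meta
    order = sorted(
        range(matrix.n_snps),
        key=lambda j: (p[j], meta["chrom"].iat[j], meta["pos"].iat[j], meta["snp_id"].iat[j]),
    )
    chrom = meta["chrom"].to_numpy()
    pos = meta["pos"].to_numpy()
    kept = np.zeros(matrix.n_snps, dtype=bool)
    removed = np.zeros(matrix.n_snps, dtype=bool)
    for j in order:
        if removed[j]:
            continue
        kept[j] = True
        near = (
            ~kept
            & ~removed
            & (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= prune_window)
        )
        idx = np.flatnonzero(near)
        if idx.size:
            r2 = _pairwise_r2(matrix.values[:, j], matrix.values[:, idx])
            removed[idx[r2 > prune_r2]] = True
    return _drop(matrix, removed, "ld_prune", window=prune_window, r2=prune_r2)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_missing_multinomial(matrix: GenotypeMatrix, seed):
    """Fill missing calls by sampling each SNP's observed genotype frequencies.

    Observed entries are never altered.  A SNP with no observed calls has
    undefined frequencies and raises.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = matrix.copy()
    n_imputed = 0
    for j in range(out.n_snps):
        col = out.values[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            raise RuntimeError(
                f"SNP {out.snp_meta['snp_id'].iat[j]} has no observed genotypes; "
                "frequencies are undefined"
            )
        freqs = np.array([(observed == g).mean() for g in (0.0, 1.0, 2.0)])
        col[miss] = rng.choice(3, size=int(miss.sum()), p=freqs).astype(float)
        n_imputed += int(miss.sum())
    report = FilterReport(
        step="impute", n_in=matrix.n_snps, n_out=matrix.n_snps, details={"n_imputed": n_imputed}
    )
    return out, report


# ---------------------------------------------------------------------------
# full stack
# ---------------------------------------------------------------------------


def apply_qc(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray | None,
    config: QcConfig = QcConfig(),
    snp_pvalues: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """Run the full QC stack in its documented order.

    LD pruning needs per-SNP association p-values; if none are supplied they
    are computed from the phenotype by univariable logistic regression (on a
    temporarily-imputed copy so missing calls do not bias the ranking).
    The stack is idempotent on its own output: a second application removes
    nothing and imputes nothing.
    """
    reports: list[FilterReport] = []
    m = matrix
    pmap = None
    if snp_pvalues is not None:
        pmap = dict(zip(matrix.snp_meta["snp_id"], np.asarray(snp_pvalues, dtype=float)))

    m, rep = filter_missingness(m, config.max_missing_rate)
    reports.append(rep)
    m, rep = filter_maf(m, config.min_maf)
    reports.append(rep)
    m, rep = filter_hwe(m, phenotype, config.hwe_alpha, config.hwe_controls_only)
    reports.append(rep)
    m, rep = exclude_region(m, config.excluded_regions)
    reports.append(rep)

    if pmap is not None:
        pvals = np.array([pmap[s] for s in m.snp_meta["snp_id"]])
    elif phenotype is not None:
        from .prs import per_snp_logistic

        work, _ = impute_missing_multinomial(m, np.random.default_rng(int(seed) + 1))
        pvals = per_snp_logistic(work, np.asarray(phenotype))["p"].to_numpy()
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    else:
        pvals = np.ones(m.n_snps)
    m, rep = ld_prune(m, pvals, config.prune_window, config.prune_r2)
    reports.append(rep)

    m, rep = impute_missing_multinomial(m, np.random.default_rng(int(seed)))
    reports.append(rep)
    return m, reports
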