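"""Core in-memory containers for genotype data.

Genotypes are stored as additive allele counts (the number of copies of the
designated *effect allele*, 0/1/2) in a float array, with ``numpy.nan``
marking missing calls.  Per-SNP metadata travels alongside the matrix in a
pandas DataFrame so that filters can report which markers they removed and
scoring can resolve allele orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SNP_META_COLUMNS",
    "GenotypeMatrix",
    "default_snp_meta",
]

#: Required columns of :attr:`GenotypeMatrix.snp_meta`.
SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]


def default_snp_meta(n_snps: int, chrom: int = 1, spacing: int = 1_000_000) -> pd.DataFrame:
    """Synthetic SNP metadata for simulated markers.

    Markers are placed on one chromosome, ``spacing`` base pairs apart, so
    that by default no two simulated SNPs fall inside the same LD-pruning
    window.  The counted (effect) allele is ``A``, the other allele ``G``.
    """
    width = max(4, len(str(n_snps)))
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:0{width}d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": 1 + spacing * np.arange(n_snps, dtype=np.int64),
            "effect_allele": "A",
            "other_allele": "G",
        }
    )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive allele counts with per-SNP metadata.

    Parameters
    ----------
    values
        Float array of shape ``(n_samples, n_snps)`` with entries in
        ``{0, 1, 2}`` or ``nan`` for missing.
    snp_meta
        DataFrame with columns :data:`SNP_META_COLUMNS`; one row per SNP
        column, ids unique, positions positive 1-based integers.
    sample_ids
        One identifier per row.
    """

    values: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-d array")
        self.sample_ids = np.asarray(self.sample_ids)
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise ValueError(f"snp_meta lacks columns {missing_cols}")
        if len(self.snp_meta) != self.values.shape[1]:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for {self.values.shape[1]} SNP columns"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[0]} rows"
            )
        if self.snp_meta["snp_id"].duplicated().any():
            dups = self.snp_meta.loc[self.snp_meta["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dups))}")
        pos = self.snp_meta["pos"].to_numpy()
        if len(pos) and (pos <= 0).any():
            raise ValueError("SNP positions must be positive 1-based integers")
        v = self.values
        ok = np.isnan(v) | (v == 0.0) | (v == 1.0) | (v == 2.0)
        if not ok.all():
            bad = v[~ok]
            raise ValueError(f"genotype values outside {{0,1,2,missing}}: e.g. {bad.flat[0]!r}")

    # -- basic shape -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    # -- per-SNP summaries -------------------------------------------------

    def missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per SNP column."""
        return np.isnan(self.values).mean(axis=0)

    def effect_allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele, on non-missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, on non-missing entries."""
        f = self.effect_allele_freq()
        return np.minimum(f, 1.0 - f)

    # -- subsetting --------------------------------------------------------

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to SNP columns ``index`` (bool mask or ints)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            values=self.values[:, index].copy(),
            snp_meta=self.snp_meta.iloc[index].reset_index(drop=True),
            sample_ids=self.sample_ids,
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to rows ``index`` (bool mask or ints)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            values=self.values[index].copy(),
            snp_meta=self.snp_meta,
            sample_ids=self.sample_ids[index],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            values=self.values.copy(),
            snp_meta=self.snp_meta.copy(),
            sample_ids=self.sample_ids.copy(),
        )
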