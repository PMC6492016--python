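"""Readers and writers for the package's text formats.

Genotypes travel in a PLINK ``.raw``-style tab-delimited dialect: a header
``FID IID PAT MAT SEX PHENOTYPE <snp>_<allele> ...`` followed by one row per
individual with allele counts 0/1/2 and ``NA`` for missing calls.  The
phenotype column is coded 1=control, 2=case on disk and 0/1 in memory.
SNP metadata uses a ``.bim``-like six-column table (chromosome, id, 0,
position, allele1, allele2) where allele1 is the counted (effect) allele.
GWAS summary statistics are a TSV with columns SNP, A1, BETA (or OR), SE, P.
"""

from __future__ import annotations

import json
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import SimulatedCohort

__all__ = [
    "ParseError",
    "read_raw",
    "write_raw",
    "read_bim",
    "write_bim",
    "read_summary_stats",
    "write_summary_stats",
    "write_truth",
    "save_cohort",
    "load_cohort",
]

_RAW_FIXED = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_GENO_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_raw(genotypes: GenotypeMatrix, phenotype: np.ndarray | None, path) -> None:
    """Write genotypes (and 1=control / 2=case phenotype) to ``path``."""
    meta = genotypes.snp_meta
    cols = [f"{s}_{a}" for s, a in zip(meta["snp_id"], meta["effect_allele"])]
    with open(path, "w") as fh:
        fh.write("\t".join(_RAW_FIXED + cols) + "\n")
        for i in range(genotypes.n_samples):
            sid = str(genotypes.sample_ids[i])
            if phenotype is None or (isinstance(phenotype[i], float) and np.isnan(phenotype[i])):
                pheno = "NA"
            else:
                pheno = str(int(phenotype[i]) + 1)
            row = genotypes.values[i]
            tokens = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write("\t".join([sid, sid, "0", "0", "0", pheno] + tokens) + "\n")


def read_raw(path, bim_path=None) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Read the ``.raw`` dialect; returns the matrix and 0/1 phenotype.

    If ``bim_path`` is given, SNP metadata is taken from it (ids must match
    the header); otherwise placeholder metadata is synthesized from the
    header.  The phenotype is ``None`` when every entry on disk is ``NA``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if fields[: len(_RAW_FIXED)] != _RAW_FIXED:
            raise ParseError(f"{path}: line 1: header must start with {' '.join(_RAW_FIXED)}")
        snp_cols = fields[len(_RAW_FIXED) :]
        snp_ids, alleles = [], []
        for col in snp_cols:
            snp, _, allele = col.rpartition("_")
            if not snp or not allele:
                raise ParseError(f"{path}: line 1: malformed SNP column {col!r}")
            snp_ids.append(snp)
            alleles.append(allele)

        sample_ids, phenos, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(fields):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(fields)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            ptok = parts[5]
            if ptok == "NA":
                phenos.append(np.nan)
            elif ptok in ("1", "2"):
                phenos.append(float(ptok) - 1.0)
            else:
                raise ParseError(f"{path}: line {lineno}: phenotype token {ptok!r} not 1/2/NA")
            try:
                rows.append([_GENO_TOKENS[t] for t in parts[6:]])
            except KeyError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: genotype token {exc.args[0]!r} not 0/1/2/NA"
                ) from None

    values = np.array(rows, dtype=float).reshape(len(rows), len(snp_ids))
    if bim_path is not None:
        meta = read_bim(bim_path)
        if list(meta["snp_id"]) != snp_ids:
            raise ParseError(f"{bim_path}: SNP ids do not match the .raw header")
        if list(meta["effect_allele"]) != alleles:
            raise ParseError(f"{bim_path}: allele1 does not match the counted allele in .raw")
    else:
        meta = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": 0,
                "pos": np.arange(1, len(snp_ids) + 1),
                "effect_allele": alleles,
                "other_allele": "0",
            }
        )
    matrix = GenotypeMatrix(values=values, snp_meta=meta, sample_ids=np.array(sample_ids))
    pheno = np.array(phenos)
    if np.isnan(pheno).all():
        return matrix, None
    if not np.isnan(pheno).any():
        pheno = pheno.astype(np.int64)
    return matrix, pheno


def write_bim(genotypes: GenotypeMatrix, path) -> None:
    meta = genotypes.snp_meta
    out = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "snp_id": meta["snp_id"],
            "cm": 0,
            "pos": meta["pos"],
            "allele1": meta["effect_allele"],
            "allele2": meta["other_allele"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bim(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"snp_id": str, "allele1": str, "allele2": str},
    )
    if df.shape[1] != 6:
        raise ParseError(f"{path}: expected 6 tab-separated columns")
    return pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"].astype(int),
            "pos": df["pos"].astype(np.int64),
            "effect_allele": df["allele1"],
            "other_allele": df["allele2"],
        }
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV into the canonical SnpStats frame.

    Columns on disk: ``SNP``, ``A1`` (effect allele), ``BETA`` or ``OR``
    (odds ratios are converted by log), optional ``SE``, ``P``.  Rows with
    OR <= 0 or P outside (0, 1] are rejected with a diagnostic.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str})
    required = {"SNP", "A1", "P"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    has_beta, has_or = "BETA" in df.columns, "OR" in df.columns
    if has_beta == has_or:
        raise ParseError(f"{path}: exactly one of BETA or OR column is required")
    p = df["P"].to_numpy(dtype=float)
    bad = np.flatnonzero(~((p > 0.0) & (p <= 1.0)))
    if bad.size:
        raise ParseError(f"{path}: row {bad[0] + 2}: P={p[bad[0]]!r} outside (0, 1]")
    if has_or:
        orv = df["OR"].to_numpy(dtype=float)
        bad = np.flatnonzero(~(orv > 0.0))
        if bad.size:
            raise ParseError(f"{path}: row {bad[0] + 2}: OR={orv[bad[0]]!r} must be positive")
        beta = np.log(orv)
    else:
        beta = df["BETA"].to_numpy(dtype=float)
    se = df["SE"].to_numpy(dtype=float) if "SE" in df.columns else np.full(len(df), np.nan)
    bad = np.flatnonzero(~(np.isnan(se) | (se > 0.0)))
    if bad.size:
        raise ParseError(f"{path}: row {bad[0] + 2}: SE={se[bad[0]]!r} must be positive")
    return pd.DataFrame(
        {"snp_id": df["SNP"], "effect_allele": df["A1"], "beta": beta, "se": se, "p": p}
    )


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    """Write a SnpStats frame as a BETA-dialect TSV (text round-trips exactly)."""
    out = pd.DataFrame(
        {
            "SNP": stats["snp_id"],
            "A1": stats["effect_allele"],
            "BETA": [repr(float(b)) for b in stats["beta"]],
            "SE": [repr(float(s)) for s in stats["se"]],
            "P": [repr(float(p)) for p in stats["p"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort bundles
# ---------------------------------------------------------------------------


def write_truth(cohort: "SimulatedCohort", path) -> None:
    """Truth table TSV: SNP id, true beta, MAF, epistatic partner, theta."""
    spec = cohort.spec
    ids = cohort.genotypes.snp_ids
    partner = ["."] * len(ids)
    theta = [0.0] * len(ids)
    for a, b, t in spec.epistatic_pairs:
        partner[a], partner[b] = ids[b], ids[a]
        theta[a] = theta[b] = t
    pd.DataFrame(
        {
            "snp_id": ids,
            "beta": spec.betas,
            "maf": cohort.mafs,
            "partner": partner,
            "theta": theta,
        }
    ).to_csv(path, sep="\t", index=False)


def save_cohort(cohort: "SimulatedCohort", prefix: str) -> None:
    """Write ``<prefix>.raw``, ``<prefix>.bim``, truth table and metadata."""
    write_raw(cohort.genotypes, cohort.phenotype, f"{prefix}.raw")
    write_bim(cohort.genotypes, f"{prefix}.bim")
    write_truth(cohort, f"{prefix}.truth.tsv")
    meta = {
        "beta0": cohort.beta0,
        "realized_prevalence": cohort.realized_prevalence,
        "n_drawn": cohort.n_drawn,
        "n_cases": cohort.spec.n_cases,
        "n_controls": cohort.spec.n_controls,
        "prevalence": cohort.spec.prevalence,
        "seed": cohort.spec.seed,
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_cohort(prefix: str) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Read ``<prefix>.raw`` (+ ``.bim`` if present) back into memory."""
    import os

    bim = f"{prefix}.bim"
    return read_raw(f"{prefix}.raw", bim_path=bim if os.path.exists(bim) else None)
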