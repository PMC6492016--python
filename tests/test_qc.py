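"""QC stack checks: each filter against small counting oracles, and the
documented hard-call / pruning / imputation semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from prsvm import (
    GenotypeMatrix,
    QcConfig,
    apply_qc,
    exclude_region,
    filter_hwe,
    filter_maf,
    filter_missingness,
    hard_call,
    impute_missing_multinomial,
    ld_prune,
)
from prsvm.data import default_snp_meta
from prsvm.qc import hwe_test


def make_matrix(columns: dict[str, np.ndarray], chrom=None, pos=None) -> GenotypeMatrix:
    ids = list(columns)
    values = np.column_stack([np.asarray(columns[s], dtype=float) for s in ids])
    meta = default_snp_meta(len(ids))
    meta["snp_id"] = ids
    if chrom is not None:
        meta["chrom"] = chrom
    if pos is not None:
        meta["pos"] = pos
    return GenotypeMatrix(
        values=values,
        snp_meta=meta,
        sample_ids=np.array([f"s{i}" for i in range(values.shape[0])]),
    )


class TestHardCall:
    def test_most_probable_genotype_above_threshold(self):
        probs = np.array([[[0.95, 0.04, 0.01], [0.50, 0.40, 0.10], [0.05, 0.05, 0.90]]])
        out = hard_call(probs, default_snp_meta(3), np.array(["s0"]), threshold=0.9)
        assert out.values[0, 0] == 0.0
        assert np.isnan(out.values[0, 1])
        assert np.isnan(out.values[0, 2])  # 0.90 is not strictly > 0.9

    def test_triple_not_summing_to_one_rejected(self):
        probs = np.array([[[0.5, 0.4, 0.2]]])
        with pytest.raises(ValueError, match="sums to"):
            hard_call(probs, default_snp_meta(1), np.array(["s0"]))


class TestPerSnpFilters:
    def test_missingness_exact_surviving_set(self):
        n = 100
        cols = {}
        missing_counts = [0, 1, 2, 3, 5, 0, 1, 4, 2, 0]
        for j, m in enumerate(missing_counts):
            col = np.ones(n)
            col[:m] = np.nan
            cols[f"snp{j}"] = col
        matrix = make_matrix(cols)
        out, report = filter_missingness(matrix, max_missing_rate=0.02)
        expected_kept = [f"snp{j}" for j, m in enumerate(missing_counts) if m / n < 0.02]
        assert list(out.snp_ids) == expected_kept
        assert report.n_in - len(report.removed_ids) == report.n_out

    def test_maf_boundary_inclusive_and_monomorphic_removed(self):
        n = 100
        boundary = np.zeros(n)
        boundary[:20] = 1.0  # allele freq 0.10 exactly
        rare = np.zeros(n)
        rare[:2] = 1.0
        common = np.ones(n)
        common[: n // 2] = 0.0
        matrix = make_matrix(
            {"mono": np.zeros(n), "rare": rare, "boundary": boundary, "common": common}
        )
        out, _ = filter_maf(matrix, min_maf=0.10)
        assert list(out.snp_ids) == ["boundary", "common"]

    def test_hwe_exact_proportions_kept(self):
        col = np.repeat([0.0, 1.0, 2.0], [490, 420, 90])
        stat, p = hwe_test(490, 420, 90)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        matrix = make_matrix({"ok": col})
        out, _ = filter_hwe(matrix, phenotype=np.zeros(1000), hwe_alpha=1e-4)
        assert list(out.snp_ids) == ["ok"]

    def test_hwe_violation_removed_matches_chi2_oracle(self):
        n0, n1, n2 = 600, 200, 200
        # direct chi-square oracle
        p_hat = (2 * n2 + n1) / 2000
        expected = np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]) * 1000
        stat = (((np.array([n0, n1, n2]) - expected) ** 2) / expected).sum()
        p_oracle = chi2.sf(stat, df=1)
        assert hwe_test(n0, n1, n2)[1] == pytest.approx(p_oracle)
        assert p_oracle < 1e-4
        col = np.repeat([0.0, 1.0, 2.0], [n0, n1, n2])
        out, report = filter_hwe(make_matrix({"bad": col}), phenotype=np.zeros(1000))
        assert report.removed_ids == ["bad"]

    def test_hwe_alpha_zero_removes_nothing(self):
        col = np.repeat([0.0, 1.0, 2.0], [600, 200, 200])
        out, _ = filter_hwe(make_matrix({"bad": col}), phenotype=np.zeros(1000), hwe_alpha=0.0)
        assert list(out.snp_ids) == ["bad"]

    def test_hwe_uses_controls_only(self):
        # controls in HWE, cases wildly out: SNP must survive
        controls = np.repeat([0.0, 1.0, 2.0], [490, 420, 90])
        cases = np.repeat([0.0, 2.0], [500, 500])
        col = np.concatenate([controls, cases])
        phenotype = np.concatenate([np.zeros(1000), np.ones(1000)])
        out, _ = filter_hwe(make_matrix({"x": col}), phenotype=phenotype)
        assert list(out.snp_ids) == ["x"]

    @pytest.mark.parametrize(
        "chrom,pos,kept",
        [(6, 30_000_000, False), (6, 24_999_999, True), (6, 34_000_000, False), (7, 30_000_000, True)],
    )
    def test_region_exclusion_closed_interval(self, chrom, pos, kept):
        matrix = make_matrix({"x": np.array([0.0, 1.0, 2.0])}, chrom=[chrom], pos=[pos])
        out, _ = exclude_region(matrix, [(6, 25_000_000, 34_000_000)])
        assert (list(out.snp_ids) == ["x"]) is kept


def _greedy_prune_oracle(values, pvals, chrom, pos, ids, window, r2_max):
    """Independent reference: explicit pairwise r^2 table + greedy scan."""
    m = values.shape[1]
    r2 = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a != b:
                r2[a, b] = np.corrcoef(values[:, a], values[:, b])[0, 1] ** 2
    order = sorted(range(m), key=lambda j: (pvals[j], chrom[j], pos[j], ids[j]))
    kept, removed = [], set()
    for j in order:
        if j in removed:
            continue
        kept.append(j)
        for k in order:
            if k in removed or k in kept:
                continue
            if chrom[k] == chrom[j] and abs(pos[k] - pos[j]) <= window and r2[j, k] > r2_max:
                removed.add(k)
    return sorted(kept)


class TestLdPrune:
    def test_duplicate_column_keeps_smaller_p(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, 200).astype(float)
        matrix = make_matrix({"a": col, "b": col}, chrom=[1, 1], pos=[100, 200])
        out, report = ld_prune(matrix, snp_pvalues=[0.5, 0.01])
        assert list(out.snp_ids) == ["b"]
        assert report.removed_ids == ["a"]

    def test_correlated_but_outside_window_both_kept(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.3, 200).astype(float)
        col2 = col.copy()
        col2[:10] = 2.0 - col2[:10]
        matrix = make_matrix({"a": col, "b": col2}, chrom=[1, 1], pos=[1, 600_001])
        assert np.corrcoef(col, col2)[0, 1] ** 2 > 0.5
        out, _ = ld_prune(matrix, snp_pvalues=[0.01, 0.5], prune_window=500_000)
        assert list(out.snp_ids) == ["a", "b"]

    def test_constructed_triple_matches_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.4, 500).astype(float)
        b = a.copy()
        b[:60] = rng.binomial(2, 0.4, 60)  # strongly correlated with a
        c = rng.binomial(2, 0.4, 500).astype(float)  # independent
        for pvals in ([0.001, 0.01, 0.1], [0.1, 0.001, 0.01], [0.01, 0.1, 0.001]):
            matrix = make_matrix({"a": a, "b": b, "c": c}, chrom=[1, 1, 1], pos=[1000, 2000, 3000])
            out, _ = ld_prune(matrix, snp_pvalues=pvals, prune_window=500_000, prune_r2=0.1)
            expected = _greedy_prune_oracle(
                matrix.values, pvals, [1, 1, 1], [1000, 2000, 3000], ["a", "b", "c"], 500_000, 0.1
            )
            assert list(out.snp_ids) == [["a", "b", "c"][j] for j in expected]


class TestImputation:
    def test_no_missing_is_identity(self, additive_cohort):
        out, report = impute_missing_multinomial(additive_cohort.genotypes, seed=0)
        np.testing.assert_array_equal(out.values, additive_cohort.genotypes.values)
        assert report.details["n_imputed"] == 0

    def test_single_observed_class_fills_with_it(self):
        col = np.zeros(50)
        col[:10] = np.nan
        out, _ = impute_missing_multinomial(make_matrix({"x": col}), seed=1)
        assert (out.values == 0.0).all()

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.3, 1000).astype(float)
        miss = rng.random(1000) < 0.2
        col_missing = col.copy()
        col_missing[miss] = np.nan
        out, _ = impute_missing_multinomial(make_matrix({"x": col_missing}), seed=4)
        np.testing.assert_array_equal(out.values[~miss, 0], col[~miss])
        assert not np.isnan(out.values).any()

    def test_all_missing_snp_is_diagnosed(self):
        col = np.full(10, np.nan)
        with pytest.raises(RuntimeError, match="no observed"):
            impute_missing_multinomial(make_matrix({"x": col}), seed=0)

    def test_imputed_class_fractions_match_observed_frequencies(self):
        observed = np.repeat([0.0, 1.0, 2.0], [640, 320, 40])
        col = np.concatenate([observed, np.full(5000, np.nan)])
        out, _ = impute_missing_multinomial(make_matrix({"x": col}), seed=5)
        imputed = out.values[1000:, 0]
        for cls, f in zip((0.0, 1.0, 2.0), (0.64, 0.32, 0.04)):
            se = np.sqrt(f * (1 - f) / imputed.size)
            assert abs((imputed == cls).mean() - f) < 3 * se


class TestFullStack:
    def test_reports_reconcile_and_idempotent(self, additive_cohort):
        from prsvm import inject_missing

        g = inject_missing(additive_cohort.genotypes, 0.005, seed=9)
        config = QcConfig(min_maf=0.05)
        out, reports = apply_qc(g, additive_cohort.phenotype, config, seed=11)
        for r in reports:
            assert r.n_in - len(r.removed_ids) == r.n_out
        assert not np.isnan(out.values).any()
        out2, reports2 = apply_qc(out, additive_cohort.phenotype, config, seed=12)
        np.testing.assert_array_equal(out2.values, out.values)
        assert all(len(r.removed_ids) == 0 for r in reports2)
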