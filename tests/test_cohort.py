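"""Simulator checks: HWE sampling, intercept solving, phenotype models,
retrospective quota sampling and missingness injection."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import chi2_contingency

from prsvm import (
    XOR_NULL_MAF,
    CohortSpec,
    assign_phenotype_additive,
    assign_phenotype_xor,
    inject_missing,
    sample_case_control,
    sample_genotypes,
    solve_intercept,
)


class TestSampleGenotypes:
    def test_hwe_class_frequencies(self):
        g = sample_genotypes(100_000, [0.2], seed=0).values[:, 0]
        n = g.size
        for cls, expected in zip((0, 1, 2), (0.64, 0.32, 0.04)):
            observed = (g == cls).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se

    def test_symmetric_maf_column_mean(self):
        g = sample_genotypes(100_000, [0.5], seed=1).values[:, 0]
        se = np.sqrt(0.5 / g.size)  # Var(Binomial(2, .5)) = 0.5
        assert abs(g.mean() - 1.0) < 3 * se

    def test_snps_mutually_independent(self):
        g = sample_genotypes(10_000, [0.3, 0.3], seed=2).values
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        # 99.9% null bound from a permutation oracle
        rng = np.random.default_rng(3)
        null = [
            abs(np.corrcoef(rng.permutation(g[:, 0]), g[:, 1])[0, 1]) for _ in range(500)
        ]
        assert abs(r) < np.quantile(null, 0.999)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_maf_outside_open_interval(self, bad):
        with pytest.raises(ValueError):
            sample_genotypes(10, [bad], seed=0)


class TestSolveIntercept:
    def test_no_genetic_effects_is_logit_prevalence(self):
        assert solve_intercept([0.3], [0.0], [], 0.1) == pytest.approx(logit(0.1), abs=1e-10)

    def test_two_snp_enumeration_matches_nine_cell_oracle(self):
        # independent 9-cell expectation, written out directly
        maf, beta, k = 0.2, np.log(4.0), 0.1
        b0 = solve_intercept([maf, maf], [beta, beta], [], k)
        probs = {0: (1 - maf) ** 2, 1: 2 * maf * (1 - maf), 2: maf**2}
        expectation = sum(
            probs[g1] * probs[g2] * expit(b0 + beta * (g1 + g2))
            for g1, g2 in itertools.product((0, 1, 2), repeat=2)
        )
        assert abs(expectation - k) < 1e-8

    def test_single_snp_monte_carlo_penetrance(self):
        b0 = solve_intercept([0.3], [np.log(2.0)], [], 0.1)
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, size=10**6)
        pen = expit(b0 + np.log(2.0) * g)
        realized = (rng.random(g.size) < pen).mean()
        se = np.sqrt(0.1 * 0.9 / g.size)
        assert abs(realized - 0.1) < 3 * se

    def test_monte_carlo_path_matches_binomial_sum_oracle(self):
        # 11 equal-effect loci exceed the enumeration limit; with equal betas
        # the exact expectation only involves the Binomial(22, maf) total.
        from scipy.stats import binom

        maf, beta, k = 0.25, 0.1, 0.05
        b0 = solve_intercept([maf] * 11, [beta] * 11, [], k)
        total = np.arange(23)
        exact = float(binom.pmf(total, 22, maf) @ expit(b0 + beta * total))
        assert abs(exact - k) < 2e-3  # Monte-Carlo integration tolerance

    def test_xor_term_enters_expectation(self):
        b0_null = solve_intercept([XOR_NULL_MAF] * 2, [0.0, 0.0], [], 0.1)
        b0_xor = solve_intercept([XOR_NULL_MAF] * 2, [0.0, 0.0], [(0, 1, 1.5)], 0.1)
        # positive interaction risk must push the intercept down
        assert b0_xor < b0_null


class TestAdditivePhenotype:
    def test_null_betas_case_fraction(self):
        g = sample_genotypes(50_000, [0.3] * 3, seed=7)
        k = 0.1
        y = assign_phenotype_additive(g, [0.0] * 3, logit(k), seed=8)
        se = np.sqrt(k * (1 - k) / g.n_samples)
        assert abs(y.mean() - k) < 3 * se

    def test_logistic_regression_recovers_beta(self):
        beta = np.log(2.0)
        g = sample_genotypes(50_000, [0.3], seed=9)
        b0 = solve_intercept([0.3], [beta], [], 0.1)
        y = assign_phenotype_additive(g, [beta], b0, seed=10)
        fit = sm.Logit(y, sm.add_constant(g.values)).fit(disp=0)
        assert abs(fit.params[1] - beta) < 3 * fit.bse[1]

    def test_null_snp_has_no_case_control_maf_difference(self):
        g = sample_genotypes(50_000, [0.3, 0.3], seed=11)
        b0 = solve_intercept([0.3, 0.3], [np.log(2.0), 0.0], [], 0.2)
        y = assign_phenotype_additive(g, [np.log(2.0), 0.0], b0, seed=12)
        cases, controls = g.values[y == 1, 1], g.values[y == 0, 1]
        diff = cases.mean() / 2 - controls.mean() / 2
        se = np.sqrt(0.3 * 0.7 / 2 * (1 / cases.size + 1 / controls.size))
        assert abs(diff) < 3 * se

    def test_misaligned_betas_rejected(self):
        g = sample_genotypes(10, [0.3, 0.3], seed=0)
        with pytest.raises(ValueError):
            assign_phenotype_additive(g, [0.1], 0.0, seed=0)


class TestXorPhenotype:
    def test_theta_zero_case_fraction(self):
        g = sample_genotypes(50_000, [XOR_NULL_MAF] * 2, seed=13)
        b0 = logit(0.15)
        y = assign_phenotype_xor(g, (0, 1), 0.0, b0, seed=14)
        se = np.sqrt(0.15 * 0.85 / g.n_samples)
        assert abs(y.mean() - 0.15) < 3 * se

    def test_null_marginals_but_strong_joint_association(self):
        g = sample_genotypes(50_000, [XOR_NULL_MAF] * 2, seed=15)
        b0 = solve_intercept([XOR_NULL_MAF] * 2, [0.0, 0.0], [(0, 1, 1.5)], 0.2)
        y = assign_phenotype_xor(g, (0, 1), 1.5, b0, seed=16)
        for j in range(2):
            fit = sm.Logit(y, sm.add_constant(g.values[:, j])).fit(disp=0)
            assert abs(fit.params[1]) < 3 * fit.bse[1]
        carriers = (g.values >= 1).astype(int)
        x = carriers[:, 0] ^ carriers[:, 1]
        table = np.array([[np.sum((x == a) & (y == b)) for b in (0, 1)] for a in (0, 1)])
        assert chi2_contingency(table)[1] < 1e-6

    def test_non_default_maf_leaks_marginal_effects(self):
        g = sample_genotypes(50_000, [0.2, 0.2], seed=17)
        b0 = solve_intercept([0.2, 0.2], [0.0, 0.0], [(0, 1, 1.5)], 0.2)
        y = assign_phenotype_xor(g, (0, 1), 1.5, b0, seed=18)
        fit = sm.Logit(y, sm.add_constant(g.values[:, 0])).fit(disp=0)
        assert abs(fit.params[1] / fit.bse[1]) > 3  # documented behavior

    def test_bad_pair_rejected(self):
        g = sample_genotypes(10, [0.3, 0.3], seed=0)
        with pytest.raises(ValueError):
            assign_phenotype_xor(g, (0, 0), 1.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            assign_phenotype_xor(g, (0, 5), 1.0, 0.0, seed=0)


class TestSampleCaseControl:
    def test_exact_quotas(self, additive_cohort):
        y = additive_cohort.phenotype
        assert int((y == 1).sum()) == 400
        assert int((y == 0).sum()) == 400

    def test_risk_allele_enriched_in_cases(self, additive_cohort):
        g = additive_cohort.genotypes
        y = additive_cohort.phenotype
        causal = g.values[:, 0]
        assert causal[y == 1].mean() > causal[y == 0].mean()

    def test_null_snps_not_enriched(self):
        spec = CohortSpec(
            n_cases=2000, n_controls=2000, n_snps=2, mafs=(0.3, 0.3), prevalence=0.1, seed=77
        )
        cohort = sample_case_control(spec)
        g, y = cohort.genotypes.values, cohort.phenotype
        for j in range(2):
            diff = g[y == 1, j].mean() / 2 - g[y == 0, j].mean() / 2
            se = np.sqrt(0.3 * 0.7 / 2 * (1 / 2000 + 1 / 2000))
            assert abs(diff) < 4 * se

    def test_bit_for_bit_reproducible(self):
        spec = CohortSpec(
            n_cases=50, n_controls=60, n_snps=4, missing_rate=0.05, prevalence=0.1, seed=99
        )
        a, b = sample_case_control(spec), sample_case_control(spec)
        np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)
        assert a.beta0 == b.beta0

    def test_attempt_budget_exceeded_is_diagnosed(self):
        spec = CohortSpec(n_cases=500, n_controls=10, n_snps=2, prevalence=0.001, seed=1)
        with pytest.raises(RuntimeError, match="quota"):
            sample_case_control(spec, max_draws_factor=0.01)

    def test_realized_prevalence_tracks_target(self):
        spec = CohortSpec(n_cases=500, n_controls=500, n_snps=2, prevalence=0.1, seed=5)
        cohort = sample_case_control(spec)
        assert 0.05 < cohort.realized_prevalence < 0.2


class TestInjectMissing:
    def test_rate_zero_is_identity(self, additive_cohort):
        g = additive_cohort.genotypes
        out = inject_missing(g, 0.0, seed=0)
        np.testing.assert_array_equal(out.values, g.values)

    def test_rate_one_all_missing(self, additive_cohort):
        out = inject_missing(additive_cohort.genotypes, 1.0, seed=0)
        assert np.isnan(out.values).all()

    def test_rate_binomial_bound(self):
        g = sample_genotypes(10_000, [0.3] * 100, seed=21)
        out = inject_missing(g, 0.01, seed=22)
        frac = np.isnan(out.values).mean()
        se = np.sqrt(0.01 * 0.99 / out.values.size)
        assert abs(frac - 0.01) < 3 * se

    def test_untouched_entries_preserved(self, additive_cohort):
        g = additive_cohort.genotypes
        out = inject_missing(g, 0.3, seed=23)
        kept = ~np.isnan(out.values)
        np.testing.assert_array_equal(out.values[kept], g.values[kept])


class TestCohortSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_cases=0, n_controls=1, n_snps=1),
            dict(n_cases=1, n_controls=1, n_snps=2, epistatic_pairs=((0, 0, 1.0),)),
            dict(n_cases=1, n_controls=1, n_snps=2, epistatic_pairs=((0, 5, 1.0),)),
            dict(n_cases=1, n_controls=1, n_snps=2, causal_betas=(0.1,)),
            dict(n_cases=1, n_controls=1, n_snps=1, prevalence=1.5),
            dict(n_cases=1, n_controls=1, n_snps=1, mafs=(0.0,)),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)

    def test_xor_loci_get_marginal_nulling_maf(self):
        spec = CohortSpec(
            n_cases=10, n_controls=10, n_snps=4, epistatic_pairs=((0, 1, 1.0),), seed=3
        )
        mafs = spec.resolve_mafs()
        assert mafs[0] == pytest.approx(XOR_NULL_MAF)
        assert mafs[1] == pytest.approx(XOR_NULL_MAF)
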