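"""Case-control cohort simulator with additive and epistatic architectures.

The disease model is logistic on the log-odds scale: an individual with
genotype vector ``g`` is a case with probability

    P(case | g) = expit(beta0 + sum_j beta_j g_j + sum_(a,b) theta * XOR(b_a, b_b))

where ``g_j`` is the allele count at SNP ``j``, ``b_j = 1(g_j >= 1)`` is the
dominant carrier indicator, and XOR pairs contribute a purely epistatic term.
The intercept ``beta0`` is solved so that the population prevalence equals a
target ``K``; cohorts are then drawn *retrospectively* — individuals are
sampled from the population and retained until fixed case and control quotas
are met — which reproduces the case enrichment of real case-control panels.

XOR loci default to MAF ``1 - sqrt(1/2)`` so the carrier probability is
exactly one half; at that frequency the XOR indicator is independent of each
single locus, making the per-locus marginal effects exactly null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data import GenotypeMatrix, default_snp_meta

__all__ = [
    "XOR_NULL_MAF",
    "CohortSpec",
    "SimulatedCohort",
    "sample_genotypes",
    "solve_intercept",
    "assign_phenotype_additive",
    "assign_phenotype_xor",
    "sample_case_control",
    "inject_missing",
]

#: MAF at which the carrier probability 1-(1-m)^2 equals 1/2, nulling the
#: marginal effects of an XOR pair.
XOR_NULL_MAF = 1.0 - np.sqrt(0.5)

# Exact genotype combinations are enumerated while 3**n_active stays below
# this; beyond it the prevalence integral falls back to Monte Carlo.
_ENUM_LIMIT = 60_000
_MC_DRAWS = 400_000


def _check_mafs(mafs: np.ndarray) -> np.ndarray:
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or mafs.size == 0:
        raise ValueError("mafs must be a non-empty 1-d sequence")
    if not ((mafs > 0.0) & (mafs < 1.0)).all():
        raise ValueError("every MAF must lie strictly inside (0, 1)")
    return mafs


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a simulated case-control cohort.

    ``causal_betas`` are per-SNP log odds ratios (0 for null SNPs);
    ``epistatic_pairs`` are ``(a, b, theta)`` triples adding ``theta`` to the
    log-odds when exactly one of loci ``a``, ``b`` carries a risk allele.
    ``mafs`` may pin per-SNP frequencies explicitly; otherwise they are drawn
    uniformly from ``maf_range`` (XOR loci forced to :data:`XOR_NULL_MAF`).
    """

    n_cases: int
    n_controls: int
    n_snps: int
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_betas: tuple[float, ...] | None = None
    epistatic_pairs: tuple[tuple[int, int, float], ...] = ()
    # Population prevalence; 1% is realistic for schizophrenia-like disorders
    # and keeps penetrance far from logistic saturation, so retrospective
    # sampling enriches risk alleles without strong collider distortion.
    prevalence: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0
    mafs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.causal_betas is not None:
            object.__setattr__(self, "causal_betas", tuple(float(b) for b in self.causal_betas))
            if len(self.causal_betas) != self.n_snps:
                raise ValueError("causal_betas length must equal n_snps")
        pairs = tuple((int(a), int(b), float(t)) for a, b, t in self.epistatic_pairs)
        object.__setattr__(self, "epistatic_pairs", pairs)
        for a, b, _ in pairs:
            if a == b:
                raise ValueError("epistatic pair indices must be distinct")
            if not (0 <= a < self.n_snps and 0 <= b < self.n_snps):
                raise ValueError("epistatic pair index out of range")
        if self.mafs is not None:
            m = _check_mafs(np.asarray(self.mafs))
            if m.size != self.n_snps:
                raise ValueError("mafs length must equal n_snps")
            object.__setattr__(self, "mafs", tuple(float(x) for x in m))

    @property
    def betas(self) -> np.ndarray:
        if self.causal_betas is None:
            return np.zeros(self.n_snps)
        return np.asarray(self.causal_betas, dtype=float)

    def resolve_mafs(self) -> np.ndarray:
        """Per-SNP MAFs: explicit if given, else drawn from ``maf_range``.

        The draw uses a dedicated child stream of ``seed`` so it does not
        perturb genotype or phenotype sampling.  XOR loci are forced to the
        marginal-nulling frequency unless ``mafs`` was set explicitly.
        """
        if self.mafs is not None:
            return np.asarray(self.mafs, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xA11E1E]))
        mafs = rng.uniform(self.maf_range[0], self.maf_range[1], size=self.n_snps)
        for a, b, _ in self.epistatic_pairs:
            mafs[a] = XOR_NULL_MAF
            mafs[b] = XOR_NULL_MAF
        return mafs


@dataclass
class SimulatedCohort:
    """A realized cohort plus the ground truth that generated it."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    spec: CohortSpec
    mafs: np.ndarray
    beta0: float
    realized_prevalence: float
    n_drawn: int

    def __post_init__(self) -> None:
        y = np.asarray(self.phenotype)
        if y.shape[0] != self.genotypes.n_samples:
            raise ValueError("phenotype not aligned to genotype rows")
        if int((y == 1).sum()) != self.spec.n_cases or int((y == 0).sum()) != self.spec.n_controls:
            raise ValueError("case/control counts do not match the spec quotas")


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------


def sample_genotypes(n_individuals: int, mafs: Sequence[float], seed) -> GenotypeMatrix:
    """Draw ``n_individuals`` unrelated genotypes at independent SNPs.

    Each genotype is the sum of two independent Bernoulli(MAF) allele draws,
    i.e. Binomial(2, MAF), giving Hardy-Weinberg proportions in expectation.
    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    mafs = _check_mafs(np.asarray(mafs))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = rng.binomial(2, mafs, size=(n_individuals, mafs.size)).astype(float)
    return GenotypeMatrix(
        values=values,
        snp_meta=default_snp_meta(mafs.size),
        sample_ids=np.array([f"ind{i + 1}" for i in range(n_individuals)]),
    )


def _as_values(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.values
    return np.asarray(genotypes, dtype=float)


def linear_predictor(
    genotypes,
    betas: Sequence[float],
    epistatic_pairs: Sequence[tuple[int, int, float]] = (),
) -> np.ndarray:
    """Genetic log-odds contribution (without intercept) per individual."""
    g = _as_values(genotypes)
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] != g.shape[1]:
        raise ValueError(f"{betas.shape[0]} betas for {g.shape[1]} SNP columns")
    eta = g @ betas
    for a, b, theta in epistatic_pairs:
        carriers = g[:, [a, b]] >= 1.0
        eta = eta + theta * (carriers[:, 0] ^ carriers[:, 1])
    return eta


def solve_intercept(
    mafs: Sequence[float],
    causal_betas: Sequence[float],
    epistatic_pairs: Sequence[tuple[int, int, float]],
    prevalence: float,
) -> float:
    """Intercept beta0 such that the population mean penetrance equals K.

    The expectation of ``expit(beta0 + eta(g))`` over the HWE genotype
    distribution is computed by exact enumeration of genotype combinations at
    the active loci (those with a nonzero beta or in an epistatic pair) when
    the 3^m grid is small, and otherwise by Monte Carlo with a fixed draw
    count and internal seed, so the result is deterministic.  The root is
    then solved by bisection to well below 1e-8.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    mafs = _check_mafs(np.asarray(mafs))
    betas = np.asarray(causal_betas, dtype=float)
    if betas.shape[0] != mafs.shape[0]:
        raise ValueError("causal_betas and mafs lengths differ")
    pairs = [(int(a), int(b), float(t)) for a, b, t in epistatic_pairs]

    active = set(np.flatnonzero(betas != 0.0).tolist())
    for a, b, _ in pairs:
        active.add(a)
        active.add(b)
    active_idx = sorted(active)
    m = len(active_idx)
    if m == 0:
        return float(logit(prevalence))

    pos = {j: k for k, j in enumerate(active_idx)}
    sub_betas = betas[active_idx]
    sub_pairs = [(pos[a], pos[b], t) for a, b, t in pairs]
    sub_mafs = mafs[active_idx]

    if 3**m <= _ENUM_LIMIT:
        combos = np.array(list(itertools.product((0.0, 1.0, 2.0), repeat=m)))
        # HWE genotype probabilities per locus: (1-p)^2, 2p(1-p), p^2
        geno_p = np.stack(
            [(1 - sub_mafs) ** 2, 2 * sub_mafs * (1 - sub_mafs), sub_mafs**2], axis=0
        )
        probs = np.prod(geno_p[combos.astype(int), np.arange(m)], axis=1)
        eta = linear_predictor(combos, sub_betas, sub_pairs)
        weights = probs
    else:
        rng = np.random.default_rng(np.random.SeedSequence([0x1B57E9, m]))
        draws = rng.binomial(2, sub_mafs, size=(_MC_DRAWS, m)).astype(float)
        eta = linear_predictor(draws, sub_betas, sub_pairs)
        weights = np.full(eta.shape[0], 1.0 / eta.shape[0])
        probs = weights

    def mean_penetrance_minus_k(b0: float) -> float:
        return float(weights @ expit(b0 + eta)) - prevalence

    lo, hi = -45.0, 45.0
    if mean_penetrance_minus_k(lo) > 0 or mean_penetrance_minus_k(hi) < 0:
        raise RuntimeError("no intercept root in bracket [-45, 45]")
    return float(brentq(mean_penetrance_minus_k, lo, hi, xtol=1e-12, rtol=1e-14))


# ---------------------------------------------------------------------------
# phenotype assignment
# ---------------------------------------------------------------------------


def assign_phenotype_additive(genotypes, causal_betas, beta0: float, seed) -> np.ndarray:
    """Bernoulli case labels under the additive logistic model."""
    g = _as_values(genotypes)
    eta = linear_predictor(g, causal_betas)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (rng.random(g.shape[0]) < expit(beta0 + eta)).astype(np.int64)


def assign_phenotype_xor(
    genotypes, pair: tuple[int, int], theta: float, beta0: float, seed
) -> np.ndarray:
    """Bernoulli case labels under a pure two-locus XOR model.

    The case probability is ``expit(beta0 + theta * XOR(b_a, b_b))`` with
    dominant carrier indicators ``b_j = 1(g_j >= 1)``; no additive terms.
    """
    g = _as_values(genotypes)
    a, b = int(pair[0]), int(pair[1])
    if a == b:
        raise ValueError("pair indices must be distinct")
    if not (0 <= a < g.shape[1] and 0 <= b < g.shape[1]):
        raise ValueError("pair index out of range")
    eta = linear_predictor(g, np.zeros(g.shape[1]), [(a, b, float(theta))])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (rng.random(g.shape[0]) < expit(beta0 + eta)).astype(np.int64)


# ---------------------------------------------------------------------------
# retrospective sampling and missingness
# ---------------------------------------------------------------------------


def sample_case_control(
    spec: CohortSpec,
    seed: int | None = None,
    max_draws_factor: float = 50.0,
) -> SimulatedCohort:
    """Draw a cohort meeting exact case/control quotas by rejection sampling.

    Individuals are simulated from the population model in batches; cases are
    retained until ``spec.n_cases`` is reached and likewise for controls.
    The attempt budget is ``max_draws_factor * (n_cases/K + n_controls/(1-K))``
    expected draws; exceeding it (e.g. a vanishing prevalence) raises.
    """
    if seed is None:
        seed = spec.seed
    root = np.random.SeedSequence(int(seed))
    s_geno, s_pheno, s_shuffle, s_missing = root.spawn(4)
    rng_g = np.random.default_rng(s_geno)
    rng_p = np.random.default_rng(s_pheno)

    mafs = spec.resolve_mafs()
    betas = spec.betas
    beta0 = solve_intercept(mafs, betas, spec.epistatic_pairs, spec.prevalence)

    k = spec.prevalence
    budget = int(max_draws_factor * (spec.n_cases / k + spec.n_controls / (1.0 - k)))
    # Batch large enough to usually finish in one pass, capped to bound memory.
    batch = min(max(1024, int(2 * max(spec.n_cases / k, spec.n_controls / (1.0 - k)))), 250_000)

    cases_g: list[np.ndarray] = []
    controls_g: list[np.ndarray] = []
    n_case = n_control = n_drawn = n_cases_seen = 0
    while n_case < spec.n_cases or n_control < spec.n_controls:
        if n_drawn >= budget:
            raise RuntimeError(
                f"case/control quotas not met after {n_drawn} draws "
                f"(prevalence {k} too extreme for the requested cohort)"
            )
        g = rng_g.binomial(2, mafs, size=(batch, mafs.size)).astype(float)
        eta = linear_predictor(g, betas, spec.epistatic_pairs)
        y = rng_p.random(batch) < expit(beta0 + eta)
        n_drawn += batch
        n_cases_seen += int(y.sum())
        if n_case < spec.n_cases:
            take = g[y][: spec.n_cases - n_case]
            cases_g.append(take)
            n_case += take.shape[0]
        if n_control < spec.n_controls:
            take = g[~y][: spec.n_controls - n_control]
            controls_g.append(take)
            n_control += take.shape[0]

    values = np.vstack(cases_g + controls_g)
    phenotype = np.concatenate(
        [np.ones(spec.n_cases, dtype=np.int64), np.zeros(spec.n_controls, dtype=np.int64)]
    )
    order = np.random.default_rng(s_shuffle).permutation(values.shape[0])
    values, phenotype = values[order], phenotype[order]

    genotypes = GenotypeMatrix(
        values=values,
        snp_meta=default_snp_meta(spec.n_snps),
        sample_ids=np.array([f"ind{i + 1}" for i in range(values.shape[0])]),
    )
    if spec.missing_rate > 0.0:
        genotypes = inject_missing(genotypes, spec.missing_rate, np.random.default_rng(s_missing))

    return SimulatedCohort(
        genotypes=genotypes,
        phenotype=phenotype,
        spec=spec,
        mafs=mafs,
        beta0=beta0,
        realized_prevalence=n_cases_seen / n_drawn,
        n_drawn=n_drawn,
    )


def inject_missing(genotypes: GenotypeMatrix, missing_rate: float, seed) -> GenotypeMatrix:
    """Set each entry to missing independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    out = genotypes.copy()
    if missing_rate == 0.0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < missing_rate
    out.values[mask] = np.nan
    return out
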