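"""Independent small-scale oracles for the stochastic engine.

Three classical results give exact or analytic expectations that the full
individual-based simulator must reproduce in reduced configurations:

* Under complete selfing with fully homozygous founders and no mutation,
  the diploid model collapses to N competing haploid lineages in which a
  mutant lineage has relative fitness 1 - s.  The exact fixation
  probability of the mutant follows from the absorbing Markov chain whose
  next-generation mutant count is Binomial(N, p') with
  p' = k (1 - s) / (k (1 - s) + (N - k)).
* Under complete selfing, neutral observed heterozygosity halves every
  generation.
* Under partial selfing at rate sigma, the neutral equilibrium inbreeding
  coefficient is F = sigma / (2 - sigma).

``check_engine_against_oracles`` runs the simulator in these reduced
configurations and reports each deviation in Monte-Carlo standard errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    AlleleRegistry,
    OUTCROSSER,
    Population,
    SimulationParams,
)
from .life_cycle import next_generation
from .statistics import observed_heterozygosity

__all__ = [
    "haploid_wf_fixation_prob",
    "selfing_inbreeding_equilibrium",
    "neutral_fis_expectation",
    "measure_fis",
    "check_engine_against_oracles",
]


def haploid_wf_fixation_prob(N: int, s: float, k0: int) -> float:
    """Exact fixation probability of a selected haploid Wright-Fisher mutant.

    Builds the (N+1)-state Markov chain with transition kernel
    ``Binomial(N, p'(k))`` where ``p'(k) = k(1-s) / (k(1-s) + (N-k))`` and
    solves the linear system for the absorption probability at state N
    starting from ``k0`` mutant copies.
    """
    if not 0 <= k0 <= N:
        raise ValueError("k0 must lie in [0, N]")
    if not 0.0 <= s < 1.0:
        raise ValueError("s must lie in [0, 1)")
    if k0 == 0:
        return 0.0
    if k0 == N:
        return 1.0
    k = np.arange(1, N)
    p_prime = k * (1.0 - s) / (k * (1.0 - s) + (N - k))
    # P[i, j]: transition from k = i+1 mutants to j mutants, j = 0..N
    P = stats.binom.pmf(np.arange(N + 1)[np.newaxis, :], N, p_prime[:, np.newaxis])
    Q = P[:, 1:N]  # transient -> transient
    b = P[:, N]  # transient -> fixation
    u = np.linalg.solve(np.eye(N - 1) - Q, b)
    return float(u[k0 - 1])


def selfing_inbreeding_equilibrium(sigma: float) -> float:
    """Neutral equilibrium inbreeding coefficient F = sigma / (2 - sigma).

    This is the classical infinite-population result; finite populations sit
    slightly below it (see :func:`neutral_fis_expectation`).
    """
    if not 0.0 <= sigma < 1.0:
        raise ValueError("sigma must lie in [0, 1); full selfing has no equilibrium")
    return sigma / (2.0 - sigma)


def neutral_fis_expectation(n_pop: int, sigma: float, mu: float) -> float:
    """Exact stationary F_IS of this life cycle at finite N with mutation.

    Solves the linear identity-by-descent recursions for the probabilities
    Q1 (two homologous genes within an individual identical) and Q2 (two
    genes in distinct individuals identical) under neutral infinite-allele
    mutation at rate ``mu`` per gene per generation:

        Q1' = a [ sigma (1 + Q1)/2 + (1 - sigma) Q2 ]
        Q2' = a [ (1 + Q1)/(2N) + (1 - 1/N) Q2 ],   a = (1 - mu)^2 .

    The returned value is the expectation of the pooled estimator
    ``1 - Ho / He`` with He the small-sample-corrected gene diversity (whose
    denominator mixes within- and between-individual pairs in proportion
    1 : 2N - 2).  As N grows and mu shrinks this converges to
    ``sigma / (2 - sigma)``.
    """
    a = (1.0 - mu) ** 2
    n = n_pop
    A = np.array(
        [
            [1.0 - a * sigma / 2.0, -a * (1.0 - sigma)],
            [-a / (2.0 * n), 1.0 - a * (1.0 - 1.0 / n)],
        ]
    )
    b = np.array([a * sigma / 2.0, a / (2.0 * n)])
    q1, q2 = np.linalg.solve(A, b)
    q_pooled = (q1 + (2 * n - 2) * q2) / (2 * n - 1)
    return float(1.0 - (1.0 - q1) / (1.0 - q_pooled))


def _row(config: str, observed: float, expected: float, se: float) -> dict:
    z = 0.0 if se == 0 else (observed - expected) / se
    return {
        "configuration": config,
        "observed": observed,
        "expected": expected,
        "se": se,
        "z": z,
        "passed": abs(z) <= 4.0,
    }


def _het_halving_check(rng: np.random.Generator, n_replicates: int) -> dict:
    """Fit the per-generation decay of neutral heterozygosity under sigma = 1."""
    n_pop, n_gen = 50, 6
    params = SimulationParams(
        n_pop=n_pop, n_loc=1, r=0.0, mu=0.0, sigma_s=1.0, t1=0, t_post=0,
        n_replicates=1, record_every=1,
    )
    ratios = []
    for _ in range(n_replicates):
        registry = AlleleRegistry()
        # Every individual heterozygous wild-type / private neutral allele.
        ids = registry.register_batch(np.zeros(n_pop), OUTCROSSER, 0)
        alleles = np.zeros((n_pop, 2, 1), dtype=np.int64)
        alleles[:, 1, 0] = ids
        ancestry = np.zeros_like(alleles, dtype=np.int8)
        pop = Population(alleles, ancestry, 1.0, "selfer", registry)
        het = [observed_heterozygosity(pop)]
        for _ in range(n_gen):
            pop = next_generation(pop, False, params, rng)
            het.append(observed_heterozygosity(pop))
        het = np.array(het)
        keep = het[:-1] > 0
        if keep.any():
            ratios.append(float(np.mean(het[1:][keep] / het[:-1][keep])))
    ratios = np.array(ratios)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    return _row("neutral het decay per generation, sigma=1", ratios.mean(), 0.5, se)


def _fixation_check(rng: np.random.Generator, n_replicates: int) -> dict:
    """sigma = 1, homozygous founders: simulator vs exact haploid chain."""
    n_pop, s = 10, 0.1
    expected = haploid_wf_fixation_prob(n_pop, s, k0=1)
    params = SimulationParams(
        n_pop=n_pop, n_loc=1, r=0.0, mu=0.0, sigma_s=1.0, t1=0, t_post=0,
        n_replicates=1, record_every=1,
    )
    fixed = 0
    for _ in range(n_replicates):
        registry = AlleleRegistry()
        mutant = registry.register(s, OUTCROSSER, 0)
        alleles = np.zeros((n_pop, 2, 1), dtype=np.int64)
        alleles[0, :, 0] = mutant  # one homozygous mutant founder
        ancestry = np.zeros_like(alleles, dtype=np.int8)
        pop = Population(alleles, ancestry, 1.0, "selfer", registry)
        while True:
            present = np.count_nonzero(pop.alleles == mutant)
            if present == 0:
                break
            if present == 2 * n_pop:
                fixed += 1
                break
            pop = next_generation(pop, False, params, rng)
    p_hat = fixed / n_replicates
    se = np.sqrt(expected * (1 - expected) / n_replicates)
    return _row(
        f"fixation prob, sigma=1, N={n_pop}, s={s}, k0=1", p_hat, expected, se
    )


def _neutral_variance_check(rng: np.random.Generator, n_replicates: int) -> dict:
    """sigma = 0 neutral drift: allele-frequency variance after t generations."""
    n_pop, t, p0 = 20, 10, 0.5
    expected = p0 * (1 - p0) * (1 - (1 - 1 / (2 * n_pop)) ** t)
    params = SimulationParams(
        n_pop=n_pop, n_loc=1, r=0.0, mu=0.0, sigma_o=0.0, t1=0, t_post=0,
        n_replicates=1, record_every=1,
    )
    freqs = np.empty(n_replicates)
    for i in range(n_replicates):
        registry = AlleleRegistry()
        marker = registry.register(0.0, OUTCROSSER, 0)  # neutral marker allele
        alleles = np.zeros((n_pop, 2, 1), dtype=np.int64)
        alleles[:, 0, 0] = marker  # every individual heterozygous, p = 0.5
        ancestry = np.zeros_like(alleles, dtype=np.int8)
        pop = Population(alleles, ancestry, 0.0, "outcrosser", registry)
        for _ in range(t):
            pop = next_generation(pop, False, params, rng)
        freqs[i] = np.count_nonzero(pop.alleles == marker) / (2 * n_pop)
    var_hat = freqs.var(ddof=1)
    # SE of a sample variance: sqrt((m4 - var^2 (n-3)/(n-1)) / n)
    m4 = np.mean((freqs - freqs.mean()) ** 4)
    n = n_replicates
    se = np.sqrt(max(m4 - var_hat**2 * (n - 3) / (n - 1), 0.0) / n)
    return _row(
        f"neutral allele-frequency variance, sigma=0, t={t}", var_hat, expected, se
    )


def measure_fis(
    rng: np.random.Generator,
    n_pop: int,
    sigma: float,
    mu: float,
    n_loc: int = 24,
    burn: int | None = None,
    n_samples: int = 8,
    sample_every: int = 20,
    n_replicates: int = 6,
) -> tuple[float, float]:
    """Monte-Carlo F_IS of the engine at neutral mutation-drift equilibrium.

    Runs ``n_replicates`` independent populations with effectively neutral
    mutation (huge DFE rate parameter, so every drawn effect is tiny), burns
    in to equilibrium and pools observed heterozygosity and gene diversity
    over loci and sampling times before taking the ratio (pooling avoids the
    downward ratio bias of per-locus estimates).  Returns (mean, SE) over
    replicates.
    """
    params = SimulationParams(
        n_pop=n_pop, n_loc=n_loc, r=0.5, mu=mu, lambda_=1e9,
        sigma_s=sigma, t1=0, t_post=0, n_replicates=1, record_every=1,
    )
    if burn is None:
        burn = 3 * n_pop  # mutation-drift equilibration
    n_copies = 2 * n_pop
    f_values = []
    for _ in range(n_replicates):
        registry = AlleleRegistry()
        pop = Population.wild_type(n_pop, n_loc, sigma, "selfer", registry)
        for gen in range(burn):
            pop = next_generation(pop, True, params, rng, origin_gen=gen)
        ho_sum = he_sum = 0.0
        for _k in range(n_samples):
            for gen in range(sample_every):
                pop = next_generation(pop, True, params, rng, origin_gen=burn + gen)
            ho_sum += observed_heterozygosity(pop) * n_loc
            for j in range(n_loc):
                _ids, counts = np.unique(pop.alleles[:, :, j], return_counts=True)
                p = counts / counts.sum()
                # small-sample-corrected gene diversity
                he_sum += n_copies / (n_copies - 1) * (1.0 - np.sum(p**2))
        if he_sum > 0:
            f_values.append(1.0 - ho_sum / he_sum)
    f_values = np.array(f_values)
    se = f_values.std(ddof=1) / np.sqrt(len(f_values))
    return float(f_values.mean()), float(se)


def _inbreeding_check(rng: np.random.Generator, n_replicates: int) -> dict:
    """Partial selfing at sigma = 0.9: equilibrium F_IS vs sigma/(2 - sigma).

    Run at N = 1600 so the exact finite-N departure from the asymptotic
    formula (see :func:`neutral_fis_expectation`) stays well below the
    Monte-Carlo resolution of the check.
    """
    sigma = 0.9
    expected = selfing_inbreeding_equilibrium(sigma)
    mean, se = measure_fis(
        rng, n_pop=1600, sigma=sigma, mu=2.5e-4, n_loc=24,
        burn=3200, n_samples=4, sample_every=40, n_replicates=n_replicates,
    )
    return _row(f"equilibrium F_IS, sigma={sigma}", mean, expected, se)


def check_engine_against_oracles(
    seed: int = 0,
    n_replicates_fixation: int = 2000,
    n_replicates_het: int = 500,
    n_replicates_variance: int = 1000,
    n_replicates_inbreeding: int = 6,
) -> pd.DataFrame:
    """Run all engine-vs-oracle comparisons; any |z| > 4 marks a failure."""
    children = np.random.SeedSequence(seed).spawn(4)
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children]
    rows = [
        _het_halving_check(rngs[0], n_replicates_het),
        _fixation_check(rngs[1], n_replicates_fixation),
        _neutral_variance_check(rngs[2], n_replicates_variance),
        _inbreeding_check(rngs[3], n_replicates_inbreeding),
    ]
    return pd.DataFrame(rows)
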