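"""One-generation update: selection, mating system, meiosis and mutation.

Each offspring is produced independently.  With probability sigma it is
selfed: one parent is selected and contributes two independent meiotic
gametes.  Otherwise it is outcrossed: two distinct parents are selected and
contribute one gamete each.  Parent selection is fitness-proportional,
implemented for single draws as the literal rejection loop (draw uniformly,
accept with probability w_i) and for whole-generation batches by
inverse-CDF sampling on the cumulative fitness vector, which has the same
marginal distribution.

Meiosis uses a per-interval crossover model: the gamete starts on a
uniformly chosen homolog and switches its source homolog independently with
probability ``r`` in each of the ``n_loc - 1`` adjacent intervals (multiple
crossovers allowed, no interference).  Ancestry tags travel with the copied
alleles.  Mutation, when enabled, hits each gamete locus independently with
probability ``mu`` and replaces the resident allele with a freshly
registered one (infinite-allele model).
"""

from __future__ import annotations

import numpy as np

from .genome_model import (
    AlleleRegistry,
    ConfigurationError,
    ExtinctionError,
    Haplotype,
    Individual,
    Population,
    SimulationParams,
    draw_mutation_effect,
    population_fitness,
)

__all__ = [
    "make_gamete",
    "choose_parent",
    "choose_parent_index",
    "reproduce_one",
    "next_generation",
]

# Above this expected number of events per batch, draw dense Bernoulli masks
# instead of sampling sparse event positions.
_DENSE_THRESHOLD = 512


def _sparse_event_sites(rng, n_sites: int, p: float) -> np.ndarray:
    """Indices of Bernoulli(p) successes over ``n_sites`` independent sites."""
    if p <= 0.0 or n_sites == 0:
        return np.empty(0, dtype=np.int64)
    n_events = rng.binomial(n_sites, p)
    if n_events == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(n_sites, size=n_events, replace=False).astype(np.int64)


def _gamete_batch(
    alleles: np.ndarray,
    ancestry: np.ndarray,
    parent_idx: np.ndarray,
    r: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Form one recombinant gamete per entry of ``parent_idx``.

    Returns (k, L) allele-id and ancestry arrays.
    """
    k = parent_idx.shape[0]
    n_loc = alleles.shape[2]
    start = rng.integers(0, 2, size=k)
    if n_loc == 1 or r == 0.0:
        active_const = start
        gam_alleles = alleles[parent_idx, active_const, :]
        gam_ancestry = ancestry[parent_idx, active_const, :]
        return gam_alleles, gam_ancestry

    n_int = n_loc - 1
    expected = k * n_int * r
    if expected > _DENSE_THRESHOLD:
        switches = rng.random((k, n_int)) < r
        parity = np.cumsum(switches, axis=1, dtype=np.int64) & 1
        active = np.empty((k, n_loc), dtype=np.intp)
        active[:, 0] = start
        active[:, 1:] = start[:, None] ^ parity
        cols = np.arange(n_loc)
        gam_alleles = alleles[parent_idx[:, None], active, cols]
        gam_ancestry = ancestry[parent_idx[:, None], active, cols]
        return gam_alleles, gam_ancestry

    sites = _sparse_event_sites(rng, k * n_int, r)
    # fancy indexing already yields fresh writable arrays
    gam_alleles = alleles[parent_idx, start, :]
    gam_ancestry = ancestry[parent_idx, start, :]
    if sites.size:
        rows = sites // n_int
        intervals = sites % n_int
        for row in np.unique(rows):
            ivs = intervals[rows == row]
            parity = np.zeros(n_loc, dtype=np.intp)
            np.add.at(parity, ivs + 1, 1)
            parity = np.cumsum(parity) & 1
            active = start[row] ^ parity
            p = parent_idx[row]
            gam_alleles[row] = alleles[p, active, np.arange(n_loc)]
            gam_ancestry[row] = ancestry[p, active, np.arange(n_loc)]
    return gam_alleles, gam_ancestry


def _mutate_batch(
    gam_alleles: np.ndarray,
    mu: float,
    lambda_: float,
    registry: AlleleRegistry,
    origin_pop: int,
    origin_gen: int,
    rng: np.random.Generator,
) -> None:
    """Apply per-locus mutation in place to a (k, L) gamete allele array."""
    if mu <= 0.0:
        return
    k, n_loc = gam_alleles.shape
    n_sites = k * n_loc
    if n_sites * mu > _DENSE_THRESHOLD:
        mask = rng.random((k, n_loc)) < mu
        rows, cols = np.nonzero(mask)
    else:
        sites = _sparse_event_sites(rng, n_sites, mu)
        if sites.size == 0:
            return
        rows, cols = sites // n_loc, sites % n_loc
    if rows.size == 0:
        return
    effects = draw_mutation_effect(rng, lambda_, size=rows.size)
    new_ids = registry.register_batch(effects, origin_pop, origin_gen)
    gam_alleles[rows, cols] = new_ids


def make_gamete(
    parent: Individual,
    r: float,
    mutate: bool,
    params: SimulationParams,
    rng: np.random.Generator,
    origin_pop: int = 0,
    origin_gen: int = 0,
) -> Haplotype:
    """One meiotic gamete of ``parent`` (see module docstring for the model)."""
    alleles = np.stack([parent.hap1.alleles, parent.hap2.alleles])[np.newaxis]
    ancestry = np.stack([parent.hap1.ancestry, parent.hap2.ancestry])[np.newaxis]
    gam_a, gam_t = _gamete_batch(alleles, ancestry, np.zeros(1, dtype=np.intp), r, rng)
    if mutate:
        _mutate_batch(
            gam_a, params.mu, params.lambda_, parent.registry, origin_pop, origin_gen, rng
        )
    return Haplotype(gam_a[0], gam_t[0])


def choose_parent_index(pop: Population, rng: np.random.Generator) -> int:
    """Fitness-rejection sampling of one parent; returns its index.

    Draw an index uniformly, accept with probability equal to its fitness,
    repeat until acceptance.  The marginal selection probability is
    proportional to fitness.
    """
    w = pop.fitness
    if not np.any(w > 0):
        raise ExtinctionError(
            f"population {pop.label!r}: every individual has fitness 0"
        )
    n = pop.n_pop
    while True:
        i = int(rng.integers(0, n))
        if rng.random() < w[i]:
            return i


def choose_parent(pop: Population, rng: np.random.Generator) -> Individual:
    return pop.member(choose_parent_index(pop, rng))


def _batch_parent_indices(
    fitness: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-proportional parent indices (inverse-CDF batch sampling)."""
    cdf = np.cumsum(fitness)
    total = cdf[-1]
    u = rng.random(size) * total
    return np.searchsorted(cdf, u, side="right").astype(np.intp)


def reproduce_one(
    pop: Population,
    sigma: float,
    mutate: bool,
    params: SimulationParams,
    rng: np.random.Generator,
    origin_gen: int = 0,
) -> Individual:
    """Produce a single offspring (object-level path, used for small studies).

    With probability ``sigma`` one accepted parent contributes two
    independent gametes (selfing: two distinct meioses of the same
    individual); otherwise two distinct accepted parents contribute one
    gamete each.
    """
    if pop.n_pop == 1 and sigma < 1.0:
        raise ConfigurationError("outcrossing impossible with a single individual")
    origin = pop.label_code
    if rng.random() < sigma:
        parent = choose_parent(pop, rng)
        hap1 = make_gamete(parent, params.r, mutate, params, rng, origin, origin_gen)
        hap2 = make_gamete(parent, params.r, mutate, params, rng, origin, origin_gen)
    else:
        i = choose_parent_index(pop, rng)
        j = choose_parent_index(pop, rng)
        while j == i:
            j = choose_parent_index(pop, rng)
        hap1 = make_gamete(
            pop.member(i), params.r, mutate, params, rng, origin, origin_gen
        )
        hap2 = make_gamete(
            pop.member(j), params.r, mutate, params, rng, origin, origin_gen
        )
    return Individual(hap1, hap2, pop.registry)


def next_generation(
    pop: Population,
    mutate: bool,
    params: SimulationParams,
    rng: np.random.Generator,
    origin_gen: int = 0,
) -> Population:
    """Replace the whole generation with ``n_pop`` independent offspring.

    Non-overlapping generations: every offspring draws its parents from
    ``pop`` only.  The returned population carries the same registry, selfing
    rate, label and substitution history; its fixed-mutation counter is
    updated by the caller via :func:`hybridload.statistics.update_fixed_count`.
    """
    w = pop.fitness
    if not np.any(w > 0):
        raise ExtinctionError(
            f"population {pop.label!r}: every individual has fitness 0"
        )
    n = pop.n_pop
    selfed = rng.random(n) < pop.sigma
    mothers = _batch_parent_indices(w, n, rng)
    fathers = mothers.copy()
    out = np.nonzero(~selfed)[0]
    if out.size:
        if n == 1:
            raise ConfigurationError(
                "outcrossing impossible with a single individual"
            )
        second = _batch_parent_indices(w, out.size, rng)
        clash = second == mothers[out]
        while np.any(clash):
            second[clash] = _batch_parent_indices(w, int(clash.sum()), rng)
            clash = second == mothers[out]
        fathers[out] = second
    # interleave so offspring i owns gamete rows 2i (maternal) and 2i+1
    parent_idx = np.empty(2 * n, dtype=np.intp)
    parent_idx[0::2] = mothers
    parent_idx[1::2] = fathers
    gam_a, gam_t = _gamete_batch(pop.alleles, pop.ancestry, parent_idx, params.r, rng)
    if mutate:
        _mutate_batch(
            gam_a,
            params.mu,
            params.lambda_,
            pop.registry,
            pop.label_code,
            origin_gen,
            rng,
        )
    child_alleles = gam_a.reshape(n, 2, -1)
    child_ancestry = gam_t.reshape(n, 2, -1)
    fitness = population_fitness(child_alleles, pop.registry)
    return pop._spawn_like(child_alleles, child_ancestry, fitness)
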