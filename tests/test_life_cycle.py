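"""Meiosis, fitness-proportional parent sampling and the generation update."""

import numpy as np
import pytest

from hybridload import (
    AlleleRegistry,
    Haplotype,
    Individual,
    SimulationParams,
    choose_parent,
    make_gamete,
    next_generation,
    reproduce_one,
)
from hybridload.genome_model import ExtinctionError, OUTCROSSER, SELFER
from hybridload.life_cycle import choose_parent_index
from hybridload.statistics import observed_heterozygosity

from conftest import make_population


def _params(**kw):
    base = dict(n_pop=20, n_loc=10, r=0.0, mu=0.0, t1=0, t_post=0, n_replicates=1)
    base.update(kw)
    return SimulationParams(**base)


def _distinct_parent(registry, n_loc=10):
    """Parent whose haplotypes are distinguishable at every locus."""
    ids = registry.register_batch(np.full(2 * n_loc, 0.01), OUTCROSSER, 0)
    h1 = Haplotype(ids[:n_loc].copy(), np.zeros(n_loc, dtype=np.int8))
    h2 = Haplotype(ids[n_loc:].copy(), np.ones(n_loc, dtype=np.int8))
    return Individual(h1, h2, registry), ids


class TestMakeGamete:
    def test_no_recombination_copies_one_homolog(self, registry, rng):
        parent, ids = _distinct_parent(registry)
        params = _params(r=0.0)
        seen = set()
        for _ in range(50):
            g = make_gamete(parent, 0.0, False, params, rng)
            if np.array_equal(g.alleles, parent.hap1.alleles):
                seen.add(1)
                assert np.all(g.ancestry == 0)
            elif np.array_equal(g.alleles, parent.hap2.alleles):
                seen.add(2)
                assert np.all(g.ancestry == 1)
            else:  # pragma: no cover
                pytest.fail("gamete is neither parental haplotype")
        assert seen == {1, 2}

    def test_homozygous_parent_any_r(self, registry, rng):
        n_loc = 10
        ids = registry.register_batch(np.full(n_loc, 0.05), OUTCROSSER, 0)
        tags = np.zeros(n_loc, dtype=np.int8)
        parent = Individual(
            Haplotype(ids.copy(), tags.copy()), Haplotype(ids.copy(), tags.copy()), registry
        )
        params = _params(r=0.5)
        for _ in range(10):
            g = make_gamete(parent, 0.5, False, params, rng)
            assert np.array_equal(g.alleles, ids)

    def test_mean_crossover_count(self, registry, rng):
        """Switch count over 1e5 gametes matches Binomial(L-1, r)."""
        n_loc, r, n_gam = 100, 0.1, 20_000
        parent, _ = _distinct_parent(registry, n_loc)
        params = _params(n_loc=n_loc, r=r)
        switches = 0
        for _ in range(n_gam):
            g = make_gamete(parent, r, False, params, rng)
            switches += int(np.sum(g.ancestry[1:] != g.ancestry[:-1]))
        mean = switches / n_gam
        se = np.sqrt((n_loc - 1) * r * (1 - r) / n_gam)
        assert abs(mean - (n_loc - 1) * r) < 4 * se

    def test_ancestry_travels_with_alleles(self, registry, rng):
        """Tag at locus j always equals the tag of the copied homolog."""
        n_loc = 20
        parent, ids = _distinct_parent(registry, n_loc)
        params = _params(n_loc=n_loc, r=0.3)
        id_to_tag = {int(a): 0 for a in ids[:n_loc]}
        id_to_tag.update({int(a): 1 for a in ids[n_loc:]})
        for _ in range(30):
            g = make_gamete(parent, 0.3, False, params, rng)
            expected = np.array([id_to_tag[int(a)] for a in g.alleles])
            assert np.array_equal(g.ancestry, expected)

    def test_mutation_replaces_allele(self, registry, rng):
        n_loc = 50
        parent = Individual(
            Haplotype.wild_type(n_loc, OUTCROSSER),
            Haplotype.wild_type(n_loc, OUTCROSSER),
            registry,
        )
        params = _params(n_loc=n_loc, mu=0.2)
        g = make_gamete(parent, 0.0, True, params, rng, origin_pop=SELFER, origin_gen=9)
        n_new = int(np.count_nonzero(g.alleles))
        assert n_new > 0
        assert registry.n_mutations == n_new
        frame = registry.to_frame()
        assert set(frame.origin_pop) == {"selfer"}
        assert set(frame.origin_gen) == {9}


class TestChooseParent:
    def test_uniform_when_equal_fitness(self, registry, rng):
        pop = make_population(np.zeros((4, 2, 3), dtype=int), registry)
        counts = np.zeros(4)
        for _ in range(4000):
            counts[choose_parent_index(pop, rng)] += 1
        assert np.all(counts > 0)
        # chi-square-ish sanity: each cell within 5 SD of 1000
        assert np.all(np.abs(counts - 1000) < 5 * np.sqrt(1000 * 0.75))

    def test_selection_ratio_two_to_one(self, registry, rng):
        """w = 1.0 vs 0.5 parents are selected in ratio 2:1."""
        a = registry.register(0.5, OUTCROSSER, 0)  # homozygote fitness 0.5
        alleles = np.zeros((2, 2, 1), dtype=int)
        alleles[1, :, 0] = a
        pop = make_population(alleles, registry)
        n = 15_000
        hits = sum(choose_parent_index(pop, rng) == 0 for _ in range(n))
        p_hat = hits / n
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(p_hat - 2 / 3) < 4 * se

    def test_zero_fitness_never_selected(self, registry, rng):
        lethal = registry.register(1.0, OUTCROSSER, 0)
        alleles = np.zeros((3, 2, 1), dtype=int)
        alleles[0, :, 0] = lethal
        pop = make_population(alleles, registry)
        for _ in range(500):
            assert choose_parent_index(pop, rng) != 0

    def test_all_dead_raises(self, registry, rng):
        lethal = registry.register(1.0, OUTCROSSER, 0)
        alleles = np.full((3, 2, 1), lethal, dtype=int)
        pop = make_population(alleles, registry)
        with pytest.raises(ExtinctionError):
            choose_parent(pop, rng)


class TestReproduceOne:
    def test_sigma_one_selfs_homozygote_identically(self, registry, rng):
        a = registry.register(0.1, OUTCROSSER, 0)
        alleles = np.full((2, 2, 4), a, dtype=int)
        pop = make_population(alleles, registry, sigma=1.0)
        params = _params(n_loc=4)
        child = reproduce_one(pop, 1.0, False, params, rng)
        assert np.all(child.hap1.alleles == a)
        assert np.all(child.hap2.alleles == a)

    def test_selfing_segregation_one_two_one(self, registry, rng):
        """Selfing a single-locus heterozygote gives 1:2:1 genotypes."""
        a = registry.register(1e-9, OUTCROSSER, 0)  # effectively neutral
        alleles = np.zeros((2, 2, 1), dtype=int)
        alleles[:, 1, 0] = a
        pop = make_population(alleles, registry, sigma=1.0)
        params = _params(n_pop=2, n_loc=1)
        n = 10_000
        counts = {0: 0, 1: 0, 2: 0}
        for _ in range(n):
            child = reproduce_one(pop, 1.0, False, params, rng)
            k = int(child.hap1.alleles[0] != 0) + int(child.hap2.alleles[0] != 0)
            counts[k] += 1
        for k, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) < 4 * se

    def test_outcross_parents_distinct(self, registry, rng):
        """sigma = 0 offspring of two distinguishable parents are always hybrid."""
        ids = registry.register_batch(np.full(2, 1e-9), OUTCROSSER, 0)
        alleles = np.zeros((2, 2, 1), dtype=int)
        alleles[0, :, 0] = ids[0]
        alleles[1, :, 0] = ids[1]
        pop = make_population(alleles, registry, sigma=0.0)
        params = _params(n_pop=2, n_loc=1)
        for _ in range(100):
            child = reproduce_one(pop, 0.0, False, params, rng)
            pair = {int(child.hap1.alleles[0]), int(child.hap2.alleles[0])}
            assert pair == {int(ids[0]), int(ids[1])}


class TestNextGeneration:
    def test_population_size_constant(self, registry, rng):
        pop = make_population(np.zeros((15, 2, 5), dtype=int), registry, sigma=0.3)
        params = _params(n_pop=15, n_loc=5, mu=1e-3)
        for _ in range(5):
            pop = next_generation(pop, True, params, rng)
            assert pop.n_pop == 15

    def test_fixed_population_unchanged(self, registry, rng):
        """A population fixed for one allele stays identical without mutation."""
        a = registry.register(0.1, OUTCROSSER, 0)
        alleles = np.full((10, 2, 3), a, dtype=int)
        pop = make_population(alleles, registry, sigma=0.5)
        params = _params(n_pop=10, n_loc=3, r=0.2)
        nxt = next_generation(pop, False, params, rng)
        assert np.all(nxt.alleles == a)

    def test_heterozygosity_halves_under_full_selfing(self, registry, rng):
        """Classic selfing recursion: E[H_{t+1}] = H_t / 2 for neutral loci."""
        n_pop, n_rep = 30, 200
        params = _params(n_pop=n_pop, n_loc=1)
        ratios = []
        for i in range(n_rep):
            reg = AlleleRegistry()
            ids = reg.register_batch(np.full(n_pop, 1e-12), OUTCROSSER, 0)
            alleles = np.zeros((n_pop, 2, 1), dtype=int)
            alleles[:, 1, 0] = ids
            pop = make_population(alleles, reg, sigma=1.0, label="selfer")
            h0 = observed_heterozygosity(pop)
            nxt = next_generation(pop, False, params, rng)
            ratios.append(observed_heterozygosity(nxt) / h0)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(n_rep)
        assert abs(mean - 0.5) < 4 * se
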