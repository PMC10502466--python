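"""Genetic architecture and fitness arithmetic.

The model follows a chromosome of ``n_loc`` equally spaced loci under an
infinite-allele scheme: every new deleterious mutation is a globally unique
allele with its own selection coefficient *s*, drawn from an exponential
distribution of mean ``1/lambda_``, and a dominance coefficient *h* that is a
deterministic, negative-exponential function of *s*,

    h(s) = exp(-alpha * s) / 2 .

With the default shape parameter ``alpha = 7`` a mildly deleterious mutation
(s = 0.1) has h ~ 0.25, weak mutations approach codominance (h -> 0.5) and
strong mutations are nearly recessive, so the whole selective process is
governed by the single distribution of selection coefficients.

Fitness is multiplicative over loci with no epistasis.  At a locus carrying
allele copies *a* and *b*:

* identical-by-descent (``a == b``, which with unique allele ids is the same
  as identity-by-state): contribution ``1 - s``;
* heterozygous: contribution ``(1 - h_a s_a)(1 - h_b s_b)``.

Allele id 0 is the ancestral wild type (s = 0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OUTCROSSER",
    "SELFER",
    "HYBRID",
    "WILD_TYPE",
    "POPULATION_LABELS",
    "ExtinctionError",
    "ConfigurationError",
    "SimulationParams",
    "AlleleRegistry",
    "Haplotype",
    "Individual",
    "Population",
    "dominance_of",
    "draw_mutation_effect",
    "locus_fitness",
    "individual_fitness",
    "population_fitness",
]

# Ancestry / origin tags (int8 codes used in the array representation).
OUTCROSSER = 0
SELFER = 1
HYBRID = 2
POPULATION_LABELS = {OUTCROSSER: "outcrosser", SELFER: "selfer", HYBRID: "hybrid"}
LABEL_CODES = {v: k for k, v in POPULATION_LABELS.items()}

#: Allele id of the ancestral (mutation-free) state.
WILD_TYPE = 0

#: Storage dtype for allele-id arrays (ids stay far below 2**31 in practice).
ALLELE_DTYPE = np.int32


class ExtinctionError(RuntimeError):
    """Raised when every individual in a population has fitness zero."""


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent simulation parameters."""


_PROBABILITIES = (
    "r",
    "mu",
    "sigma_o",
    "sigma_s",
    "sigma_h",
)


@dataclass(frozen=True)
class SimulationParams:
    """Complete parameterisation of one simulation experiment.

    Parameters
    ----------
    n_pop
        Number of diploid individuals per population (all three populations
        share the same size).
    n_loc
        Number of selected loci on the single chromosome.
    r
        Recombination probability per adjacent-locus interval per meiosis.
    mu
        Mutation probability per locus per chromosome per generation.
    lambda_
        Rate parameter of the exponential distribution of selection
        coefficients; the mean effect of a new mutation is ``1 / lambda_``.
    alpha
        Shape of the dominance-selection relationship ``h = exp(-alpha s)/2``.
    sigma_o, sigma_s, sigma_h
        Selfing probabilities of the outcrossing, selfing and hybrid
        populations.
    t1
        Generations of independent (divergence/burn-in) evolution of the two
        parental populations before hybridization.
    t_post
        Generations of hybrid evolution after the founding event (mutation
        is switched off during this phase).
    n_replicates
        Number of independent replicate simulations.
    seed
        Root seed; each replicate receives an independent spawned substream.
    record_every
        Sampling stride (in generations) of the recorded time series.
    """

    n_pop: int = 500
    n_loc: int = 100
    r: float = 1e-6
    mu: float = 1e-5
    lambda_: float = 10.0
    alpha: float = 7.0
    sigma_o: float = 0.0
    sigma_s: float = 1.0
    sigma_h: float = 0.0
    t1: int = 10_000
    t_post: int = 20_000
    n_replicates: int = 100
    seed: int = 0
    record_every: int = 100

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ConfigurationError("n_pop must be at least 2")
        if self.n_loc < 1:
            raise ConfigurationError("n_loc must be at least 1")
        for name in _PROBABILITIES:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(
                    f"{name} must be a probability in [0, 1], got {value!r}"
                )
        if not self.lambda_ > 0:
            raise ConfigurationError("lambda_ must be positive")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be non-negative")
        for name in ("t1", "t_post"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if self.record_every < 1:
            raise ConfigurationError("record_every must be at least 1")

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def dominance_of(s, alpha):
    """Dominance coefficient ``h = exp(-alpha * s) / 2``.

    Strictly decreasing in *s* for ``alpha > 0``; equals the codominant value
    0.5 at ``s = 0`` and stays strictly positive (long-tailed recessivity for
    strongly deleterious mutations).  Accepts scalars or arrays.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise ValueError("selection coefficient s must lie in [0, 1]")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    h = np.exp(-alpha * s_arr) / 2.0
    return float(h) if np.isscalar(s) or s_arr.ndim == 0 else h


def draw_mutation_effect(rng: np.random.Generator, lambda_: float, size=None):
    """Draw selection coefficients from Exponential(mean ``1/lambda_``).

    Raw draws above 1 are clamped to 1 (a homozygote would then have fitness
    exactly 0, i.e. a recessive lethal); at ``lambda_ = 10`` this affects a
    fraction ``exp(-10) ~ 4.5e-5`` of draws.  Values are strictly positive.
    """
    if not lambda_ > 0:
        raise ValueError("lambda_ must be positive")
    s = rng.exponential(scale=1.0 / lambda_, size=size)
    s = np.minimum(s, 1.0)
    # rng.exponential can in principle return exactly 0.0; keep s > 0.
    s = np.maximum(s, np.finfo(float).tiny)
    return float(s) if size is None else s


class AlleleRegistry:
    """Global table of every mutation that ever arose in one replicate.

    Implements the infinite-allele model: each registered mutation gets a
    fresh positive integer id, so identity of ids is identity by descent.
    Id 0 is reserved for the wild type (s = 0; its stored h = 0.5 is the
    codominance limit and never enters any fitness product because s = 0).
    """

    _GROW = 1024

    def __init__(self, alpha: float = 7.0) -> None:
        self.alpha = float(alpha)
        self._s = np.zeros(self._GROW, dtype=float)
        self._h = np.zeros(self._GROW, dtype=float)
        self._origin = np.zeros(self._GROW, dtype=np.int8)
        self._gen = np.zeros(self._GROW, dtype=np.int64)
        self._h[0] = 0.5
        self._n = 1  # wild type pre-registered

    def __len__(self) -> int:
        return self._n

    @property
    def n_mutations(self) -> int:
        """Number of registered mutations (excluding the wild type)."""
        return self._n - 1

    def _ensure_capacity(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._s.shape[0]:
            return
        cap = max(need, 2 * self._s.shape[0])
        for name in ("_s", "_h", "_origin", "_gen"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            new[: self._n] = old[: self._n]
            setattr(self, name, new)

    def register(self, s: float, origin_pop: int, origin_gen: int) -> int:
        """Register one allele and return its fresh id."""
        return int(self.register_batch(np.array([s]), origin_pop, origin_gen)[0])

    def register_batch(self, s, origin_pop: int, origin_gen: int) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("selection coefficients must lie in [0, 1]")
        k = s.shape[0]
        self._ensure_capacity(k)
        lo, hi = self._n, self._n + k
        self._s[lo:hi] = s
        self._h[lo:hi] = dominance_of(s, self.alpha)
        self._origin[lo:hi] = origin_pop
        self._gen[lo:hi] = origin_gen
        self._n = hi
        return np.arange(lo, hi, dtype=np.int64)

    def _check_ids(self, ids) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        if np.any(ids < 0) or np.any(ids >= self._n):
            bad = ids[(ids < 0) | (ids >= self._n)]
            raise KeyError(f"unregistered allele id(s): {bad.tolist()[:5]}")
        return ids

    def s_of(self, ids):
        return self._s[self._check_ids(ids)]

    def h_of(self, ids):
        return self._h[self._check_ids(ids)]

    @property
    def s_table(self) -> np.ndarray:
        """Selection coefficients indexed by allele id (read-only view)."""
        view = self._s[: self._n]
        view.flags.writeable = False
        return view

    @property
    def h_table(self) -> np.ndarray:
        view = self._h[: self._n]
        view.flags.writeable = False
        return view

    def to_frame(self) -> pd.DataFrame:
        """Export all mutations as a table (wild type excluded)."""
        n = self._n
        return pd.DataFrame(
            {
                "allele_id": np.arange(1, n, dtype=np.int64),
                "s": self._s[1:n],
                "h": self._h[1:n],
                "origin_pop": [
                    POPULATION_LABELS[int(o)] for o in self._origin[1:n]
                ],
                "origin_gen": self._gen[1:n],
            }
        )


def locus_fitness(allele_a: int, allele_b: int, registry: AlleleRegistry) -> float:
    """Fitness contribution of one locus.

    Identical ids (identity by descent, including wild type/wild type)
    contribute ``1 - s``; heterozygous pairs contribute
    ``(1 - h_a s_a)(1 - h_b s_b)``.
    """
    a = int(allele_a)
    b = int(allele_b)
    if a == b:
        return float(1.0 - registry.s_of(a))
    sa, sb = registry.s_of(a), registry.s_of(b)
    ha, hb = registry.h_of(a), registry.h_of(b)
    return float((1.0 - ha * sa) * (1.0 - hb * sb))


def population_fitness(alleles: np.ndarray, registry: AlleleRegistry) -> np.ndarray:
    """Multiplicative fitness of every individual in an (N, 2, L) allele array.

    Computed sparsely: only non-wild-type allele copies contribute factors,
    so the cost scales with the number of segregating mutation copies rather
    than with N x L.  Products are accumulated in log space; a recessive
    lethal homozygote (s = 1) yields fitness exactly 0.
    """
    n, _, n_loc = alleles.shape
    idx_i, idx_c, idx_j = np.nonzero(alleles)
    w = np.ones(n, dtype=float)
    if idx_i.size == 0:
        return w
    ids = alleles[idx_i, idx_c, idx_j]
    s = registry.s_table[ids]
    h = registry.h_table[ids]
    with np.errstate(divide="ignore"):
        log_het = np.log1p(-h * s)  # per-copy heterozygous-style factor
    log_w = np.bincount(idx_i, weights=log_het, minlength=n)
    # Correct loci where the two copies are identical by descent:
    # replace (1 - h s)^2 by (1 - s).  Detected sparsely: a locus is
    # homozygous mutant iff both copies appear in the nonzero list at the
    # same (individual, locus) key with equal ids.
    key = idx_i.astype(np.int64) * n_loc + idx_j
    first = idx_c == 0
    _, pos0, pos1 = np.intersect1d(
        key[first], key[~first], assume_unique=True, return_indices=True
    )
    if pos0.size:
        ids0 = ids[first][pos0]
        ids1 = ids[~first][pos1]
        same = ids0 == ids1
        if np.any(same):
            ids_hom = ids0[same]
            i_hom = idx_i[first][pos0][same]
            s_hom = registry.s_table[ids_hom]
            h_hom = registry.h_table[ids_hom]
            with np.errstate(divide="ignore"):
                corr = np.log1p(-s_hom) - 2.0 * np.log1p(-h_hom * s_hom)
            log_w += np.bincount(i_hom, weights=corr, minlength=n)
    return np.exp(log_w)


@dataclass
class Haplotype:
    """One chromosome: per-locus allele ids and parental ancestry tags."""

    alleles: np.ndarray  # (L,) int64, 0 = wild type
    ancestry: np.ndarray  # (L,) int8, OUTCROSSER or SELFER

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=ALLELE_DTYPE)
        self.ancestry = np.asarray(self.ancestry, dtype=np.int8)
        if self.alleles.shape != self.ancestry.shape or self.alleles.ndim != 1:
            raise ValueError("alleles and ancestry must be equal-length vectors")

    def copy(self) -> "Haplotype":
        return Haplotype(self.alleles.copy(), self.ancestry.copy())

    @classmethod
    def wild_type(cls, n_loc: int, ancestry_tag: int) -> "Haplotype":
        return cls(
            np.zeros(n_loc, dtype=ALLELE_DTYPE),
            np.full(n_loc, ancestry_tag, dtype=np.int8),
        )


@dataclass
class Individual:
    """A diploid individual; fitness is cached at construction time."""

    hap1: Haplotype
    hap2: Haplotype
    registry: AlleleRegistry
    fitness: float = field(init=False)

    def __post_init__(self) -> None:
        if self.hap1.alleles.shape != self.hap2.alleles.shape:
            raise ValueError("haplotypes must have equal length")
        self.fitness = individual_fitness(self)

    @property
    def allele_array(self) -> np.ndarray:
        return np.stack([self.hap1.alleles, self.hap2.alleles])[np.newaxis]


def individual_fitness(ind: Individual) -> float:
    """Multiplicative fitness over loci (1 iff mutation-free)."""
    return float(population_fitness(ind.allele_array, ind.registry)[0])


class Population:
    """Fixed-size generation of diploid individuals, stored as arrays.

    ``alleles`` and ``ancestry`` are (n_pop, 2, n_loc) arrays; ``fitness``
    caches every individual's multiplicative fitness.  ``cumulative_fixed``
    counts distinct deleterious alleles that have ever reached frequency 1
    at their locus (a substitution counter; never decremented).
    """

    def __init__(
        self,
        alleles: np.ndarray,
        ancestry: np.ndarray,
        sigma: float,
        label: str,
        registry: AlleleRegistry,
        fitness: np.ndarray | None = None,
    ) -> None:
        alleles = np.asarray(alleles, dtype=ALLELE_DTYPE)
        ancestry = np.asarray(ancestry, dtype=np.int8)
        if alleles.ndim != 3 or alleles.shape[1] != 2:
            raise ValueError("alleles must have shape (n_pop, 2, n_loc)")
        if ancestry.shape != alleles.shape:
            raise ValueError("ancestry must match alleles in shape")
        if label not in LABEL_CODES:
            raise ValueError(f"unknown population label {label!r}")
        if not 0.0 <= sigma <= 1.0:
            raise ConfigurationError("sigma must be a probability")
        self.alleles = alleles
        self.ancestry = ancestry
        self.sigma = float(sigma)
        self.label = label
        self.registry = registry
        self.fitness = (
            population_fitness(alleles, registry) if fitness is None else fitness
        )
        self.cumulative_fixed = 0
        self._fixed_ids: set[int] = set()

    @property
    def n_pop(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loc(self) -> int:
        return self.alleles.shape[2]

    @property
    def label_code(self) -> int:
        return LABEL_CODES[self.label]

    def member(self, i: int) -> Individual:
        """Materialise individual *i* as an object view (copies the rows)."""
        return Individual(
            Haplotype(self.alleles[i, 0].copy(), self.ancestry[i, 0].copy()),
            Haplotype(self.alleles[i, 1].copy(), self.ancestry[i, 1].copy()),
            self.registry,
        )

    def members(self):
        return (self.member(i) for i in range(self.n_pop))

    def mean_fitness(self) -> float:
        return float(self.fitness.mean())

    @classmethod
    def wild_type(
        cls,
        n_pop: int,
        n_loc: int,
        sigma: float,
        label: str,
        registry: AlleleRegistry,
    ) -> "Population":
        tag = LABEL_CODES[label]
        shape = (n_pop, 2, n_loc)
        return cls(
            np.zeros(shape, dtype=ALLELE_DTYPE),
            np.full(shape, tag, dtype=np.int8),
            sigma,
            label,
            registry,
            fitness=np.ones(n_pop, dtype=float),
        )

    @classmethod
    def from_individuals(
        cls, individuals, sigma: float, label: str, registry: AlleleRegistry
    ) -> "Population":
        alleles = np.stack(
            [np.stack([ind.hap1.alleles, ind.hap2.alleles]) for ind in individuals]
        )
        ancestry = np.stack(
            [np.stack([ind.hap1.ancestry, ind.hap2.ancestry]) for ind in individuals]
        )
        return cls(alleles, ancestry, sigma, label, registry)

    def _spawn_like(self, alleles, ancestry, fitness) -> "Population":
        child = Population.__new__(Population)
        child.alleles = alleles
        child.ancestry = ancestry
        child.sigma = self.sigma
        child.label = self.label
        child.registry = self.registry
        child.fitness = fitness
        child.cumulative_fixed = self.cumulative_fixed
        child._fixed_ids = self._fixed_ids  # shared substitution history
        return child
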