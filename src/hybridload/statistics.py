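"""Summary statistics: mean fitness, substitutions, heterozygosity, ancestry.

The substitution counter follows standard forward-simulator semantics: an
allele counts as fixed once it is present in all 2 N copies at its locus,
and it stays counted even if a later mutation overwrites one of its copies.
Heterozygosity is identity-based (fraction of individual-locus pairs whose
two allele ids differ), matching the identity-by-descent dichotomy of the
fitness model.  The selfing-ancestry fraction of a hybrid population is the
fraction of all 2 N L locus copies whose ancestry tag points to the selfing
parental population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import SELFER, WILD_TYPE, Population, SimulationParams

__all__ = [
    "ReplicateSummary",
    "mean_fitness",
    "update_fixed_count",
    "observed_heterozygosity",
    "selfing_ancestry_fraction",
    "genomic_mutation_rate",
    "ancestry_histogram",
]

SERIES_COLUMNS = [
    "generation",
    "population",
    "mean_fitness",
    "cumulative_fixed",
    "heterozygosity",
]


@dataclass
class ReplicateSummary:
    """Recorded trajectory and final state of one replicate simulation."""

    replicate_id: int
    series: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SERIES_COLUMNS))
    final_ancestry: float | None = None
    termination: str = "completed"


def mean_fitness(pop: Population) -> float:
    """Arithmetic mean of cached individual fitnesses."""
    return float(pop.fitness.mean())


def update_fixed_count(pop: Population) -> int:
    """Update and return the cumulative count of distinct fixed alleles.

    A deleterious allele is fixed when every one of the 2 N copies at its
    locus carries its id.  Each distinct allele is counted at most once,
    ever (cumulative substitution semantics).
    """
    lo = pop.alleles.min(axis=(0, 1))
    hi = pop.alleles.max(axis=(0, 1))
    fixed_ids = lo[(lo == hi) & (lo != WILD_TYPE)]
    for allele_id in fixed_ids:
        aid = int(allele_id)
        if aid not in pop._fixed_ids:
            pop._fixed_ids.add(aid)
            pop.cumulative_fixed += 1
    return pop.cumulative_fixed


def observed_heterozygosity(pop: Population) -> float:
    """Fraction of (individual, locus) pairs with two non-identical ids."""
    return float(np.mean(pop.alleles[:, 0, :] != pop.alleles[:, 1, :]))


def selfing_ancestry_fraction(pop: Population) -> float:
    """Fraction of all locus copies tagged with selfing-parent ancestry.

    Only meaningful for hybrid populations, where each locus copy descends
    from exactly one of the two parental populations.
    """
    if pop.label != "hybrid":
        raise ValueError(
            "selfing_ancestry_fraction is defined for hybrid populations only; "
            f"got a population labelled {pop.label!r}"
        )
    return float(np.mean(pop.ancestry == SELFER))


def genomic_mutation_rate(params: SimulationParams) -> float:
    """Expected new mutations per diploid offspring, 2 * n_loc * mu."""
    return 2.0 * params.n_loc * params.mu


def ancestry_histogram(
    fractions, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of final ancestry fractions over [0, 1].

    Bins are half-open ``[k w, (k+1) w)`` with the last bin closed at 1, so
    counts always sum to the number of replicates.  Returns (counts, edges).
    """
    values = np.asarray(list(fractions), dtype=float)
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError("ancestry fractions must lie in [0, 1]")
    if not 0.0 < bin_width <= 1.0:
        raise ValueError("bin_width must lie in (0, 1]")
    edges = np.arange(0.0, 1.0, bin_width)
    edges = np.append(edges, 1.0)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges
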