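"""Three-population experiment driver.

One replicate consists of (1) a burn-in of ``t1`` generations during which a
purely outcrossing and a (predominantly) self-fertilizing population of
equal size evolve independently under mutation, selection, recombination and
drift; (2) a hybridization event in which a third population of the same
size is founded, each founder receiving one recombinant gamete from a
uniformly drawn parent of each parental population; and (3) ``t_post``
generations of hybrid evolution with mutation switched off and no further
gene flow, after which the genome-wide selfing-ancestry fraction summarises
which parental genome prevailed.

Named presets reproduce the published mutation/recombination regimes:
``scenario-I`` (low mutation, low recombination), ``scenario-II`` (high
mutation, low recombination) and ``scenario-III`` (high mutation, high
recombination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import (
    AlleleRegistry,
    ExtinctionError,
    Population,
    SimulationParams,
)
from .life_cycle import _gamete_batch, next_generation
from .statistics import (
    ReplicateSummary,
    SERIES_COLUMNS,
    mean_fitness,
    observed_heterozygosity,
    selfing_ancestry_fraction,
    update_fixed_count,
)

__all__ = [
    "PRESETS",
    "apply_preset",
    "init_population",
    "run_burn_in",
    "hybridize",
    "run_post_hybrid",
    "run_replicate",
    "run_replicates",
    "ExperimentResult",
]

#: Mutation/recombination regimes of the three published scenarios.
PRESETS: dict[str, dict[str, float]] = {
    "scenario-I": {"mu": 1e-5, "r": 1e-6},
    "scenario-II": {"mu": 5e-4, "r": 1e-6},
    "scenario-III": {"mu": 5e-4, "r": 1e-1},
}


def apply_preset(params: SimulationParams, name: str) -> SimulationParams:
    if name not in PRESETS:
        known = ", ".join(sorted(PRESETS))
        raise ValueError(f"unknown preset {name!r}; known presets: {known}")
    return params.replace(**PRESETS[name])


def init_population(
    params: SimulationParams, sigma: float, label: str, registry: AlleleRegistry
) -> Population:
    """Mutation-free starting population; every ancestry tag is its own label."""
    return Population.wild_type(params.n_pop, params.n_loc, sigma, label, registry)


def _record(series: list, generation: int, pop: Population) -> None:
    series.append(
        (
            generation,
            pop.label,
            mean_fitness(pop),
            pop.cumulative_fixed,
            observed_heterozygosity(pop),
        )
    )


def _series_frame(series: list) -> pd.DataFrame:
    return pd.DataFrame(series, columns=SERIES_COLUMNS)


def run_burn_in(
    params: SimulationParams, rng: np.random.Generator, registry: AlleleRegistry
) -> tuple[Population, Population, list]:
    """Evolve both parental populations independently for ``t1`` generations.

    Mutation is on; new mutations are tagged with the population they arise
    in.  Returns the two final populations and the recorded time series.
    """
    pop_out = init_population(params, params.sigma_o, "outcrosser", registry)
    pop_self = init_population(params, params.sigma_s, "selfer", registry)
    series: list = []
    _record(series, 0, pop_out)
    _record(series, 0, pop_self)
    for gen in range(1, params.t1 + 1):
        pop_out = next_generation(pop_out, True, params, rng, origin_gen=gen)
        pop_self = next_generation(pop_self, True, params, rng, origin_gen=gen)
        update_fixed_count(pop_out)
        update_fixed_count(pop_self)
        if gen % params.record_every == 0 or gen == params.t1:
            _record(series, gen, pop_out)
            _record(series, gen, pop_self)
    return pop_out, pop_self, series


def hybridize(
    pop_out: Population,
    pop_self: Population,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Population:
    """Found the hybrid population.

    Every founder receives one recombinant meiotic gamete (mutation off)
    from a uniformly drawn outcrossing parent and one from a uniformly drawn
    selfing parent, so each founder carries one chromosome of each parental
    ancestry and the population-wide selfing-ancestry fraction is exactly
    0.5.
    """
    n = params.n_pop
    idx_o = rng.integers(0, pop_out.n_pop, size=n).astype(np.intp)
    idx_s = rng.integers(0, pop_self.n_pop, size=n).astype(np.intp)
    gam_o, tag_o = _gamete_batch(pop_out.alleles, pop_out.ancestry, idx_o, params.r, rng)
    gam_s, tag_s = _gamete_batch(pop_self.alleles, pop_self.ancestry, idx_s, params.r, rng)
    alleles = np.stack([gam_o, gam_s], axis=1)
    ancestry = np.stack([tag_o, tag_s], axis=1)
    return Population(alleles, ancestry, params.sigma_h, "hybrid", pop_out.registry)


def run_post_hybrid(
    hybrid: Population,
    params: SimulationParams,
    rng: np.random.Generator,
    stop_when_ancestry_fixed: bool = False,
) -> tuple[list, float]:
    """Evolve the hybrid for ``t_post`` generations without mutation.

    Returns the recorded time series and the final genome-wide
    selfing-ancestry fraction.  With ``stop_when_ancestry_fixed`` the loop
    ends as soon as every ancestry tag is identical: no later event can then
    change the final ancestry fraction (there is no mutation and no gene
    flow), so the returned value is exact while the series simply ends
    early.
    """
    series: list = []
    t0 = params.t1
    _record(series, t0, hybrid)
    for gen in range(1, params.t_post + 1):
        hybrid = next_generation(hybrid, False, params, rng)
        update_fixed_count(hybrid)
        if gen % params.record_every == 0 or gen == params.t_post:
            _record(series, t0 + gen, hybrid)
        if stop_when_ancestry_fixed:
            frac = selfing_ancestry_fraction(hybrid)
            if frac == 0.0 or frac == 1.0:
                if series[-1][0] != t0 + gen:
                    _record(series, t0 + gen, hybrid)
                break
    return series, selfing_ancestry_fraction(hybrid)


def run_replicate(
    params: SimulationParams,
    rng: np.random.Generator,
    replicate_id: int = 0,
    stop_when_ancestry_fixed: bool = False,
) -> tuple[ReplicateSummary, AlleleRegistry]:
    """One full burn-in / hybridization / post-hybridization run."""
    registry = AlleleRegistry(alpha=params.alpha)
    try:
        pop_out, pop_self, series = run_burn_in(params, rng, registry)
        hybrid = hybridize(pop_out, pop_self, params, rng)
        post_series, final = run_post_hybrid(
            hybrid, params, rng, stop_when_ancestry_fixed=stop_when_ancestry_fixed
        )
    except ExtinctionError:
        return (
            ReplicateSummary(
                replicate_id,
                _series_frame([]),
                final_ancestry=None,
                termination="extinct",
            ),
            registry,
        )
    summary = ReplicateSummary(
        replicate_id,
        _series_frame(series + post_series),
        final_ancestry=final,
        termination="completed",
    )
    return summary, registry


@dataclass
class ExperimentResult:
    """Replicate summaries plus across-replicate aggregates."""

    params: SimulationParams
    summaries: list[ReplicateSummary]
    aggregates: pd.DataFrame
    first_registry: AlleleRegistry | None = None
    replicate_seeds: list = field(default_factory=list)

    @property
    def final_ancestries(self) -> np.ndarray:
        return np.array(
            [
                s.final_ancestry
                for s in self.summaries
                if s.final_ancestry is not None
            ],
            dtype=float,
        )

    @property
    def n_extinct(self) -> int:
        return sum(1 for s in self.summaries if s.termination == "extinct")


def _aggregate(summaries: list[ReplicateSummary]) -> pd.DataFrame:
    frames = [s.series for s in summaries if len(s.series)]
    if not frames:
        return pd.DataFrame(
            columns=["generation", "population"]
            + [f"{c}_{a}" for c in SERIES_COLUMNS[2:] for a in ("mean", "sd")]
        )
    stacked = pd.concat(frames, ignore_index=True)
    grouped = stacked.groupby(["generation", "population"], sort=True)[
        SERIES_COLUMNS[2:]
    ].agg(["mean", "std"])
    grouped.columns = [
        f"{col}_{'sd' if agg == 'std' else agg}" for col, agg in grouped.columns
    ]
    return grouped.reset_index()


def run_replicates(
    params: SimulationParams,
    stop_when_ancestry_fixed: bool = False,
    progress_callback=None,
) -> ExperimentResult:
    """Run the full experiment ``n_replicates`` times.

    Each replicate uses an independent substream spawned from the root seed,
    so the whole experiment is a pure function of ``params``.  Replicates
    that go extinct are recorded as such and excluded from the ancestry
    vector; per-time-point mean and standard deviation of every recorded
    statistic are aggregated over the completed replicates.
    """
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_replicates)
    summaries: list[ReplicateSummary] = []
    first_registry: AlleleRegistry | None = None
    for rep, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        summary, registry = run_replicate(
            params, rng, replicate_id=rep, stop_when_ancestry_fixed=stop_when_ancestry_fixed
        )
        if rep == 0:
            first_registry = registry
        summaries.append(summary)
        if progress_callback is not None:
            progress_callback(rep, summary)
    return ExperimentResult(
        params=params,
        summaries=summaries,
        aggregates=_aggregate(summaries),
        first_registry=first_registry,
        # spawn keys: replicate i uses SeedSequence(seed).spawn()[i]
        replicate_seeds=[list(child.spawn_key) for child in children],
    )
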