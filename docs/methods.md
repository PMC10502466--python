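# Methods

## Model

`hybridload` is a forward-time, individual-based Wright–Fisher simulator for
diploid, hermaphroditic populations with partial self-fertilization. Its
purpose is to study how deleterious-mutation load accumulates differently in
selfing and outcrossing populations — through the interplay of selective
interference, homozygosity and purging — and which parental genome prevails
in a hybrid population founded from one chromosome of each.

### Genome and mutation

Each individual carries two homologous chromosomes of `n_loc` equally spaced
loci. Mutation follows the infinite-allele model: each new mutation is a
globally unique allele with its own selection coefficient *s*, drawn from an
exponential distribution with mean 1/λ and clamped to (0, 1] (draws above 1,
a fraction e^{-λ} of them, become recessive lethals with homozygote fitness
exactly 0). A mutation landing on an occupied locus replaces the resident
allele on that chromosome: the infinite-allele description concerns allelic
state, and replacement keeps exactly one allele per locus per chromosome.

Dominance is a deterministic function of the selection coefficient,

    h(s) = exp(-α s) / 2 ,

so weak mutations approach codominance (h → 0.5), strong mutations are
nearly — but never completely — recessive, and the whole selective process
is governed by the single distribution of selection coefficients. At the
default α = 7, a mildly deleterious mutation (s = 0.1) has h ≈ 0.25, in line
with empirical estimates for such mutations.

### Fitness

Fitness is multiplicative across loci with no epistasis. A locus with
allele copies *a*, *b* contributes 1 − s if the copies are identical by
descent (with unique allele ids, identity of ids), and
(1 − h_a s_a)(1 − h_b s_b) otherwise. Fitness is computed once at birth and
cached; individuals are immutable between generations.

### Life cycle

Generations are non-overlapping and of fixed size `n_pop`. Each offspring is
produced independently: with probability σ it is selfed (one selected parent
contributes two *independent* meiotic gametes — two distinct meioses, which
is what distinguishes selfing from clonality); otherwise two *distinct*
selected parents contribute one gamete each. Requiring distinct outcross
parents avoids injecting residual selfing at rate 1/N.

Parent selection is fitness-proportional. The single-draw operation
(`choose_parent`) implements the literal rejection scheme — draw an index
uniformly, accept with probability equal to its fitness — while the
whole-generation path samples parents by inversion on the cumulative fitness
vector, which has an identical marginal distribution and vectorises.

Meiosis starts from a uniformly chosen homolog and switches the active
homolog independently with probability *r* in each of the `n_loc − 1`
adjacent intervals (no interference, no obligate crossover, multiple
crossovers allowed). Ancestry tags travel with the copied alleles, so a
gamete's tag at a locus always identifies the parental population that
contributed that copy.

### Experiment

One replicate runs three phases:

1. **Burn-in** (`t1` generations): a purely outcrossing population
   (σ_o = 0) and a selfing population (σ_s = 1 by default) evolve
   independently from a mutation-free state with mutation on. New mutations
   are tagged with the population they arise in.
2. **Hybridization**: a third population of the same size is founded; each
   founder receives one recombinant gamete from a uniformly drawn parent of
   each parental population (founding draws are not fitness-weighted —
   selection acts before and after, not at the founding event). Every
   founder therefore carries one chromosome of each ancestry and the
   genome-wide selfing-ancestry fraction is exactly 0.5.
3. **Post-hybridization** (`t_post` generations): the hybrid evolves at
   selfing rate σ_h with mutation off and no gene flow. The final
   selfing-ancestry fraction (fraction of all 2·N·L locus copies tagged
   with selfing-parent ancestry) summarises which parental genome prevailed.

Starting the parental populations mutation-free (no standing variation) is a
deliberate choice: the burn-in itself generates the load whose consequences
are under study, and `t1` is then interpretable as divergence time from a
common, load-free ancestor.

## Parameters

| symbol | field | default | meaning |
|--------|-------|---------|---------|
| N_pop  | `n_pop` | 500 | diploid individuals per population |
| N_loc  | `n_loc` | 100 | selected loci per chromosome |
| r      | `r` | 1e-6 | recombination probability per adjacent interval per meiosis |
| μ      | `mu` | 1e-5 | mutation probability per locus per chromosome per generation |
| λ      | `lambda_` | 10 | DFE rate parameter; mean effect 1/λ = 0.1 |
| α      | `alpha` | 7 | dominance-decay shape |
| σ_o    | `sigma_o` | 0 | selfing rate, outcrossing population |
| σ_s    | `sigma_s` | 1 | selfing rate, selfing population |
| σ_h    | `sigma_h` | 0 | selfing rate, hybrid population |
| t₁     | `t1` | 10000 | divergence generations before hybridization |
| —      | `t_post` | 20000 | hybrid generations after founding |
| —      | `n_replicates` | 100 | independent replicates |
| —      | `record_every` | 100 | time-series sampling stride |

The `mu`/`r` defaults are the low-mutation, low-recombination baseline
(preset `scenario-I`); `scenario-II` raises the genomic mutation rate
2·N_loc·μ from 0.002 to 0.1 (μ = 5e-4), and `scenario-III` additionally
raises recombination to r = 0.1. σ_h defaults to 0 (an outcrossing hybrid).

## Statistics

* **Mean fitness** — arithmetic mean of cached individual fitnesses.
* **Cumulative fixed deleterious mutations** — a substitution counter: an
  allele counts once it has ever occupied all 2N copies at its locus, and
  stays counted if later overwritten by new mutation. Checked every
  generation, so no substitution is missed between recording points.
* **Observed heterozygosity** — fraction of (individual, locus) pairs whose
  two allele ids differ. This identity-based definition matches the
  identity-by-descent dichotomy of the fitness model; it is not the
  frequency-based expected heterozygosity.
* **Selfing-ancestry fraction** — fraction of all locus copies tagged with
  selfing-parent ancestry; defined only for hybrid populations.
* **Ancestry histogram** — half-open bins [k·w, (k+1)·w) with the last bin
  closed at 1 (default width 0.05), so counts always sum to the number of
  replicates.

## Reproducibility and numerics

The whole experiment is a pure function of the parameter set: the root seed
spawns one independent PCG64 substream per replicate
(`SeedSequence(seed).spawn(i)`), replicate spawn keys are written to the run
manifest, and identical parameter sets give byte-identical TSV outputs.

Fitness products are accumulated in log space over the sparse set of
non-wild-type allele copies; a recessive lethal homozygote yields fitness
exactly 0, and a mutation-free individual exactly 1. Allele ids are stored
as 32-bit integers (ids stay far below 2³¹ even in the high-mutation
regime). Rare-event sampling (crossovers at r = 1e-6, mutations at small μ)
draws a binomial event count and then uniform positions, switching to dense
Bernoulli masks when the expected event count per generation is large; both
paths realise independent per-site Bernoulli trials.

`run_post_hybrid` accepts `stop_when_ancestry_fixed`: once every ancestry
tag in the hybrid population is identical, no later event can change the
final ancestry fraction (mutation is off and there is no gene flow), so the
run may stop early with the exact final value; only the recorded time
series is shortened. Long-running checks use this to stay within practical
runtimes.

## Validation oracles

Three independent small-scale results validate the stochastic engine
(`hybridload validate`, `check_engine_against_oracles`):

1. **Haploid reduction.** Under complete selfing with fully homozygous
   founders and no mutation, the model collapses exactly to N haploid
   lineages with lineage fitness 1 − s. The fixation probability of a
   mutant lineage follows from the absorbing Markov chain with
   next-generation count Binomial(N, k(1−s)/(k(1−s)+N−k)), solved by a
   direct linear system — an oracle entirely independent of the simulator.
2. **Neutral selfing laws.** Observed heterozygosity halves per generation
   at σ = 1, and neutral allele-frequency variance after t generations is
   p(1−p)(1−(1−1/2N)^t) at σ = 0.
3. **Equilibrium inbreeding.** The classical neutral equilibrium
   F = σ/(2−σ) is an infinite-population result. For this exact life cycle
   the stationary identity-by-descent recursions solve in closed form
   (`neutral_fis_expectation`); at finite N the expectation is
   1 − 2(1+(1−σ)N)/(1+N(2−σ)) in the low-mutation limit, e.g. 0.786 rather
   than 0.818 at N = 50, σ = 0.9. The simulator is checked tightly against
   the exact finite-N value at N = 50, and against the asymptotic formula
   at N = 1600, where the finite-N departure (~0.002) is below the
   Monte-Carlo resolution of the check. F_IS is estimated by pooling
   observed heterozygosity and small-sample-corrected gene diversity over
   loci and sampling times before taking the ratio; per-locus ratios would
   be biased downward when diversity is low.

Deviations are reported in Monte-Carlo standard errors; any |z| > 4 marks a
validation failure.

## Test scales

The test suite runs the full model at reduced problem sizes, chosen as the
smallest scales at which each claim is statistically decidable:

* Even ancestry split under low mutation/low recombination: N = 500,
  t₁ = 2000, t_post = 5000, 50 replicates.
* Scenario orderings: high-mutation/low-recombination at t₁ = 2000
  (10 replicates; the outcrosser-ahead fixed-count ordering emerges once
  fixation sojourn times ~4N have elapsed) and high-recombination at
  t₁ = 5000 (6 replicates; the selfer's fixation-driven fitness erosion
  needs longer divergence before outcrosser ancestry is favoured on
  average).
* Population-size effect on the fixation rate: fixation events at
  μ = 1e-5 are rare (~1.5e-5 per population-generation at N = 500, with a
  further ~10-fold reduction at N = 5000 from the effectively-neutral
  fraction λ/(2Nh)), so the check accumulates events over ~280,000
  population-generations at N = 500 and compares per-generation rates
  against a shorter N = 5000 exposure, asserting the ordering and a ≥3×
  reduction rather than the full 10×.

What passing these tests shows is that the engine reproduces the model's
internal logic and its qualitative regime structure at reduced scale; it
does not demonstrate quantitative agreement at the full published scale
(t₁ = 10⁴, t_post = 2×10⁴, 100 replicates), which the same code reproduces
by running the presets at their default sizes.

## Known limitations

* Purely deleterious, non-epistatic mutations; no beneficial, compensatory
  or reverse mutations, and dominance is a deterministic function of s.
* No backcrossing or continued gene flow after the founding event; parental
  populations are discarded at hybridization.
* Uniform μ and r along the chromosome; equal sizes and environments for
  all populations; no selfing-rate evolution.
* The hybrid founding event applies meiosis (with recombination) but no
  mutation; mutation stays off for the whole hybrid phase, which keeps the
  final ancestry fraction interpretable but means hybrid evolution sorts
  only standing variation.
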