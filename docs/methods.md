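# Model and methods

`ecotypesim` simulates ecological divergence of a bacterial population
split between two habitat niches that exchange DNA but not cells. It is
a discrete-generation, individual-based (forward-time) Wright–Fisher
model of a haploid population of `N` cells, each carrying `L` locus
slots. The quantity under selection is a single quantitative trait: the
phenotype of a cell is the plain sum of the allele effect sizes at its
present loci. There is no environmental variance, no dominance and no
epistasis; a "locus" may be read as one gene or a tightly linked block
(an operon, integron or plasmid).

## State

The population is a matrix of effect sizes (`N × L`, real-valued) plus
a boolean presence mask of the same shape. An absent slot contributes
exactly zero to the phenotype and is exempt from mutation and
homologous recombination (gene conversion requires homologous tract to
pair with; after loss there is none). Presence is stored explicitly
rather than as a sentinel value so that a genuine zero-effect allele
(possible under the evolving-effects model) remains distinguishable
from an absent gene.

Each individual belongs permanently to subpopulation 1 or 2 after the
split; there is no migration of cells, ever. DNA may cross between
niches only if the gene pool is `global`.

## Fitness

Stabilizing selection follows a Gaussian fitness function

    W(p) = exp( −(p − x)² / (2 σw²) )

where `x` is the niche optimum (+1 and −1 by default) and `σw²` sets
the width (default 2.0; larger is weaker selection). With ten loci of
effect ±0.1, a genotype carrying one allele adapted to the opposite
niche has relative fitness 0.99; if the same total effect is spread
over two loci, 0.78; concentrated in a single locus, 0.37. Divergence
with gene flow therefore depends strongly on how the genetic
architecture distributes the trait across loci.

## Generation cycle

Each generation applies, in order:

1. **Reproduction and selection.** Every cell divides into two
   identical offspring; of the `2n` offspring in each (sub)population,
   exactly `n` survive. Under `selection="neutral"` survivors are a
   uniform random subset. Under `divergent` selection the default
   regime (`survival_model="fitness_weighted"`) draws survivors
   sequentially without replacement with probability proportional to
   `W(p)`; this is implemented with exponential sort keys (take the
   `n` largest values of `log(U)/W`), which is distribution-identical
   to sequential weighted draws and fully vectorized. An alternative
   strong-selection regime (`"fitness_ranked"`) keeps the `n` fittest
   offspring outright, breaking ties uniformly at random (so it reduces
   exactly to neutral drift within a fitness class).
2. **Mutation** at rate `m` per present gene copy. Fixed-effects model:
   the allele flips between `+a` and `−a` (`a = |x₁|/L`, 0.1 by
   default). Evolving-effects model: the effect is perturbed by a
   Gaussian kernel with variance `σm²` (default 4 × 10⁻⁴), creating an
   effectively infinite allele space.
3. **Homologous recombination** (gene conversion) at rate `r` per
   present copy. The resident allele is replaced by a copy drawn
   uniformly (i.e. frequency-weighted) from the pool of all extant
   copies at that locus — across the whole metapopulation (`global`
   pool) or only the recipient's own subpopulation (`local` pool).
   Pools are frozen snapshots taken after the mutation phase, so
   conversion events within a generation are exchangeable and
   order-independent, and a copy may recombine with itself (a no-op).
4. **Gene loss** at rate `λ` per present copy: the slot becomes empty
   and its effect value is discarded.
5. **Gene gain** at rate `γ` per *empty* slot: the slot is refilled
   with a copy drawn from the pool of extant copies of that locus, at
   the same scope as recombination. Donor pools for gain are rebuilt
   after the loss phase, so a locus whose last copy was lost this
   generation is already extinct and cannot donate. A locus extinct in
   scope can never be regained; with a `local` pool, extinction in one
   subpopulation is permanent there even if the other still carries it.

All rates are independent Bernoulli probabilities per copy (or per
empty slot) per generation, which keeps them interpretable and bounded
in [0, 1]. Gain requires loss to be enabled — the model starts from the
maximum locus complement, so there is nothing for gain alone to refill.

## Run protocol

A run starts from a fully homogeneous founder population optimal for
niche 1 (every slot present, every effect `x₁/L`). Phase 1 is a burn-in
(default 1,000 generations) of the undivided metapopulation with
*neutral* reproduction; by default every other configured operator
(mutation, recombination, loss, gain) already runs at its scenario
rate, so the two phases share a single generation loop and differ only
in selection and population structure. `burn_in_processes=
"mutation_only"` restricts the burn-in to mutation instead; with the
default mutation rate either choice randomizes allele frequencies to
~0.5 by the split, but only the full-dynamics burn-in seeds standing
presence/absence variation in gene-loss scenarios. At the split the
population is divided into two fixed halves (rows are exchangeable
after a neutral burn-in, so block assignment is unbiased) and phase 2
runs the full operator set for `run_generations` (default 5,000) with
the niche optima applied.

## Summary statistics

- **Phenotypic divergence**: |mean phenotype of subpopulation 1 − mean
  phenotype of subpopulation 2|.
- **Per-locus divergence `d`**: within each subpopulation only the most
  frequent ("leading") allele at a locus is considered, alleles being
  identified by exact effect value (identity by copying); `d = |a₁ −
  a₂|` is the absolute difference of the two leading effects, with
  summaries `d_max` (largest) and `d_mean` (mean over all `L` loci,
  including extinct ones). In scenarios with gene loss, every absent
  slot counts as a vote for a virtual allele of effect 0, which can
  itself lead a mostly-lost locus. Frequency ties are broken toward the
  smallest effect value — deterministic and platform-stable.
- **Genome content**: mean percentage of slots missing per individual;
  number of extant loci (≥1 copy anywhere); mean copy number per
  surviving locus; and the fraction of loci *private* to one
  subpopulation, defined by near-fixation: presence frequency ≥ 0.95 in
  one subpopulation and ≤ 0.05 in the other. The threshold is a
  parameter; tightening it to 0.99/0.01 can only shrink the private
  set, and tests verify that monotonicity.

## Experiment driver

`build_grid` constructs the factorial design — recombination rate ∈
{0, 0.005, 0.05} × gene pool {global, local} × selection {neutral,
divergent} × genome content {fixed, loss, loss + gain} × effect model —
minus two excluded cells: neutral evolution with gene loss (all loci
simply drift to extinction) and gain without loss. With fixed effects
this yields 24 scenarios. `run_grid` runs each scenario for a fixed
number of replicates with deterministic seeds (`base_seed +
scenario_index × replicates + replicate_index`), so a table is
bit-identical for identical inputs regardless of execution order, and
any single cell can be reproduced in isolation.

## Parameters that matter

| Parameter | Meaning | Default |
|---|---|---|
| `n_total` | metapopulation size N (cells) | 2000 |
| `n_loci` | locus slots L per genome | 10 |
| `mutation_rate` | m, per present copy per generation | 0.005 |
| `recombination_rate` | r, per present copy per generation | 0 / 0.005 / 0.05 |
| `loss_rate` | λ, per present copy per generation | 0 or 10⁻⁴ |
| `gain_rate` | γ, per empty slot per generation | 0 or 10⁻⁴ |
| `sigma2_mutation` | variance of the evolving-effects kernel | 4 × 10⁻⁴ |
| `sigma2_selection` | σw², width of the fitness function | 2.0 |
| `optima` | niche phenotypic optima (x₁, x₂) | (+1, −1) |

`r = 0.005` equals the mutation rate (the border of clonal versus
quasi-sexual dynamics); `r = 0.05` is ten times it, within the upper
range of recombination-to-mutation ratios estimated across bacteria;
`r = 0` is the strictly clonal limit. The loss/gain rate is set fifty
times below the mutation rate, low enough that genome content evolves
on the same timescale as the trait rather than collapsing instantly.

## Calibration of the two survival regimes

The two survival regimes bracket very different selection intensities,
and several headline statistics are sensitive to the choice:

- Under the default `fitness_weighted` regime, stabilizing selection of
  per-allele strength ~0.01 against a per-copy mutation rate of 0.005
  sustains a large segregating load: clonal populations equilibrate at
  a phenotypic divergence of ≈ 1.2 (of a maximal 2.0). Gene flow is a
  strong force in this regime: with a global pool and r = 0.05,
  divergence falls to roughly a third of the clonal value; gene loss
  escalates with recombination and produces loci private to one niche;
  and in the evolving-effects model divergence concentrates into a
  single locus of large effect (`d_max` exceeds half the summed
  divergence). These are the phenomena the package exists to study.
- Under `fitness_ranked`, selection is near-deterministic: clonal
  divergence reaches ≈ 1.98, but gene flow, gene loss and architecture
  concentration are all essentially suppressed (losses never fix;
  divergence stays near-maximal at every recombination rate).

No single intensity reproduces both a near-optimal clonal equilibrium
*and* drift-scale gene-loss fixation: any regime strong enough for the
former (effective per-allele coefficients of order 0.5) removes the
latter. The package therefore ships the weighted regime as the default
and exposes the ranked regime for sensitivity analysis.

## Numerical and design choices

- One `numpy` Generator per replicate, seeded from the scenario seed;
  every stochastic draw flows from it, so runs are exactly reproducible
  and replicates are independent streams.
- Operators with zero rates are skipped without consuming random draws.
- Under the fixed-effects model with no loss, the set of effect values
  provably never leaves {+a, −a} (property-tested).
- Two gene copies are "the same allele" iff their effect values are
  bit-identical; mutation under the evolving model almost surely
  creates a new value, so allele identity tracks descent.
- Degenerate selection weights (all offspring at numerically zero
  fitness) raise an error rather than sampling arbitrarily; this cannot
  occur with the Gaussian fitness function on finite phenotypes.
- Snapshots (NumPy `.npz` with the config embedded as JSON plus a
  hash) allow checkpoint/resume of long runs and feeding saved states
  to the `stats` command.

## What the tests do and do not show

The operator layer is verified against independent oracles: survivor
sampling against brute-force enumeration of sequential weighted draws;
a full generation step on an enumerable four-individual, single-locus
model against its exact transition distribution (chi-squared over 10⁵
sampled steps); mutation and conversion kernels against their stated
moments and pool frequencies; neutrality against the allele-frequency
martingale; and local pools against perfect lineage isolation using
per-copy origin tags. Endpoint checks run the full study design
(N = 2000, 1,000 + 5,000 generations, ten replicates per scenario);
the evolving-effects concentration property is demonstrated at reduced
scale (N = 400, 20,000 post-split generations) because the full
500,000-generation design is far beyond a test suite's budget — the
long-run arm remains available through configuration.

All of this exercises the model under its own assumptions. Passing
tests say nothing about real bacterial populations: genomes here have
ten exchangeable loci, one trait, symmetric niches and constant rates;
real divergence involves many traits, asymmetric selection and gene
flow, linkage, and recombination efficiency that decays with sequence
divergence — all outside this model's scope.

## Known limitations

- No cell migration between niches; selection and gene flow are
  symmetric by construction.
- Homologous recombination converts exactly one locus per event; no
  multi-locus tracts, no dependence of conversion efficiency on
  sequence divergence.
- Haploid, purely additive genetics; no dominance or epistasis.
- The deterministic small-locus companion analysis often used to
  interpret such simulations is not part of the package.
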