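"""Per-generation stochastic operators and their composition into runs.

One generation applies, in order: reproduction with selection/drift,
mutation, homologous recombination (gene conversion against a frozen
allele pool), gene loss, and gene gain.  All event rates are independent
Bernoulli probabilities per extant gene copy (per empty slot for gain).

A full run has two phases: a burn-in of neutral reproduction and
mutation in the undivided metapopulation, then a split into two equal,
permanently separate subpopulations with the full operator set active
and divergent niche optima (under divergent selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import (
    PopulationState,
    ScenarioConfig,
    fitness,
    founder_population,
)
from . import summary_stats

__all__ = [
    "AllelePool",
    "GenerationRecord",
    "weighted_sample_without_replacement",
    "ranked_survival",
    "reproduce_and_select",
    "mutate",
    "build_pools",
    "recombine",
    "lose_genes",
    "gain_genes",
    "step_generation",
    "split_population",
    "run",
    "records_to_frame",
]

log = logging.getLogger(__name__)


class DegenerateWeightsError(RuntimeError):
    """All offspring carry numerically zero fitness; survival is undefined."""


def weighted_sample_without_replacement(rng: np.random.Generator, weights, k: int) -> np.ndarray:
    """Draw ``k`` distinct indices by sequential fitness-weighted sampling.

    Implemented with exponential sort keys (take the ``k`` largest values
    of ``log(U)/w``), which has exactly the distribution of sequential
    weighted draws without replacement.  ``weights`` may be a 1-D array or
    a batch ``(B, n)``; the result is ``(k,)`` or ``(B, k)`` (unordered).
    """
    w = np.asarray(weights, dtype=float)
    if k > w.shape[-1]:
        raise ValueError("cannot sample more survivors than offspring")
    if np.any(np.all(w <= 0.0, axis=-1)):
        raise DegenerateWeightsError("all sampling weights are zero")
    u = rng.random(w.shape)
    with np.errstate(divide="ignore"):
        keys = np.log(u) / w  # -inf where w == 0: never chosen while others remain
    return np.argpartition(keys, -k, axis=-1)[..., -k:]


def ranked_survival(rng: np.random.Generator, weights, k: int) -> np.ndarray:
    """Deterministic survival of the ``k`` fittest, uniform random tie-break.

    With all weights equal this reduces to a uniform random subset, so
    neutral drift is preserved within fitness classes.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise ValueError("ranked survival expects a 1-D weight vector")
    perm = rng.permutation(w.size)
    order = perm[np.argsort(-w[perm], kind="stable")]
    return order[:k]


@dataclass
class GenerationRecord:
    """Snapshot of the summary statistics at one recorded generation."""

    generation: int
    mean_phenotype_pop1: float
    mean_phenotype_pop2: float
    divergence: float
    d_max: float
    d_mean: float
    pct_missing: float
    n_extant_loci: int


class AllelePool:
    """Frozen per-locus collections of extant gene copies.

    Global scope holds one value array per locus over the whole
    metapopulation; local scope one array per (locus, subpopulation).
    Only present copies enter a pool, each with its multiplicity, so a
    uniform draw over a pool is a frequency-weighted draw over alleles.
    """

    def __init__(self, scope: str, values, origins=None):
        self.scope = scope
        self._values = values
        self._origins = origins

    @classmethod
    def empty_tracking(cls) -> bool:  # pragma: no cover - trivial
        return False

    def donors(self, locus: int, subpop: int | None = None):
        """Value (and origin-tag) arrays donatable at ``locus`` for ``subpop``."""
        if self.scope == "global":
            vals = self._values[locus]
            orig = None if self._origins is None else self._origins[locus]
        else:
            if subpop is None:
                raise ValueError("local pools require a subpopulation")
            vals = self._values[locus][subpop]
            orig = None if self._origins is None else self._origins[locus][subpop]
        return vals, orig

    def size(self, locus: int, subpop: int | None = None) -> int:
        return len(self.donors(locus, subpop)[0])


def build_pools(state: PopulationState, scope: str) -> AllelePool:
    """Snapshot the extant allele pools of every locus at the given scope."""
    if scope not in ("global", "local"):
        raise ValueError("scope must be 'global' or 'local'")
    track = state.origin is not None
    values, origins = [], ([] if track else None)
    if scope == "global":
        for l in range(state.n_loci):
            rows = state.present[:, l]
            values.append(state.effects[rows, l])
            if track:
                origins.append(state.origin[rows, l])
    else:
        sub0 = state.niche_of == 0
        sub1 = state.niche_of == 1
        for l in range(state.n_loci):
            p = state.present[:, l]
            values.append((state.effects[sub0 & p, l], state.effects[sub1 & p, l]))
            if track:
                origins.append((state.origin[sub0 & p, l], state.origin[sub1 & p, l]))
    return AllelePool(scope, values, origins)


def reproduce_and_select(
    state: PopulationState, config: ScenarioConfig, rng: np.random.Generator
) -> PopulationState:
    """One round of fission and fitness-weighted (or neutral) survival.

    Every individual divides into two identical offspring; from each
    group's offspring pool of size ``2n`` exactly ``n`` survive, sampled
    without replacement — uniformly under neutral evolution, or with
    probability proportional to stabilizing-selection fitness against the
    group's niche optimum under divergent selection.  Before the split the
    whole metapopulation forms a single (always neutral in the standard
    protocol) group; afterwards each subpopulation reproduces separately,
    so subpopulation sizes are conserved exactly.
    """
    if state.is_split:
        groups = [(state.subpop_rows(0), config.optima[0]), (state.subpop_rows(1), config.optima[1])]
    else:
        groups = [(np.arange(state.n_individuals), config.optima[0])]

    selective = config.selection == "divergent"
    if selective:
        phen = state.phenotypes()

    survivor_parents = []
    for rows, x in groups:
        n = rows.size
        if n == 0:
            raise ValueError("empty reproduction group")
        offspring_parent = np.repeat(rows, 2)  # two identical offspring per parent
        if selective:
            w = np.repeat(fitness(phen[rows], x, config.sigma2_selection), 2)
            if config.survival_model == "fitness_ranked":
                pick = ranked_survival(rng, w, n)
            else:
                pick = weighted_sample_without_replacement(rng, w, n)
        else:
            pick = rng.permutation(2 * n)[:n]
        survivor_parents.append(offspring_parent[pick])

    idx = np.concatenate(survivor_parents)
    return PopulationState(
        effects=state.effects[idx],
        present=state.present[idx],
        niche_of=state.niche_of[idx],
        generation=state.generation,
        origin=None if state.origin is None else state.origin[idx],
    )


def mutate(state: PopulationState, config: ScenarioConfig, rng: np.random.Generator) -> PopulationState:
    """Mutate each present gene copy independently with probability ``m``.

    Fixed model: the allele flips sign (``+a <-> -a``).  Evolving model:
    the effect is redrawn from a normal kernel centred on its current
    value with variance ``sigma2_mutation``.  Absent slots are untouched.
    Operates in place and returns the state.
    """
    m = config.mutation_rate
    if m == 0.0:
        return state
    hit = (rng.random(state.effects.shape) < m) & state.present
    k = int(hit.sum())
    if k == 0:
        return state
    if config.effect_model == "fixed":
        state.effects[hit] = -state.effects[hit]
    else:
        state.effects[hit] += rng.normal(0.0, np.sqrt(config.sigma2_mutation), size=k)
    return state


def recombine(
    state: PopulationState,
    pools: AllelePool,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Homologous recombination as gene conversion from a frozen pool.

    Each present copy independently converts with probability ``r``; the
    resident allele is replaced by a uniform (multiplicity-weighted) draw
    from the pool of extant copies at that locus in the configured scope.
    Self-recombination is possible and a no-op.  Absent slots neither
    donate nor receive; the presence mask is unchanged.  In place.
    """
    r = config.recombination_rate
    if r == 0.0:
        return state
    hit = (rng.random(state.effects.shape) < r) & state.present
    if not hit.any():
        return state
    track = state.origin is not None
    for l in range(state.n_loci):
        col = hit[:, l]
        if not col.any():
            continue
        if pools.scope == "global":
            targets = np.flatnonzero(col)
            _convert(state, pools, rng, l, None, targets, track)
        else:
            for s in (0, 1):
                targets = np.flatnonzero(col & (state.niche_of == s))
                if targets.size:
                    _convert(state, pools, rng, l, s, targets, track)
    return state


def _convert(state, pools, rng, locus, subpop, targets, track):
    vals, orig = pools.donors(locus, subpop)
    # a present recipient guarantees a nonempty pool in its own scope
    assert vals.size > 0, "recombination event at a locus with an empty pool"
    j = rng.integers(0, vals.size, size=targets.size)
    state.effects[targets, locus] = vals[j]
    if track and orig is not None:
        state.origin[targets, locus] = orig[j]


def lose_genes(state: PopulationState, config: ScenarioConfig, rng: np.random.Generator) -> PopulationState:
    """Each present copy becomes absent with probability ``lambda`` (in place).

    A lost slot drops its effect value (stored as 0.0), contributes zero
    to the phenotype, and is thereafter exempt from mutation and
    recombination until refilled by gene gain.
    """
    lam = config.loss_rate
    if lam == 0.0:
        return state
    lost = (rng.random(state.effects.shape) < lam) & state.present
    if not lost.any():
        return state
    state.present[lost] = False
    state.effects[lost] = 0.0
    if state.origin is not None:
        state.origin[lost] = -1
    return state


def gain_genes(
    state: PopulationState,
    pools: AllelePool,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Refill empty slots with copies from carriers, with probability ``gamma``.

    Each absent slot independently attempts a gain; if any extant copy of
    that locus exists within the configured pool scope, the slot becomes
    present with the value of a uniformly drawn copy.  A locus extinct in
    scope can never be regained.  In place.
    """
    gamma = config.gain_rate
    if gamma == 0.0:
        return state
    hit = (rng.random(state.effects.shape) < gamma) & ~state.present
    if not hit.any():
        return state
    track = state.origin is not None
    for l in range(state.n_loci):
        col = hit[:, l]
        if not col.any():
            continue
        if pools.scope == "global":
            groups = [(None, np.flatnonzero(col))]
        else:
            groups = [(s, np.flatnonzero(col & (state.niche_of == s))) for s in (0, 1)]
        for s, targets in groups:
            if not targets.size:
                continue
            vals, orig = pools.donors(l, s)
            if vals.size == 0:
                continue  # locus extinct in scope: no gain possible
            j = rng.integers(0, vals.size, size=targets.size)
            state.effects[targets, l] = vals[j]
            state.present[targets, l] = True
            if track and orig is not None:
                state.origin[targets, l] = orig[j]
    return state


def step_generation(
    state: PopulationState, config: ScenarioConfig, rng: np.random.Generator
) -> PopulationState:
    """Advance the population by one full generation.

    Order of operators: reproduction/selection, mutation, recombination
    (against pools frozen after mutation), gene loss, gene gain (against
    pools rebuilt after loss, so a locus extinguished this generation
    cannot donate).  Zero-rate operators are skipped without consuming
    random draws.
    """
    state = reproduce_and_select(state, config, rng)
    state = mutate(state, config, rng)
    if config.recombination_rate > 0:
        pools = build_pools(state, config.gene_pool)
        state = recombine(state, pools, config, rng)
    state = lose_genes(state, config, rng)
    if config.gain_rate > 0:
        pools = build_pools(state, config.gene_pool)
        state = gain_genes(state, pools, config, rng)
    state.generation += 1
    return state


def split_population(state: PopulationState, config: ScenarioConfig) -> PopulationState:
    """Split the metapopulation into two fixed subpopulations in place.

    The first ``N/2`` rows become subpopulation 1 (niche optimum ``x1``)
    and the rest subpopulation 2 (``x2``); rows are exchangeable after a
    neutral burn-in, so block assignment is unbiased.  If lineage
    tracking is on, every present copy is tagged with its subpopulation.
    """
    n = state.n_individuals
    state.niche_of = np.repeat(np.array([0, 1], dtype=np.int8), n // 2)
    if config.track_lineage:
        tags = np.repeat(state.niche_of[:, None], state.n_loci, axis=1).astype(np.int8)
        tags[~state.present] = -1
        state.origin = tags
    return state


def _make_record(state: PopulationState, config: ScenarioConfig) -> GenerationRecord:
    phen = state.phenotypes()
    sub0 = state.niche_of == 0
    sub1 = state.niche_of == 1
    m1 = float(phen[sub0].mean())
    m2 = float(phen[sub1].mean())
    absence = config.loss_rate > 0 or config.gain_rate > 0
    prof = summary_stats.divergence_profile(state, absence_as_zero=absence)
    return GenerationRecord(
        generation=state.generation,
        mean_phenotype_pop1=m1,
        mean_phenotype_pop2=m2,
        divergence=abs(m1 - m2),
        d_max=prof.d_max,
        d_mean=prof.d_mean,
        pct_missing=100.0 * float((~state.present).mean()),
        n_extant_loci=int(state.present.any(axis=0).sum()),
    )


def run(
    config: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    log_every: int = 0,
) -> tuple[PopulationState, list[GenerationRecord]]:
    """Run one replicate: burn-in, split, and the post-split phase.

    Phase 1 (burn-in): the undivided metapopulation reproduces neutrally;
    by default every other configured operator (mutation, recombination,
    loss, gain) already runs at its scenario rate, so the two phases share
    one generation loop and differ only in selection and population
    structure (``burn_in_processes="mutation_only"`` restricts the burn-in
    to mutation instead).  Phase 2: the population is split and the full
    operator set runs for ``run_generations`` with niche optima applied
    under divergent selection.  Summary statistics are recorded at the
    split, every ``record_every`` generations, and at the final generation.

    Returns the final state and the list of generation records.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.burn_in_processes == "mutation_only":
        burn_cfg = config.replace(
            selection="neutral", recombination_rate=0.0, loss_rate=0.0, gain_rate=0.0
        )
    else:
        burn_cfg = config.replace(selection="neutral")
    state = founder_population(config)
    for _ in range(config.burn_in_generations):
        state = step_generation(state, burn_cfg, rng)

    state = split_population(state, config)
    records = [_make_record(state, config)]
    for g in range(1, config.run_generations + 1):
        state = step_generation(state, config, rng)
        if g % config.record_every == 0 or g == config.run_generations:
            records.append(_make_record(state, config))
        if log_every and g % log_every == 0:
            log.info("generation %d/%d divergence=%.3f", g, config.run_generations, records[-1].divergence)
    return state, records


def records_to_frame(
    records: list[GenerationRecord],
    scenario_id: str = "",
    replicate: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy time-series table (one row per recorded generation)."""
    df = pd.DataFrame([vars(r) for r in records])
    df.insert(0, "scenario", scenario_id)
    df.insert(1, "replicate", replicate)
    df.insert(2, "seed", seed)
    return df
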