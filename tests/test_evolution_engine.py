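"""Per-generation operators: sampling distributions, event semantics, invariants."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ecotypesim import (
    PopulationState,
    ScenarioConfig,
    build_pools,
    fitness,
    founder_population,
    gain_genes,
    lose_genes,
    mutate,
    recombine,
    reproduce_and_select,
    run,
    split_population,
    step_generation,
)
from ecotypesim.evolution_engine import (
    DegenerateWeightsError,
    ranked_survival,
    weighted_sample_without_replacement,
)

from conftest import make_state


def sequential_pair_probabilities(weights):
    """Exact distribution over unordered survivor pairs for k=2, by
    enumerating sequential weighted draws without replacement."""
    w = np.asarray(weights, float)
    total = w.sum()
    probs = {}
    for i, j in itertools.permutations(range(len(w)), 2):
        p = (w[i] / total) * (w[j] / (total - w[i]))
        key = frozenset((i, j))
        probs[key] = probs.get(key, 0.0) + p
    return probs


class TestSurvivorSampling:
    def test_weighted_sampler_matches_sequential_enumeration(self, rng):
        """Chi-squared check of the vectorized sampler against brute-force
        enumeration of sequential fitness-weighted draws, for the toy pool
        of four offspring with fitnesses {1, 1, e^-1, e^-1}."""
        w = np.array([1.0, 1.0, math.exp(-1), math.exp(-1)])
        exact = sequential_pair_probabilities(w)
        n = 100_000
        picks = weighted_sample_without_replacement(rng, np.tile(w, (n, 1)), 2)
        keys = sorted(exact, key=sorted)
        index = {k: i for i, k in enumerate(keys)}
        counts = np.zeros(len(keys))
        for a, b in picks:
            counts[index[frozenset((int(a), int(b)))]] += 1
        expected = n * np.array([exact[k] for k in keys])
        assert stats.chisquare(counts, expected).pvalue > 1e-3

    def test_equal_weights_reduce_to_uniform(self, rng):
        n = 50_000
        picks = weighted_sample_without_replacement(rng, np.ones((n, 4)), 2)
        freq = np.bincount(picks.ravel(), minlength=4) / (2 * n)
        assert np.allclose(freq, 0.25, atol=3 * math.sqrt(0.25 * 0.75 / (2 * n)))

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(DegenerateWeightsError):
            weighted_sample_without_replacement(rng, np.zeros(4), 2)

    def test_ranked_survival_keeps_fittest_and_breaks_ties_uniformly(self, rng):
        w = np.array([1.0, 0.5, 1.0, 0.2])
        for _ in range(20):
            picks = set(ranked_survival(rng, w, 2).tolist())
            assert picks == {0, 2}
        # among ties, each equally likely
        w = np.ones(4)
        counts = np.zeros(4)
        for _ in range(8000):
            counts[ranked_survival(rng, w, 2)] += 1
        assert np.allclose(counts / 16000, 0.25, atol=0.02)


class TestReproduceAndSelect:
    def test_neutral_survival_marginal_probability_half(self, rng):
        """Uniform sampling of N from the 2N offspring pool: each of a
        parent's two offspring survives with marginal probability 1/2, so
        the expected offspring count per parent is exactly 1."""
        cfg = ScenarioConfig(n_total=8, n_loci=1, selection="neutral")
        state = make_state(np.arange(8, dtype=float).reshape(8, 1))
        n_rep = 4000
        out_counts = np.zeros(8)
        for _ in range(n_rep):
            out = reproduce_and_select(state, cfg, rng)
            vals, cnt = np.unique(out.effects[:, 0], return_counts=True)
            out_counts[vals.astype(int)] += cnt
        mean_offspring = out_counts / n_rep
        se = math.sqrt(0.5 / n_rep)  # var of a parent's offspring count ~ 0.5
        assert np.allclose(mean_offspring, 1.0, atol=4 * se)

    def test_subpopulation_sizes_conserved_and_no_migration(self, rng):
        cfg = ScenarioConfig(n_total=40, n_loci=2)
        state = split_population(founder_population(cfg), cfg)
        for _ in range(10):
            state = step_generation(state, cfg, rng)
            assert (state.niche_of == 0).sum() == 20
            assert (state.niche_of == 1).sum() == 20
            assert np.all(state.niche_of[:20] == 0)

    def test_family_size_capped_at_two(self, rng):
        cfg = ScenarioConfig(n_total=20, n_loci=1, selection="divergent")
        # unique effect per parent identifies lineages
        state = make_state(np.linspace(0.0, 1.9, 20).reshape(20, 1))
        for _ in range(50):
            out = reproduce_and_select(state, cfg, rng)
            _, counts = np.unique(out.effects[:, 0], return_counts=True)
            assert counts.max() <= 2

    def test_expected_mean_fitness_matches_enumeration_and_never_decreases(self, rng):
        """One selective round on an enumerable pool: Monte-Carlo mean fitness
        agrees with exact enumeration over all ordered survivor draws, and
        exceeds the parental mean."""
        cfg = ScenarioConfig(n_total=4, n_loci=1, allele_magnitude=1.0)
        phen = np.array([1.0, 0.8, 0.6, 0.2])
        state = make_state(phen.reshape(4, 1), niche=np.full(4, -1))
        w_parent = fitness(phen, 1.0, cfg.sigma2_selection)
        w_pool = np.repeat(w_parent, 2)
        # exact expectation over sequential draws of 4 survivors from 8
        total_p = 0.0
        expect_fit = 0.0
        for perm in itertools.permutations(range(8), 4):
            p, remaining = 1.0, w_pool.sum()
            for idx in perm:
                p *= w_pool[idx] / remaining
                remaining -= w_pool[idx]
            total_p += p
            expect_fit += p * w_pool[list(perm)].mean()
        assert total_p == pytest.approx(1.0)
        n_rep = 3000
        sims = np.empty(n_rep)
        for i in range(n_rep):
            out = reproduce_and_select(state, cfg, rng)
            sims[i] = fitness(out.phenotypes(), 1.0, cfg.sigma2_selection).mean()
        se = sims.std(ddof=1) / math.sqrt(n_rep)
        assert abs(sims.mean() - expect_fit) < 3 * se
        assert expect_fit > w_parent.mean()


class TestMutate:
    def test_zero_rate_is_identity(self, rng):
        cfg = ScenarioConfig(mutation_rate=0.0, n_total=20)
        state = founder_population(cfg)
        before = state.effects.copy()
        mutate(state, cfg, rng)
        assert np.array_equal(state.effects, before)

    def test_fixed_model_flips_sign(self, rng):
        cfg = ScenarioConfig(n_total=10, mutation_rate=1.0)
        state = founder_population(cfg)
        mutate(state, cfg, rng)
        assert np.all(state.effects == -0.1)

    def test_evolving_kernel_moments(self, rng):
        """1e5 forced mutations of a copy at 0.1: sample mean ~ 0.1 and
        sample variance ~ sigma2_m, within 3 standard errors."""
        n = 100_000
        cfg = ScenarioConfig(
            n_total=n, n_loci=1, effect_model="evolving", mutation_rate=1.0
        )
        state = make_state(np.full((n, 1), 0.1), niche=np.full(n, -1, dtype=np.int8))
        mutate(state, cfg, rng)
        vals = state.effects[:, 0]
        sd = math.sqrt(cfg.sigma2_mutation)
        assert abs(vals.mean() - 0.1) < 3 * sd / math.sqrt(n)
        se_var = cfg.sigma2_mutation * math.sqrt(2.0 / (n - 1))
        assert abs(vals.var(ddof=1) - cfg.sigma2_mutation) < 3 * se_var

    def test_absent_slots_untouched(self, rng):
        cfg = ScenarioConfig(n_total=10, n_loci=4, mutation_rate=1.0, loss_rate=0.5)
        state = founder_population(cfg)
        state.present[:, 1] = False
        state.effects[:, 1] = 0.0
        mutate(state, cfg, rng)
        assert np.all(state.effects[:, 1] == 0.0)
        assert np.all(state.effects[:, [0, 2, 3]] == -0.25)  # founder allele is x1/L


class TestPools:
    def test_global_pool_counts_multiplicities(self):
        effects = np.concatenate([np.full(10, 0.1), np.full(30, -0.1)]).reshape(40, 1)
        state = make_state(effects)
        pool = build_pools(state, "global")
        vals, _ = pool.donors(0)
        assert (vals == 0.1).sum() == 10
        assert (vals == -0.1).sum() == 30

    def test_extinct_locus_has_empty_pool(self):
        state = make_state(np.zeros((8, 2)), present=[[True, False]] * 8)
        pool = build_pools(state, "global")
        assert pool.size(1) == 0
        assert pool.size(0) == 8

    def test_local_pool_excludes_other_subpopulation(self):
        effects = np.array([[0.1]] * 4 + [[-0.1]] * 4)
        state = make_state(effects)
        pool = build_pools(state, "local")
        vals0, _ = pool.donors(0, 0)
        vals1, _ = pool.donors(0, 1)
        assert np.all(vals0 == 0.1)
        assert np.all(vals1 == -0.1)


class TestRecombine:
    def test_zero_rate_is_identity(self, rng):
        cfg = ScenarioConfig(n_total=20, recombination_rate=0.0)
        state = founder_population(cfg)
        before = state.effects.copy()
        recombine(state, build_pools(state, "global"), cfg, rng)
        assert np.array_equal(state.effects, before)

    def test_monomorphic_pool_converts_to_pool_value(self, rng):
        cfg = ScenarioConfig(n_total=10, n_loci=1, recombination_rate=1.0)
        state = make_state(np.full((10, 1), 0.1))
        donor_state = make_state(np.full((10, 1), -0.1))
        pool = build_pools(donor_state, "global")
        recombine(state, pool, cfg, rng)
        assert np.all(state.effects == -0.1)

    def test_acquired_values_match_pool_frequencies(self, rng):
        """1e5 forced conversions against a 25/75 pool reproduce the pool
        frequencies within 3 standard errors."""
        n = 100_000
        cfg = ScenarioConfig(n_total=n, n_loci=1, recombination_rate=1.0)
        effects = np.where(np.arange(n) < n // 4, 0.3, 0.7).reshape(n, 1)
        state = make_state(effects, niche=np.full(n, -1, dtype=np.int8))
        recombine(state, build_pools(state, "global"), cfg, rng)
        freq = (state.effects[:, 0] == 0.3).mean()
        assert abs(freq - 0.25) < 3 * math.sqrt(0.25 * 0.75 / n)

    def test_absent_slots_neither_receive_nor_donate(self, rng):
        cfg = ScenarioConfig(n_total=8, n_loci=2, recombination_rate=1.0, loss_rate=0.1)
        state = make_state(
            [[0.1, 0.5]] * 8, present=[[True, False]] * 4 + [[True, True]] * 4
        )
        pool = build_pools(state, "global")
        recombine(state, pool, cfg, rng)
        assert np.all(state.effects[:4, 1] == 0.0)
        vals, _ = pool.donors(1)
        assert len(vals) == 4  # only present copies entered the pool


class TestLossAndGain:
    def test_certain_loss_empties_all_genomes(self, rng):
        cfg = ScenarioConfig(n_total=10, loss_rate=1.0)
        state = founder_population(cfg)
        lose_genes(state, cfg, rng)
        assert not state.present.any()
        assert np.all(state.phenotypes() == 0.0)

    def test_single_loss_drops_phenotype_linearly(self):
        state = make_state([[0.1] * 10] * 4)
        state.present[0, 0] = False
        state.effects[0, 0] = 0.0
        assert state.phenotypes()[0] == pytest.approx(0.9)
        assert state.phenotypes()[1] == pytest.approx(1.0)

    def test_zero_gain_is_identity(self, rng):
        cfg = ScenarioConfig(n_total=10, loss_rate=0.1, gain_rate=0.0)
        state = founder_population(cfg)
        state.present[:, 0] = False
        mask = state.present.copy()
        gain_genes(state, build_pools(state, "global"), cfg, rng)
        assert np.array_equal(state.present, mask)

    def test_extinct_locus_never_regained(self, rng):
        cfg = ScenarioConfig(n_total=10, n_loci=2, loss_rate=0.5, gain_rate=1.0)
        state = founder_population(cfg)
        state.present[:, 0] = False  # locus 0 extinct everywhere
        state.effects[:, 0] = 0.0
        state.present[:5, 1] = False
        state.effects[:5, 1] = 0.0
        gain_genes(state, build_pools(state, "global"), cfg, rng)
        assert not state.present[:, 0].any()
        assert state.present[:, 1].all()  # refilled from surviving carriers
        assert np.all(state.effects[:, 1] == 0.5)  # founder allele is x1/L

    def test_local_gain_draws_from_own_subpopulation(self, rng):
        cfg = ScenarioConfig(
            n_total=8, n_loci=1, gene_pool="local", loss_rate=0.5, gain_rate=1.0
        )
        state = make_state([[0.1]] * 4 + [[-0.1]] * 4)
        state.present[0, 0] = False
        state.effects[0, 0] = 0.0
        state.present[4, 0] = False
        state.effects[4, 0] = 0.0
        gain_genes(state, build_pools(state, "local"), cfg, rng)
        assert state.effects[0, 0] == 0.1
        assert state.effects[4, 0] == -0.1


class TestStepInvariants:
    def test_allele_closure_fixed_model(self, rng):
        cfg = ScenarioConfig(n_total=40, recombination_rate=0.05)
        state = split_population(founder_population(cfg), cfg)
        for _ in range(30):
            state = step_generation(state, cfg, rng)
        assert set(np.unique(np.round(state.effects, 12))) <= {0.1, -0.1}

    def test_mask_shrinks_monotonically_without_gain(self, rng):
        cfg = ScenarioConfig(n_total=40, loss_rate=0.05)
        state = split_population(founder_population(cfg), cfg)
        extant = state.present.any(axis=0)
        for _ in range(30):
            state = step_generation(state, cfg, rng)
            now = state.present.any(axis=0)
            assert not np.any(now & ~extant)  # extinct loci stay extinct
            extant = now

    def test_absent_slot_exemption_across_steps(self, rng):
        cfg = ScenarioConfig(
            n_total=40, n_loci=4, recombination_rate=0.2, mutation_rate=0.2, loss_rate=0.0
        )
        state = split_population(founder_population(cfg), cfg)
        state.present[:, 2] = False  # locus 2 extinct by construction
        state.effects[:, 2] = 0.0
        for _ in range(20):
            state = step_generation(state, cfg, rng)
            assert not state.present[:, 2].any()
            assert np.all(state.effects[:, 2] == 0.0)

    def test_neutral_one_step_allele_frequency_martingale(self, rng):
        cfg = ScenarioConfig(n_total=20, n_loci=1, selection="neutral", mutation_rate=0.0)
        effects = np.where(np.arange(20) < 6, 0.1, -0.1).reshape(20, 1)
        base = make_state(effects)
        n_rep = 4000
        freqs = np.empty(n_rep)
        for i in range(n_rep):
            out = step_generation(base.copy(), cfg, rng)
            freqs[i] = (out.effects[:, 0] == 0.1).mean()
        se = freqs.std(ddof=1) / math.sqrt(n_rep)
        assert abs(freqs.mean() - 0.3) < 3 * se


class TestRun:
    def test_burn_in_keeps_full_gene_complement_without_loss(self):
        cfg = ScenarioConfig(
            n_total=40, burn_in_generations=50, run_generations=10, record_every=5
        )
        state, records = run(cfg)
        assert state.present.all()
        assert state.generation == 60

    def test_records_cadence_and_final_generation(self):
        cfg = ScenarioConfig(
            n_total=40, burn_in_generations=10, run_generations=23, record_every=10
        )
        _, records = run(cfg)
        gens = [r.generation for r in records]
        assert gens == [10, 20, 30, 33]

    def test_identical_seed_reproduces_run_exactly(self):
        cfg = ScenarioConfig(
            n_total=60,
            recombination_rate=0.05,
            loss_rate=0.01,
            gain_rate=0.01,
            burn_in_generations=20,
            run_generations=50,
            record_every=25,
            seed=99,
        )
        s1, r1 = run(cfg)
        s2, r2 = run(cfg)
        assert np.array_equal(s1.effects, s2.effects)
        assert np.array_equal(s1.present, s2.present)
        assert [vars(a) for a in r1] == [vars(b) for b in r2]

    def test_local_pools_isolate_lineages(self):
        """With niche-local donor pools there is no channel for DNA to cross
        between subpopulations: every gene copy descends from a split-time
        copy of its own subpopulation."""
        cfg = ScenarioConfig(
            n_total=60,
            recombination_rate=0.1,
            loss_rate=0.01,
            gain_rate=0.01,
            gene_pool="local",
            burn_in_generations=20,
            run_generations=150,
            record_every=150,
            track_lineage=True,
            seed=5,
        )
        state, _ = run(cfg)
        for sub in (0, 1):
            tags = state.origin[state.niche_of == sub]
            present = state.present[state.niche_of == sub]
            assert set(np.unique(tags[present])) <= {sub}
            assert np.all(tags[~present] == -1)
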