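import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from prfsim import (
    FixationLog,
    MutationArray,
    ScenarioError,
    add_new_mutations,
    compact,
    drift,
    migrate,
    select,
    simulate,
    step_generation,
)

from conftest import neutral_scenario, replicate_array


def viability_recursion(x, s, h):
    """Independently coded textbook diploid selection recursion (F = 0)."""
    wbar = 1 + s * x**2 + 2 * h * s * x * (1 - x)
    return (x**2 * (1 + s) + x * (1 - x) * (1 + h * s)) / wbar


class TestMigrate:
    def test_identity_matrix_is_noop(self, rng):
        x = rng.uniform(size=(20, 3))
        assert np.array_equal(migrate(x, np.eye(3)), x)

    def test_weighted_average(self):
        x = np.array([[0.2, 0.8]])
        m = np.array([[0.9, 0.0], [0.1, 1.0]])  # 10% of pop 0 from pop 1
        out = migrate(x, m)
        assert out[0, 0] == pytest.approx(0.9 * 0.2 + 0.1 * 0.8)
        assert out[0, 1] == pytest.approx(0.8)

    @given(p=st.floats(0, 1), rate=st.floats(0, 0.5))
    def test_equal_frequencies_are_a_fixed_point(self, p, rate):
        x = np.full((1, 2), p)
        m = np.array([[1 - rate, rate], [rate, 1 - rate]])
        assert np.allclose(migrate(x, m), p)

    def test_bad_column_sum_rejected(self):
        with pytest.raises(ScenarioError):
            migrate(np.ones((1, 2)), np.array([[0.5, 0.0], [0.1, 1.0]]))


class TestSelect:
    def test_neutral_identity(self, rng):
        x = rng.uniform(size=100)
        assert np.allclose(select(x, 0.0, 0.3, 0.7), x)

    def test_boundaries_absorbing(self):
        out = select(np.array([0.0, 1.0]), 0.5, 0.2, 0.1)
        assert out[0] == 0.0 and out[1] == 1.0

    def test_printed_example(self):
        out = select(np.array([0.5]), 0.1, 0.5, 0.0)
        assert out[0] == pytest.approx(0.5375 / 1.05)

    @given(
        x=st.floats(0, 1),
        s=st.floats(-0.9, 2.0),
        h=st.floats(0, 1),
    )
    def test_agrees_with_viability_recursion_outbred(self, x, s, h):
        ours = select(np.array([x]), s, h, 0.0)[0]
        assert ours == pytest.approx(viability_recursion(x, s, h), abs=1e-12)

    @given(x=st.floats(0.0, 1.0), s=st.floats(-0.9, 2.0))
    def test_haploid_limit(self, x, s):
        """F = 1 reduces to the haploid recursion x(1+s)/(1+sx), any h."""
        ours = select(np.array([x]), s, 0.1, 1.0)[0]
        assert ours == pytest.approx(x * (1 + s) / (1 + s * x), abs=1e-12)

    @given(
        x=st.floats(0, 1),
        s=st.floats(-0.99, 5.0),
        h=st.floats(0, 1),
        f=st.floats(0, 1),
    )
    def test_result_stays_in_unit_interval(self, x, s, h, f):
        """For h in [0,1] all genotype fitnesses are positive when s > -1."""
        out = select(np.array([x]), s, h, f)[0]
        assert 0.0 <= out <= 1.0

    def test_lethal_rejected(self):
        with pytest.raises(ScenarioError):
            select(np.array([0.5]), -1.0, 0.5, 0.0)

    def test_extreme_underdominance_nonpositive_fitness_rejected(self):
        # s=4, h=-1: mean fitness hits zero at x=1/2
        with pytest.raises(ScenarioError, match="fitness"):
            select(np.array([0.5]), 4.0, -1.0, 0.0)


class TestDrift:
    def test_absorbing_boundaries(self, rng):
        x = np.array([0.0, 1.0, 0.0])
        assert np.array_equal(drift(x, 100, rng), x)

    def test_output_on_lattice(self, rng):
        out = drift(rng.uniform(size=1000), 64, rng)
        assert np.allclose(out * 64, np.rint(out * 64))

    def test_binomial_mean(self, rng):
        reps, ne, x = 10_000, 1000, 0.3
        out = drift(np.full(reps, x), ne, rng)
        tol = 4 * np.sqrt(x * (1 - x) / (ne * reps))
        assert abs(out.mean() - x) < tol

    def test_exact_distribution_ne2(self, rng):
        """x=1/2, Ne=2: outcomes {0, 1/2, 1} with probabilities 1/4, 1/2, 1/4."""
        draws = drift(np.full(10_000, 0.5), 2, rng)
        observed = np.bincount((draws * 2).astype(int), minlength=3)
        result = stats.chisquare(observed, 10_000 * np.array([0.25, 0.5, 0.25]))
        assert result.pvalue > 0.001


class TestAddNewMutations:
    def test_zero_rate_appends_nothing(self):
        sc = neutral_scenario(100, 10, mu=0.0)
        arr = MutationArray(1)
        add_new_mutations(sc, 1, arr)
        assert len(arr) == 0

    def test_poisson_mean_influx(self):
        """Ne=20,000, mu=1e-9, L=2e9: mean Ne*mu*L = 40,000 per generation."""
        gens = 100
        sc = neutral_scenario(10_000, gens, mu=1e-9, num_sites=2e9, seed=5)
        arr = MutationArray(1)
        for t in range(1, gens + 1):
            add_new_mutations(sc, t, arr)
        expected = 40_000 * gens
        se = np.sqrt(expected)
        assert abs(len(arr) - expected) < 3 * se

    def test_new_rows_start_at_one_over_ne(self):
        sc = neutral_scenario(100, 10, mu=1e-5, num_sites=1e6, seed=2)
        arr = MutationArray(1)
        add_new_mutations(sc, 3, arr)
        assert len(arr) > 0
        assert np.all(arr.freq[:, 0] == 1.0 / 200)
        assert np.all(arr.origin_generation == 3)
        ids = set(zip(arr.origin_generation.tolist(), arr.origin_index.tolist()))
        assert len(ids) == len(arr)


class TestCompact:
    def test_filters_lost_and_fixed_logs_fixations(self, three_row_array):
        log = FixationLog(2)
        out, log = compact(three_row_array, log, 7, np.array([True, True]))
        assert len(out) == 1
        assert np.allclose(out.freq, [[0.5, 0.2]])
        assert len(log.events) == 1
        gen, counts = log.events[0]
        assert gen == 7 and np.array_equal(counts, [1, 1])
        assert log.cumulative(0) == 1

    def test_fixed_in_one_population_only_is_retained(self):
        arr = MutationArray.from_arrays(
            np.array([[1.0, 0.4]]), np.array([0]), np.array([0]), np.array([0])
        )
        log = FixationLog(2)
        out, _ = compact(arr, log, 1, np.array([True, True]))
        assert len(out) == 1  # still segregating overall

    def test_empty_array_noop(self):
        arr, log = MutationArray(2), FixationLog(2)
        out, log2 = compact(arr, log, 1, np.array([True, True]))
        assert len(out) == 0 and log2.events == []

    def test_preserves_row_order(self, rng):
        freq = rng.uniform(0.1, 0.9, size=(50, 1))
        freq[::7] = 0.0
        arr = MutationArray.from_arrays(
            freq, np.zeros(50, int), np.zeros(50, int), np.arange(50)
        )
        out, _ = compact(arr, FixationLog(1), 1, np.array([True]))
        survivors = np.arange(50)[(freq[:, 0] != 0.0)]
        assert np.array_equal(out.origin_index, survivors)


class TestStepGeneration:
    def test_deterministic_under_seed(self):
        sc = neutral_scenario(200, 5, mu=1e-6, num_sites=1e6, seed=11)
        a = replicate_array(100, 0.5)
        b = replicate_array(100, 0.5)
        for t in range(5):
            step_generation(sc, t, a)
            step_generation(sc, t, b)
        assert np.array_equal(a.freq, b.freq)

    def test_huge_ne_nearly_deterministic(self):
        """With drift variance x(1-x)/Ne -> 0, frequencies barely move."""
        sc = neutral_scenario(5e8, 1, mu=0.0)
        arr = replicate_array(1000, 0.3)
        step_generation(sc, 0, arr)
        assert np.max(np.abs(arr.freq - 0.3)) < 5 / np.sqrt(1e9)

    def test_neutral_fixation_probability_equals_start_frequency(self):
        """20,000 replicate chains from x=1/2, Ne=100: ~half fix."""
        reps = 20_000
        sc = neutral_scenario(
            50, 3000, mu=0.0, seed=21, initial_state=replicate_array(reps, 0.5)
        )
        arr, log = simulate(sc)
        assert len(arr) == 0  # all absorbed by 30 Ne generations
        fixed_fraction = log.totals[0] / reps
        assert abs(fixed_fraction - 0.5) < 3 * np.sqrt(0.25 / reps)


class TestSimulate:
    def test_zero_generations_returns_compacted_initial_state(self):
        init = MutationArray.from_arrays(
            np.array([[0.0], [1.0], [0.25]]),
            np.zeros(3, int), np.zeros(3, int), np.arange(3),
        )
        sc = neutral_scenario(100, 0, mu=0.0, initial_state=init)
        arr, log = simulate(sc)
        assert len(arr) == 1 and arr.freq[0, 0] == 0.25
        assert log.totals[0] == 1

    def test_frequencies_stay_in_unit_interval_on_lattice(self):
        sc = neutral_scenario(
            50, 40, mu=1e-5, num_sites=1e6, seed=9,
            selection=lambda j, t, x: 0.02,
        )
        arr, _ = simulate(sc)
        f = arr.freq
        assert np.all((f >= 0.0) & (f <= 1.0))
        assert np.allclose(f * 100, np.rint(f * 100))

    def test_identical_seeds_identical_outputs(self):
        sc = neutral_scenario(100, 50, mu=1e-6, num_sites=1e7, seed=13,
                              initial_state="equilibrium")
        a1, _ = simulate(sc)
        a2, _ = simulate(sc)
        assert np.array_equal(a1.freq, a2.freq)
        assert np.array_equal(a1.origin_generation, a2.origin_generation)

    def test_origin_ids_unique_across_run(self):
        sc = neutral_scenario(100, 100, mu=1e-5, num_sites=1e6, seed=4,
                              initial_state="equilibrium")
        arr, _ = simulate(sc)
        triples = set(
            zip(
                arr.origin_generation.tolist(),
                arr.origin_population.tolist(),
                arr.origin_index.tolist(),
            )
        )
        assert len(triples) == len(arr)

    def test_trajectory_recording(self):
        init = replicate_array(5, 0.5)
        sc = neutral_scenario(500, 20, mu=0.0, seed=8, initial_state=init,
                              compact_interval=100)
        arr, log, tracks = simulate(
            sc, track_ids=[(0, 0, 2)], track_every=5
        )
        (rec,) = tracks
        gens = [g for g, _, _ in rec.points]
        assert gens == sorted(set(gens))
        assert gens[0] == 0 and gens[-1] == 20
        assert all(0 <= f <= 1 for _, _, f in rec.points)


class TestFoundingEvents:
    def test_split_copies_source_frequencies(self):
        from prfsim import FoundingEvent, Scenario

        init = MutationArray.from_arrays(
            np.array([[0.4, 0.0], [0.9, 0.0]]),
            np.zeros(2, int), np.zeros(2, int), np.arange(2),
        )
        # huge sizes so drift is negligible; split at generation 3
        sc = Scenario(
            num_populations=2,
            num_sites=1e6,
            num_generations=5,
            mutation_rate=lambda j, t: 0.0,
            census_size=lambda j, t: 1e8 if (j == 0 or t >= 3) else 0,
            founding_events=(FoundingEvent(3, source=0, target=1),),
            seed=6,
            initial_state=init,
        )
        arr, _ = simulate(sc)
        assert np.allclose(arr.freq[:, 1], [0.4, 0.9], atol=1e-3)

    def test_target_column_zero_before_split(self):
        from prfsim import FoundingEvent, Scenario

        init = replicate_array(10, 0.5, num_pops=2)
        init.freq[:, 1] = 0.0
        sc = Scenario(
            num_populations=2,
            num_sites=1e6,
            num_generations=2,
            mutation_rate=lambda j, t: 0.0,
            census_size=lambda j, t: 1000 if (j == 0 or t >= 4) else 0,
            founding_events=(FoundingEvent(4, source=0, target=1),),
            seed=6,
            initial_state=init,
        )
        arr, _ = simulate(sc)  # run ends before the split
        assert np.all(arr.freq[:, 1] == 0.0)
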