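import numpy as np
import pytest
from scipy import stats

from _oracle import exact_wf_log_likelihood
from timesel.hmm import (
    InitialCondition,
    TemporalSamples,
    batch_log_likelihood,
    build_grid,
    build_transition_matrix,
    emission_probability,
    forward_log_likelihood,
    gaussian_moments,
    initial_distribution,
)
from timesel.wf_core import DiploidFitness, PopParams, SelectionSchedule, from_s_h


class TestFrequencyGrid:
    def test_small_uniform_grid_points(self):
        g = build_grid(3)
        np.testing.assert_allclose(g.points, [0, 0.25, 0.5, 0.75, 1])

    def test_point_count_arithmetic(self):
        assert build_grid(499).n == 501

    @pytest.mark.parametrize("n,refine", [(3, 0), (50, 0), (50, 3)])
    def test_cells_tile_unit_interval(self, n, refine):
        g = build_grid(n, refine)
        assert g.cell_edges[0] == 0 and g.cell_edges[-1] == 1
        assert np.all(np.diff(g.cell_edges) > 0)
        assert g.cell_widths.sum() == pytest.approx(1.0, abs=1e-12)
        # each point lies inside its own cell
        assert np.all(g.cell_edges[:-1] <= g.points)
        assert np.all(g.points <= g.cell_edges[1:])

    def test_refinement_concentrates_points_near_boundaries(self):
        plain, refined = build_grid(50), build_grid(50, refinement=3)
        assert refined.n == plain.n + 6
        delta = 1 / 51
        assert np.sum(refined.points < delta) > np.sum(plain.points < delta)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            build_grid(2)


class TestGaussianMoments:
    def test_zero_elapsed_time(self):
        m, v = gaussian_moments(0.37, DiploidFitness(), PopParams(1e4), 0)
        assert (m, v) == (0.37, 0.0)

    def test_one_generation_neutral_variance(self):
        m, v = gaussian_moments(0.5, DiploidFitness(), PopParams(1e4), 1)
        assert m == 0.5
        assert v == pytest.approx(0.25 / 2e4, rel=1e-12)

    @pytest.mark.parametrize("dt", [1, 10, 100, 1000])
    @pytest.mark.parametrize("x", [0.1, 0.5, 0.9])
    def test_neutral_variance_closed_form(self, x, dt):
        ne = 5000.0
        _, v = gaussian_moments(x, DiploidFitness(), PopParams(ne), dt)
        expected = x * (1 - x) * (1 - (1 - 1 / (2 * ne)) ** dt)
        assert v == pytest.approx(expected, abs=1e-10)

    def test_mean_is_iterated_deterministic_map(self):
        from timesel.wf_core import deterministic_trajectory

        pop = PopParams(2000, 1e-5, 1e-5)
        fit = from_s_h(0.02, 0.5)
        m, _ = gaussian_moments(0.1, fit, pop, 50)
        traj = deterministic_trajectory(0.1, SelectionSchedule.constant(fit), pop, 50)
        assert m == pytest.approx(traj[-1], rel=1e-12)


class TestTransitionMatrix:
    def test_zero_dt_is_identity(self, grid500, small_pop):
        t = build_transition_matrix(grid500, DiploidFitness(), small_pop, 0)
        np.testing.assert_array_equal(t.matrix, np.eye(grid500.n))

    @pytest.mark.parametrize(
        "fit", [DiploidFitness(), from_s_h(0.05, 0.5), from_s_h(-0.03, 1.0)]
    )
    def test_rows_are_probability_distributions(self, grid500, small_pop, fit):
        t = build_transition_matrix(grid500, fit, small_pop, 25)
        assert np.all(t.matrix >= 0)
        np.testing.assert_allclose(t.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_neutral_drift_is_a_martingale_away_from_boundaries(self, grid500):
        pop = PopParams(1000)
        t = build_transition_matrix(grid500, DiploidFitness(), pop, 10)
        row_means = t.matrix @ grid500.points
        interior = (grid500.points > 0.1) & (grid500.points < 0.9)
        np.testing.assert_allclose(
            row_means[interior], grid500.points[interior], atol=2e-3
        )

    def test_positive_selection_pushes_row_means_up(self, grid500):
        pop = PopParams(1000)
        t = build_transition_matrix(grid500, from_s_h(0.1, 0.5), pop, 10)
        interior = (grid500.points > 0.05) & (grid500.points < 0.9)
        assert np.all((t.matrix @ grid500.points)[interior] > grid500.points[interior])

    def test_chapman_kolmogorov_composition(self, grid500):
        pop = PopParams(500)
        a = build_transition_matrix(grid500, DiploidFitness(), pop, 8).matrix
        b = build_transition_matrix(grid500, DiploidFitness(), pop, 5).matrix
        ab = build_transition_matrix(grid500, DiploidFitness(), pop, 13).matrix
        l1 = np.abs(a @ b - ab).sum(axis=1).max()
        assert l1 <= 5e-3

    def test_absorbing_boundary_row_without_mutation(self, grid500):
        t = build_transition_matrix(grid500, from_s_h(0.1, 0.5), PopParams(200), 5)
        assert t.matrix[0, 0] == pytest.approx(1.0)
        assert t.matrix[-1, -1] == pytest.approx(1.0)


class TestEmission:
    @pytest.mark.parametrize(
        "x, size, count, expected",
        [
            (0.0, 5, 0, 1.0),
            (0.5, 2, 1, 0.5),
            (0.3, 0, 0, 1.0),  # missing data
            (1.0, 3, 3, 1.0),
        ],
    )
    def test_binomial_values(self, x, size, count, expected):
        assert emission_probability(x, size, count) == pytest.approx(expected)

    def test_count_exceeding_size_rejected(self):
        with pytest.raises(ValueError):
            emission_probability(0.5, 2, 3)


class TestInitialDistribution:
    def test_uniform_has_equal_interior_masses(self, small_pop):
        g = build_grid(10)
        w = initial_distribution(InitialCondition.uniform(), g, small_pop)
        np.testing.assert_allclose(w[1:-1], w[1], rtol=1e-12)
        assert w[0] == pytest.approx(w[1] / 2)
        assert w.sum() == pytest.approx(1.0)

    def test_fixed_on_boundary_and_on_grid(self, grid499, small_pop):
        w = initial_distribution(InitialCondition.fixed(0.0), grid499, small_pop)
        assert w[0] == 1.0 and w[1:].sum() == 0.0
        w = initial_distribution(InitialCondition.fixed(0.5), grid499, small_pop)
        assert w[np.searchsorted(grid499.points, 0.5)] == 1.0

    def test_fixed_off_grid_interpolates_preserving_mean(self, grid499, small_pop):
        x0 = 0.2503
        w = initial_distribution(InitialCondition.fixed(x0), grid499, small_pop)
        assert np.count_nonzero(w) == 2
        assert w @ grid499.points == pytest.approx(x0, abs=1e-12)

    def test_stationary_beta_symmetric_when_rates_match(self, grid499):
        # 4*Ne*u = 1 on both sides gives the flat Beta(1,1)
        pop = PopParams(Ne=2500, u01=1e-4, u10=1e-4)
        w = initial_distribution(InitialCondition.stationary_beta(), grid499, pop)
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        assert w.sum() == pytest.approx(1.0)

    def test_stationary_beta_against_numeric_integration(self, grid499):
        pop = PopParams(Ne=2500, u01=2e-4, u10=1e-4)
        w = initial_distribution(InitialCondition.stationary_beta(), grid499, pop)
        a, b = 4 * 2500 * 2e-4, 4 * 2500 * 1e-4
        dist = stats.beta(a, b)
        expected = np.diff(dist.cdf(grid499.cell_edges))
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_stationary_beta_requires_two_sided_mutation(self, grid499):
        with pytest.raises(ValueError):
            initial_distribution(
                InitialCondition.stationary_beta(), grid499, PopParams(100, 0.0, 1e-6)
            )

    def test_explicit_weights_validated(self, grid499, small_pop):
        w = np.zeros(grid499.n)
        w[7] = 2.0  # renormalized
        out = initial_distribution(InitialCondition.explicit(w), grid499, small_pop)
        assert out[7] == 1.0
        with pytest.raises(ValueError):
            initial_distribution(InitialCondition.explicit(w[:5]), grid499, small_pop)


class TestForwardAlgorithm:
    def test_single_sample_reduces_to_binomial_pmf(self, grid499, small_pop):
        samples = TemporalSamples(times=[0], sizes=[2], counts=[1])
        ll = forward_log_likelihood(
            samples,
            SelectionSchedule.constant(DiploidFitness()),
            small_pop,
            InitialCondition.fixed(0.5),
            grid499,
        )
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_all_missing_data_gives_zero_loglik(self, grid499, small_pop):
        samples = TemporalSamples(times=[0, 50, 100], sizes=[0, 0, 0], counts=[0, 0, 0])
        ll = forward_log_likelihood(
            samples,
            SelectionSchedule.constant(DiploidFitness()),
            small_pop,
            InitialCondition.uniform(),
            grid499,
        )
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            TemporalSamples(times=[10, 0], sizes=[2, 2], counts=[0, 0])

    @pytest.mark.parametrize(
        "fit", [DiploidFitness(), from_s_h(0.02, 0.5), from_s_h(-0.02, 1.0)]
    )
    def test_matches_exact_small_population_hmm(self, grid500, small_pop, fit, rng):
        times = np.arange(0, 201, 50)
        sizes = np.full(5, 40)
        sched = SelectionSchedule.constant(fit)
        for _ in range(5):
            samples = TemporalSamples(
                times=times, sizes=sizes, counts=rng.integers(0, 41, size=5)
            )
            ll = forward_log_likelihood(
                samples, sched, small_pop, InitialCondition.fixed(0.3), grid500
            )
            oracle = exact_wf_log_likelihood(samples, fit, small_pop, 0.3)
            assert ll == pytest.approx(oracle, abs=0.1)

    def test_allele_relabeling_invariance(self, grid500):
        # swapping allele labels: mirror counts, mutation rates, the initial
        # condition, and refer fitnesses to the other homozygote
        pop = PopParams(Ne=500, u01=2e-5, u10=5e-5)
        pop_m = PopParams(Ne=500, u01=5e-5, u10=2e-5)
        fit = DiploidFitness(sAa=0.03, sAA=0.08)
        fit_m = DiploidFitness(
            sAa=(1 + fit.sAa) / (1 + fit.sAA) - 1, sAA=1 / (1 + fit.sAA) - 1
        )
        times = np.array([0, 40, 90])
        sizes = np.array([30, 30, 30])
        counts = np.array([5, 11, 19])
        s = TemporalSamples(times=times, sizes=sizes, counts=counts)
        s_m = TemporalSamples(times=times, sizes=sizes, counts=sizes - counts)
        ll = forward_log_likelihood(
            s,
            SelectionSchedule.constant(fit),
            pop,
            InitialCondition.fixed(0.3),
            grid500,
        )
        ll_m = forward_log_likelihood(
            s_m,
            SelectionSchedule.constant(fit_m),
            pop_m,
            InitialCondition.fixed(0.7),
            grid500,
        )
        assert ll == pytest.approx(ll_m, abs=1e-8)

    def test_epoch_boundary_splits_transition(self, grid500, small_pop):
        # likelihood with an onset inside an interval must differ from both
        # constant-neutral and constant-selected models
        times = np.array([0, 100])
        s = TemporalSamples(times=times, sizes=[40, 40], counts=[8, 30])
        init = InitialCondition.fixed(0.2)
        fit = from_s_h(0.05, 0.5)
        ll_onset = forward_log_likelihood(
            s, SelectionSchedule.with_onset(fit, 50), small_pop, init, grid500
        )
        ll_neu = forward_log_likelihood(
            s, SelectionSchedule.constant(DiploidFitness()), small_pop, init, grid500
        )
        ll_sel = forward_log_likelihood(
            s, SelectionSchedule.constant(fit), small_pop, init, grid500
        )
        assert ll_neu < ll_onset < ll_sel

    def test_grid_refinement_changes_little_at_large_ne(self):
        pop = PopParams(1e4, 1e-6, 1e-6)
        times = np.arange(0, 2001, 500)
        s = TemporalSamples(
            times=times, sizes=np.full(5, 40), counts=[4, 10, 14, 22, 30]
        )
        init = InitialCondition.uniform()
        sched = SelectionSchedule.constant(from_s_h(0.002, 0.5))
        ll_500 = forward_log_likelihood(s, sched, pop, init, build_grid(500))
        ll_1000 = forward_log_likelihood(s, sched, pop, init, build_grid(1000))
        assert abs(ll_500 - ll_1000) <= 0.01


class TestBatch:
    def _make_loci(self, rng, n):
        times = np.arange(0, 151, 50)
        sizes = np.full(4, 30)
        return [
            TemporalSamples(times=times, sizes=sizes, counts=rng.integers(0, 31, size=4))
            for _ in range(n)
        ]

    def test_batch_equals_scalar_loop(self, grid500, small_pop, rng):
        loci = self._make_loci(rng, 30)
        sched = SelectionSchedule.constant(from_s_h(0.01, 0.5))
        init = InitialCondition.uniform()
        batch = batch_log_likelihood(loci, sched, small_pop, init, grid500)
        scalar = [
            forward_log_likelihood(l, sched, small_pop, init, grid500) for l in loci
        ]
        np.testing.assert_allclose(batch, scalar, atol=1e-12, rtol=0)

    def test_duplicated_locus_duplicates_loglik(self, grid500, small_pop, rng):
        loci = self._make_loci(rng, 1) * 2
        out = batch_log_likelihood(
            loci,
            SelectionSchedule.constant(DiploidFitness()),
            small_pop,
            InitialCondition.uniform(),
            grid500,
        )
        assert out[0] == out[1]

    def test_mismatched_time_schedules_rejected(self, grid500, small_pop):
        a = TemporalSamples(times=[0, 50], sizes=[10, 10], counts=[1, 2])
        b = TemporalSamples(times=[0, 60], sizes=[10, 10], counts=[1, 2])
        with pytest.raises(ValueError):
            batch_log_likelihood(
                [a, b],
                SelectionSchedule.constant(DiploidFitness()),
                small_pop,
                InitialCondition.uniform(),
                grid500,
            )
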