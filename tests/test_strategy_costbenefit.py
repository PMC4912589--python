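"""Forced stay/leave strategies, omega posteriors, and the strategy grid."""

import numpy as np
import pytest

import famstate as fs
from famstate.fitness_projection import FitnessPosterior


@pytest.fixture(scope="module")
def truth_tables(truth):
    return fs.tables_from_truth(truth)


class TestStrategySpec:
    def test_bounds(self):
        with pytest.raises(ValueError):
            fs.StrategySpec(0)
        with pytest.raises(ValueError):
            fs.StrategySpec(8)
        with pytest.raises(ValueError):
            fs.StrategySpec(3, -1)

    def test_grid_enumeration(self):
        grid = fs.default_strategies()
        assert len(grid) == 28  # sum_{p=1..7} (8 - p)
        assert all(s.leave_parents_age + s.sibling_years <= 7 for s in grid)


class TestForcedTransitionTables:
    def test_immediate_independence(self, truth_tables):
        forced = fs.forced_transition_tables(truth_tables, fs.StrategySpec(1, 0))
        # every age-1 with-parents bird goes straight to independent/nonbreeder
        assert forced.psi[0, 0, 2] == 1.0

    def test_boundary_stay_until_seven(self, truth_tables):
        forced = fs.forced_transition_tables(truth_tables, fs.StrategySpec(7, 0))
        for a in range(1, 7):
            assert forced.psi[0, a - 1, 0] == 1.0
        assert forced.psi[0, 6, 2] == 1.0

    def test_sibling_phase_schedule(self, truth_tables):
        forced = fs.forced_transition_tables(truth_tables, fs.StrategySpec(2, 2))
        assert forced.psi[0, 1, 1] == 1.0   # leave parents at age 2, to siblings
        assert forced.psi[1, 2, 1] == 1.0   # stay with siblings at age 3
        assert forced.psi[1, 3, 2] == 1.0   # leave siblings at age 4

    def test_all_rows_sum_to_one(self, truth_tables):
        for spec in fs.default_strategies():
            forced = fs.forced_transition_tables(truth_tables, spec)
            assert np.allclose(forced.psi.sum(axis=2), 1.0, atol=1e-12)

    def test_no_breeding_from_forced_family_phases(self, truth_tables):
        forced = fs.forced_transition_tables(truth_tables, fs.StrategySpec(3, 2))
        assert np.all(forced.psi[0, :, 3] == 0)
        assert np.all(forced.psi[1, :, 3] == 0)

    def test_observed_breeding_from_independence_retained(self, truth_tables):
        forced = fs.forced_transition_tables(truth_tables, fs.StrategySpec(2, 1))
        assert np.allclose(forced.psi[2], truth_tables.psi[2])

    def test_sibling_breeding_switch(self, truth_tables):
        spec = fs.StrategySpec(2, 3, allow_sibling_breeding=True)
        forced = fs.forced_transition_tables(truth_tables, spec)
        # during the forced sibling phase the observed shortcut is retained
        assert forced.psi[1, 3, 3] == pytest.approx(truth_tables.psi[1, 3, 3])
        assert np.allclose(forced.psi.sum(axis=2), 1.0, atol=1e-12)

    def test_saturating_schedule_never_reaches_independence(self, truth_tables):
        forced = fs.forced_transition_tables(truth_tables, fs.StrategySpec(5, 10))
        assert forced.psi[1, 6, 1] == 1.0  # sibling state absorbs within class 7


class TestStrategyFitness:
    def test_fixed_point_when_observed_equals_forced(self):
        """Deterministic stay-forever tables are their own forced version."""
        phi = np.full((4, 7), 0.9)
        psi = np.zeros((4, 7, 4))
        psi[0, :, 0] = 1.0
        psi[1, :, 1] = 1.0
        psi[2, :, 2] = 1.0
        psi[3, :, 3] = 1.0
        tables = fs.ProbabilityTables(phi=phi, psi=psi, p=np.full(4, 0.9))
        lam_wt = fs.dominant_eigenvalue(fs.build_projection_matrix(tables))
        lam_s = fs.dominant_eigenvalue(fs.build_projection_matrix(tables, fs.StrategySpec(7, 0)))
        # strategy (7, 0) only changes the (unreachable-in-time) exit at age 7
        assert lam_s == pytest.approx(lam_wt, abs=1e-9)

    def test_early_departure_ignores_later_parent_survival(self, truth_tables):
        spec = fs.StrategySpec(1, 0)
        A = fs.build_projection_matrix(truth_tables, spec)
        from famstate.fitness_projection import stage_index

        # with-parents stages beyond age 1 receive no inflow
        inflow = A[[stage_index(a, 1) for a in range(2, 8)], :].sum()
        assert inflow == 0.0

    def test_per_draw_matches_dense_eigensolver(self, small_draws):
        spec = fs.StrategySpec(2, 1)
        fit = fs.strategy_fitness(small_draws, spec)
        for i in range(0, small_draws.n_draws, 37):
            A = fs.build_projection_matrix(small_draws.tables(i), spec)
            assert fit.lambdas[i] == pytest.approx(np.max(np.abs(np.linalg.eigvals(A))), abs=1e-10)


class TestFitnessDifference:
    def test_identical_posteriors(self):
        lam = np.linspace(0.5, 0.9, 40)
        wt = FitnessPosterior.from_lambdas(lam)
        res = fs.fitness_difference(wt, FitnessPosterior.from_lambdas(lam.copy()), fs.StrategySpec(1))
        assert res.p_below_zero == 0.0  # strict tie policy

    def test_uniformly_better_strategy(self):
        lam = np.linspace(0.5, 0.9, 40)
        wt = FitnessPosterior.from_lambdas(lam)
        sim = FitnessPosterior.from_lambdas(lam + 0.01)
        res = fs.fitness_difference(wt, sim, fs.StrategySpec(1))
        assert res.p_below_zero == 1.0 and res.credible

    def test_counting(self):
        wt = FitnessPosterior.from_lambdas(np.array([0.99, 0.98, 1.03, 1.04]))
        sim = FitnessPosterior.from_lambdas(np.array([1.0, 1.0, 1.0, 1.0]))
        res = fs.fitness_difference(wt, sim, fs.StrategySpec(1))
        assert res.p_below_zero == 0.5 and not res.credible

    def test_misaligned_draws_rejected(self):
        with pytest.raises(ValueError):
            fs.fitness_difference(
                FitnessPosterior.from_lambdas(np.ones(5)),
                FitnessPosterior.from_lambdas(np.ones(6)),
                fs.StrategySpec(1),
            )


class TestStrategyGrid:
    def test_grid_shape_and_order(self, small_draws):
        sub = fs.PosteriorDraws(
            params=small_draws.params[::30],
            chain=small_draws.chain[::30],
            iteration=small_draws.iteration[::30],
            layout=small_draws.layout,
        )
        grid = fs.strategy_grid(sub)
        assert len(grid) == 29  # wildtype row + 28 strategies
        assert grid.iloc[0]["strategy"] == "wildtype"
        body = grid.iloc[1:]
        keys = list(zip(body["leave_parents_age"], body["sibling_years"]))
        assert keys == sorted(keys)

    def test_order_invariance(self, small_draws):
        sub = fs.PosteriorDraws(
            params=small_draws.params[::60],
            chain=small_draws.chain[::60],
            iteration=small_draws.iteration[::60],
            layout=small_draws.layout,
        )
        specs = [fs.StrategySpec(1, 0), fs.StrategySpec(3, 2)]
        a = fs.strategy_grid(sub, strategies=specs)
        b = fs.strategy_grid(sub, strategies=specs[::-1])
        assert np.allclose(a["P"].iloc[1:].to_numpy(dtype=float), b["P"].iloc[1:].to_numpy(dtype=float))

    def test_shifting_wildtype_up_moves_p_toward_zero(self, small_draws):
        sub = fs.PosteriorDraws(
            params=small_draws.params[::60],
            chain=small_draws.chain[::60],
            iteration=small_draws.iteration[::60],
            layout=small_draws.layout,
        )
        wt = fs.wildtype_fitness(sub)
        spec = fs.StrategySpec(1, 0)
        fit = fs.strategy_fitness(sub, spec)
        p0 = fs.fitness_difference(wt, fit, spec).p_below_zero
        shifted = FitnessPosterior.from_lambdas(wt.lambdas + 0.05)
        p1 = fs.fitness_difference(shifted, fit, spec).p_below_zero
        assert p1 <= p0


class TestMonitorDrawCorrelations:
    def test_age_constant_duplicated_columns_flagged(self, small_sim):
        mcmc = fs.McmcConfig(n_chains=2, n_iterations=800, n_burnin=300, thin=5, seed=17)
        draws = fs.sample_posterior(small_sim.histories, mcmc, variant="age_constant")
        report = fs.monitor_draw_correlations(draws)
        # consecutive ages share one parameter -> perfect correlation everywhere
        assert report["flagged"].all()
        assert np.allclose(report["r"], 1.0)

    def test_independent_draws_near_zero(self):
        layout = fs.ParamLayout()
        rng = np.random.default_rng(3)
        params = rng.normal(0, 0.2, (400, layout.n_params))
        params[:, layout.p_indices] = rng.uniform(0.2, 0.8, (400, 4))
        draws = fs.PosteriorDraws(params=params, chain=np.zeros(400, dtype=int),
                                  iteration=np.arange(400), layout=layout)
        report = fs.monitor_draw_correlations(draws)
        assert report["r"].abs().max() < 0.25

    def test_matches_direct_recomputation(self, small_draws):
        report = fs.monitor_draw_correlations(small_draws)
        derived = small_draws.derived()
        row = report[(report.from_state == "P") & (report.destination == "P") & (report.age_pair == "a2-a3")]
        direct = np.corrcoef(derived["psi[P->P,a2]"], derived["psi[P->P,a3]"])[0, 1]
        assert row["r"].iloc[0] == pytest.approx(direct, abs=1e-12)
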