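"""Likelihood, priors, sampler plumbing, and diagnostics for the multistate model.

The forward log-likelihood is checked against an exhaustive enumeration of
latent state paths (the independent oracle), written here from scratch.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import famstate as fs
from famstate.core_io import DEAD
from famstate.multistate_model import psrf, transition_ages
from tests.conftest import random_tables

# ---------------------------------------------------------------------------
# independent oracle: brute-force sum over latent state paths
# ---------------------------------------------------------------------------

LIVING = (1, 2, 3, 4)


def brute_force_loglik(obs, tables):
    """Enumerate all latent paths over {1..4, dead} consistent with marking.

    obs: observation codes from the marking occasion onward (obs[0] == 1).
    Transition from occasion j-1 to j uses the age class min(j, 7); emission
    is p_s for a sighting in the true state, 1-p_s for a zero, and 1 for a
    zero emitted by the dead state.
    """
    phi, psi, p = tables.phi, tables.psi, tables.p
    L = len(obs)
    total = 0.0
    for path in itertools.product(*([LIVING + (DEAD,)] * (L - 1))):
        states = (1,) + path
        prob = 1.0
        for j in range(1, L):
            prev, cur = states[j - 1], states[j]
            a = min(j, 7)
            if prev == DEAD:
                prob *= 1.0 if cur == DEAD else 0.0
            elif cur == DEAD:
                prob *= 1.0 - phi[prev - 1, a - 1]
            else:
                prob *= phi[prev - 1, a - 1] * psi[prev - 1, a - 1, cur - 1]
            if prob == 0.0:
                break
            o = obs[j]
            if cur == DEAD:
                prob *= 1.0 if o == 0 else 0.0
            elif o == 0:
                prob *= 1.0 - p[cur - 1]
            else:
                prob *= p[cur - 1] if o == cur else 0.0
        total += prob
    return math.log(total) if total > 0 else -math.inf


def all_short_observation_sequences(max_len=4):
    """Every valid observation sequence of length <= max_len starting with 1."""
    seqs = []
    for L in range(1, max_len + 1):
        for tail in itertools.product((0, 1, 2, 3, 4), repeat=L - 1):
            seq = (1,) + tail
            nonzero = [o for o in seq if o != 0]
            if nonzero == sorted(nonzero):
                seqs.append(seq)
    return seqs


def make_history(obs):
    return fs.CaptureHistory(individual_id="x", cohort_year=1, start_year=1, observations=obs)


class TestForwardLoglik:
    def test_length_one_history_contributes_zero(self):
        tables = random_tables(np.random.default_rng(0))
        assert fs.forward_loglik(make_history((1,)), tables) == 0.0

    def test_two_occasions_perfect_detection_single_path(self):
        rng = np.random.default_rng(1)
        layout = fs.ParamLayout()
        theta = rng.normal(0, 1, layout.n_params)
        theta[layout.p_indices] = 1.0
        tables = layout.tables(theta)
        ll = fs.forward_loglik(make_history((1, 1)), tables)
        expected = math.log(tables.phi[0, 0] * tables.psi[0, 0, 0])
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_on_gap_history(self):
        tables = random_tables(np.random.default_rng(2))
        obs = (1, 0, 3, 0)
        ll = fs.forward_loglik(make_history(obs), tables)
        assert ll == pytest.approx(brute_force_loglik(obs, tables), abs=1e-10)

    def test_matches_oracle_over_random_parameters(self):
        # subset of sequences here; the exhaustive sweep runs in test_acceptance
        seqs = all_short_observation_sequences(4)[::7]
        for i in range(10):
            tables = random_tables(np.random.default_rng(100 + i))
            for obs in seqs:
                ll = fs.forward_loglik(make_history(obs), tables)
                assert ll == pytest.approx(brute_force_loglik(obs, tables), abs=1e-10)

    def test_impossible_history_warns_and_returns_neg_inf(self):
        layout = fs.ParamLayout()
        theta = np.zeros(layout.n_params)
        theta[layout.p_indices] = 1.0  # perfect detection: a gap is impossible
        tables = layout.tables(theta)
        with pytest.warns(UserWarning, match="x"):
            ll = fs.forward_loglik(make_history((1, 0, 3)), tables)
        assert ll == -np.inf

    def test_accepts_raw_parameter_vector(self):
        layout = fs.ParamLayout()
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 0.5, layout.n_params)
        theta[layout.p_indices] = 0.7
        h = make_history((1, 1, 2))
        assert fs.forward_loglik(h, theta, layout) == pytest.approx(
            fs.forward_loglik(h, layout.tables(theta)), abs=1e-14
        )


class TestTransitionRow:
    def test_symmetric_etas_give_uniform(self):
        assert np.allclose(fs.transition_row([0.0, 0.0, 0.0]), 0.25)

    def test_saturation(self):
        row = fs.transition_row([500.0, -500.0, -500.0])
        assert row == pytest.approx([1.0, 0.0, 0.0, 0.0], abs=1e-12)

    def test_closed_form(self):
        # exp(ln 2) = 2 -> (2, 1, 1)/4
        row = fs.transition_row([math.log(2.0), 0.0])
        assert row == pytest.approx([0.5, 0.25, 0.25], abs=1e-14)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-700, 700), min_size=1, max_size=3))
    def test_rows_are_probabilities_summing_to_one(self, eta):
        row = fs.transition_row(eta)
        assert np.all(row >= 0)
        assert abs(row.sum() - 1.0) < 1e-12

    def test_last_entry_is_one_minus_sum(self):
        eta = [0.3, -1.2, 2.0]
        row = fs.transition_row(eta)
        assert row[-1] == pytest.approx(1.0 - row[:-1].sum(), abs=1e-15)


class TestSurvivalProb:
    def test_identity(self):
        assert fs.survival_prob(0.0, 0.0, 3) == 0.5

    def test_closed_form(self):
        # logit^-1(ln 3) = 3/4
        assert fs.survival_prob(0.0, math.log(3.0), 1) == pytest.approx(0.75, abs=1e-14)

    def test_monotone_in_age_for_positive_slope(self):
        assert fs.survival_prob(0.1, 0.4, 7) > fs.survival_prob(0.1, 0.4, 1)

    def test_age_range_enforced(self):
        with pytest.raises(ValueError):
            fs.survival_prob(0.0, 0.0, 8)


class TestLogPrior:
    def test_all_zero_coefficients_is_maximal(self):
        layout = fs.ParamLayout()
        theta = np.zeros(layout.n_params)
        theta[layout.p_indices] = 0.5
        base = fs.log_prior(theta, layout)
        other = theta.copy()
        other[0] = 1.0
        assert base > fs.log_prior(other, layout)

    def test_detection_outside_unit_interval(self):
        layout = fs.ParamLayout()
        theta = np.zeros(layout.n_params)
        theta[layout.p_indices] = 0.5
        theta[layout.p_indices[0]] = 1.5
        assert fs.log_prior(theta, layout) == -np.inf

    def test_one_prior_sd_drop_is_half(self):
        layout = fs.ParamLayout()
        prior = fs.PriorConfig()
        theta = np.zeros(layout.n_params)
        theta[layout.p_indices] = 0.5
        base = fs.log_prior(theta, layout, prior)
        theta[0] = prior.prior_sd
        assert base - fs.log_prior(theta, layout, prior) == pytest.approx(0.5, abs=1e-12)


class TestParamLayout:
    def test_age_specific_size(self):
        # 8 survival + (7*3 + 6*2 + 6*1) transitions + 4 detection
        assert fs.ParamLayout("age_specific").n_params == 51

    def test_age_constant_size(self):
        assert fs.ParamLayout("age_constant").n_params == 18

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            fs.ParamLayout("weekly")

    def test_transition_ages(self):
        assert transition_ages(1) == (1, 2, 3, 4, 5, 6, 7)
        assert transition_ages(2) == (2, 3, 4, 5, 6, 7)

    @pytest.mark.parametrize("variant", ["age_specific", "age_constant"])
    def test_derived_psi_rows_sum_to_one(self, variant):
        layout = fs.ParamLayout(variant)
        rng = np.random.default_rng(4)
        for _ in range(20):
            theta = rng.normal(0, 2, layout.n_params)
            theta[layout.p_indices] = rng.uniform(0, 1, 4)
            tables = layout.tables(theta)
            assert np.allclose(tables.psi.sum(axis=2), 1.0, atol=1e-12)
            assert np.all(tables.psi >= 0)


class TestSampler:
    def test_seed_determinism(self, small_sim):
        mcmc = fs.McmcConfig(n_chains=2, n_iterations=600, n_burnin=200, thin=4, seed=9)
        a = fs.sample_posterior(small_sim.histories, mcmc)
        b = fs.sample_posterior(small_sim.histories, mcmc)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.chain, b.chain)

    def test_draw_bookkeeping(self, small_draws):
        # 2 chains x (2500-1000)/5 retained draws
        assert small_draws.n_draws == 2 * 300
        assert small_draws.n_chains == 2
        assert small_draws.params.shape[1] == 51

    def test_degenerate_data_concentrates_posterior(self):
        # immortal birds that always stay with parents, perfect detection
        obs = tuple([1] * 10)
        histories = [
            fs.CaptureHistory(individual_id=f"g{i}", cohort_year=1, start_year=1, observations=obs)
            for i in range(60)
        ]
        mcmc = fs.McmcConfig(n_chains=2, n_iterations=2000, n_burnin=800, thin=4, seed=21)
        draws = fs.sample_posterior(histories, mcmc)
        psi11 = draws.derived()["psi[P->P,a2]"]
        assert psi11.mean() > 0.9

    def test_age_constant_variant_fits(self, small_sim):
        mcmc = fs.McmcConfig(n_chains=2, n_iterations=800, n_burnin=300, thin=5, seed=13)
        draws = fs.sample_posterior(small_sim.histories, mcmc, variant="age_constant")
        derived = draws.derived()
        # all ages share one multinomial: derived psi identical across ages
        assert np.allclose(derived["psi[P->P,a2]"], derived["psi[P->P,a6]"])


class TestGelmanRubin:
    def test_identical_chains_give_sqrt_ratio(self):
        x = np.random.default_rng(0).normal(size=100)
        chains = np.vstack([x, x])
        assert psrf(chains) == pytest.approx(math.sqrt(99 / 100), abs=1e-12)

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 2000))
        assert abs(psrf(chains) - 1.0) < 0.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.vstack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        # B/n = var of means ~ 50 -> Rhat ~ sqrt(51) >> 1.1
        assert psrf(chains) > 5.0

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            psrf(np.ones((1, 100)))

    def test_dataframe_output_flags(self, small_draws):
        report = fs.gelman_rubin(small_draws)
        assert set(report.columns) == {"parameter", "rhat", "flagged"}
        assert (report["rhat"] > 0).all()


class TestSummaries:
    def test_constant_draws_degenerate_cri(self):
        d = fs.credible_difference(np.full(100, 0.3), np.full(100, 0.3))
        assert (d.mean, d.lo95, d.hi95) == (0.0, 0.0, 0.0)

    def test_percentile_arithmetic(self):
        draws = np.arange(1, 1001) / 1000.0
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(0.025, abs=0.002)
        assert hi == pytest.approx(0.975, abs=0.002)

    def test_summary_bounds(self, small_draws):
        summ = fs.summarize_posterior(small_draws)
        assert (summ["mean"] >= 0).all() and (summ["mean"] <= 1).all()
        assert (summ["lo95"] <= summ["mean"]).all()
        assert (summ["mean"] <= summ["hi95"]).all()


class TestCredibleDifference:
    def test_shifted_by_one_is_credible(self):
        b = np.random.default_rng(0).normal(size=200)
        d = fs.credible_difference(b + 1.0, b)
        assert d.p_below_zero == 0.0 and d.credible

    def test_tie_policy_strict_below(self):
        b = np.ones(50)
        d = fs.credible_difference(b, b)
        assert d.p_below_zero == 0.0

    def test_counting(self):
        d = fs.credible_difference(np.array([0.1, -0.2, 0.3, 0.4]), np.zeros(4))
        assert d.p_below_zero == 0.25
        assert not d.credible

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fs.credible_difference(np.zeros(3), np.zeros(4))
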