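import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twopathway.reinforce import (RLState, _sigmoid, compute_reward,
                                  habit_experiment, reinforce_update,
                                  stochastic_readout, train_rl,
                                  update_baseline)


class TestStochasticReadout:
    def test_unbiased_at_zero_current(self, rng):
        z = stochastic_readout(np.zeros(5000), np.zeros(5000), rng)
        assert set(np.unique(z)) <= {-1.0, 1.0}
        assert abs(z.mean()) < 4 / np.sqrt(5000)

    def test_saturates_at_large_current(self, rng):
        z = stochastic_readout(np.full(2000, 20.0), np.zeros(2000), rng)
        assert np.all(z == 1.0)

    def test_matches_sigmoid_probability(self, rng):
        m = np.full(10_000, 0.7)
        z = stochastic_readout(m, np.zeros_like(m), rng)
        target = 2 * _sigmoid(0.7) - 1
        se = np.sqrt(4 * _sigmoid(0.7) * (1 - _sigmoid(0.7)) / m.size)
        assert abs(z.mean() - target) < 4 * se


class TestReward:
    @pytest.mark.parametrize("z,expected", [
        (np.array([1.0, 1.0, 1.0, 1.0]), 2.0),
        (np.array([-1.0, -1.0, -1.0, -1.0]), -2.0),
        (np.array([1.0, 1.0, -1.0, -1.0]), 0.0),
    ])
    def test_alignment_reward(self, z, expected):
        zhat = np.ones(4)
        assert compute_reward(z, zhat) == expected


class TestReinforceUpdate:
    def test_direct_substitution(self):
        W = np.zeros((1, 1))
        reinforce_update(W, x=np.array([2.0]), z=np.array([1.0]),
                         m=np.array([0.0]), h=np.array([0.0]),
                         R=0.5, Rbar=0.0, eta=1.0)
        assert W[0, 0] == pytest.approx(0.5 * 1.0 * 0.5 * 2.0)

    def test_zero_prediction_error_is_noop(self, rng):
        W = rng.standard_normal((3, 4))
        W0 = W.copy()
        reinforce_update(W, rng.standard_normal(4), np.ones(3),
                         rng.standard_normal(3), np.zeros(3),
                         R=1.3, Rbar=1.3, eta=1.0)
        assert np.array_equal(W, W0)

    def test_expected_update_matches_exhaustive_average(self, rng):
        # oracle: expectation of the update over all 2^N_z readout
        # outcomes, each weighted by its Bernoulli probability, compared
        # with the Monte-Carlo average over sampled readouts
        N_z, N_x = 4, 3
        x = rng.standard_normal(N_x)
        u = rng.standard_normal(N_z)          # currents m + h (h = 0)
        zhat = np.where(rng.random(N_z) < 0.5, -1.0, 1.0)
        Rbar, eta = 0.1, 1.0

        expected = np.zeros((N_z, N_x))
        for bits in itertools.product([-1.0, 1.0], repeat=N_z):
            z = np.array(bits)
            prob = np.prod(np.where(z > 0, _sigmoid(u), _sigmoid(-u)))
            R = compute_reward(z, zhat)
            dW = np.zeros((N_z, N_x))
            reinforce_update(dW, x, z, u, np.zeros(N_z), R, Rbar, eta)
            expected += prob * dW

        n_samples = 40_000
        acc = np.zeros((N_z, N_x))
        acc2 = np.zeros((N_z, N_x))
        for _ in range(n_samples):
            z = stochastic_readout(u, np.zeros(N_z), rng)
            dW = np.zeros((N_z, N_x))
            reinforce_update(dW, x, z, u, np.zeros(N_z),
                             compute_reward(z, zhat), Rbar, eta)
            acc += dW
            acc2 += dW**2
        mc = acc / n_samples
        se = np.sqrt((acc2 / n_samples - mc**2) / n_samples)
        assert np.all(np.abs(mc - expected) < 3 * np.maximum(se, 1e-6))

    def test_expected_update_projects_onto_target_direction(self, rng):
        # averaged over readouts, the update moves W along zhat x^T
        N_z, N_x = 4, 3
        x = rng.standard_normal(N_x)
        zhat = np.where(rng.random(N_z) < 0.5, -1.0, 1.0)
        u = 0.3 * zhat                         # weakly aligned currents
        expected = np.zeros((N_z, N_x))
        for bits in itertools.product([-1.0, 1.0], repeat=N_z):
            z = np.array(bits)
            prob = np.prod(np.where(z > 0, _sigmoid(u), _sigmoid(-u)))
            dW = np.zeros((N_z, N_x))
            reinforce_update(dW, x, z, u, np.zeros(N_z),
                             compute_reward(z, zhat), 0.0, 1.0)
            expected += prob * dW
        assert np.sum(expected * np.outer(zhat, x)) > 0


class TestBaseline:
    def test_single_step(self):
        assert update_baseline(0.0, 1.0, 10.0) == pytest.approx(0.1)

    def test_fixed_point(self):
        assert update_baseline(0.7, 0.7, 10.0) == pytest.approx(0.7)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(r=st.floats(-2, 2), r0=st.floats(-2, 2),
           n=st.integers(1, 50))
    def test_matches_geometric_closed_form(self, r, r0, n):
        tau = 10.0
        rbar = r0
        for _ in range(n):
            rbar = update_baseline(rbar, r, tau)
        closed = r + (r0 - r) * (1 - 1 / tau) ** n
        assert rbar == pytest.approx(closed, rel=1e-9, abs=1e-12)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            update_baseline(0.0, 1.0, 0.5)


class TestTrainRL:
    def test_frozen_rates_leave_weights_invariant(self, rng):
        state = RLState.random(30, 30, 5, seed=1, eta=0.0, beta=0.0,
                               variant="RL_plus_HL", alpha=0.0)
        W0, V0 = state.W.copy(), state.V.copy()
        train_rl(state, rng.standard_normal(30), rng.standard_normal(30),
                 np.where(rng.random(5) < 0.5, -1.0, 1.0), 200, seed=2)
        assert np.array_equal(state.W, W0)
        assert np.array_equal(state.V, V0)

    def test_reward_improves_with_learning(self):
        # trial-averaged reward over the last tenth beats the first tenth
        n_seeds, n_trials = 20, 2000
        first, last = [], []
        for s in range(n_seeds):
            r = np.random.default_rng(1000 + s)
            x = r.standard_normal(200)
            zhat = np.where(r.random(10) < 0.5, -1.0, 1.0)
            state = RLState.zeros(200, 0, 10, eta=1.0, variant="RL_only")
            tr = train_rl(state, x, np.zeros(0), zhat, n_trials, seed=s)
            first.append(tr.reward[:n_trials // 10].mean())
            last.append(tr.reward[-n_trials // 10:].mean())
        # learning is fast at eta = 1, so much of the gain lands inside
        # the first tenth already; the late average must still exceed it
        assert np.mean(last) > np.mean(first) + 0.1

    def test_rl_hl_transfers_control_rl_rl_does_not(self):
        r = np.random.default_rng(5)
        x, y = r.standard_normal(500), r.standard_normal(500)
        zhat = np.where(r.random(10) < 0.5, -1.0, 1.0)
        results = {}
        for variant in ("RL_plus_HL", "RL_plus_RL"):
            state = RLState.random(500, 500, 10, seed=6, eta=1.0, beta=0.01,
                                   eta2=0.01, variant=variant)
            tr = train_rl(state, x, y, zhat, 2500, seed=7)
            results[variant] = tr
        hl, rl = results["RL_plus_HL"], results["RL_plus_RL"]
        # both solve the task through the intact network
        assert hl.match_fraction[-200:].mean() > 0.9
        assert rl.match_fraction[-200:].mean() > 0.9
        # only the Hebbian variant survives removal of the fast pathway
        assert hl.match_m_removed.iloc[-1] > 0.9
        assert rl.match_m_removed.iloc[-1] < 0.7
        assert hl.alignment.iloc[-1] > rl.alignment.iloc[-1]

    def test_hebbian_alignment_nondecreasing_after_learning(self):
        r = np.random.default_rng(9)
        x, y = r.standard_normal(300), r.standard_normal(300)
        zhat = np.where(r.random(10) < 0.5, -1.0, 1.0)
        state = RLState.random(300, 300, 10, seed=3, eta=1.0, beta=0.01)
        tr = train_rl(state, x, y, zhat, 2000, seed=4)
        late = tr.alignment[500:].to_numpy()
        # smoothed trace rises over the Hebbian accumulation phase
        smooth = np.convolve(late, np.ones(100) / 100, mode="valid")
        assert smooth[-1] > smooth[0]
        assert np.min(np.diff(smooth)) > -0.01


class TestHabit:
    def test_no_pretraining_both_variants_fast(self):
        r1 = habit_experiment("RL_only", 0, N_x=300, N_y=300, seed=11)
        r2 = habit_experiment("RL_plus_HL", 0, N_x=300, N_y=300, seed=11)
        assert r1.attained and r2.attained
        assert r1.trials_to_criterion < 500
        assert abs(r1.trials_to_criterion - r2.trials_to_criterion) < 300

    def test_habit_grows_with_pretraining_and_blocks_relearning(self):
        needed = {}
        for n_nu in (0, 60):
            res = habit_experiment("RL_plus_HL", n_nu, N_x=300, N_y=300,
                                   trial_cap=4000, seed=12)
            needed[n_nu] = (res.trials_to_criterion, res.attained)
        assert needed[60][0] is None or needed[60][0] > needed[0][0]
        big = habit_experiment("RL_plus_HL", 2000, N_x=300, N_y=300,
                               trial_cap=4000, seed=12)
        assert not big.attained

    def test_invalid_criterion_rejected(self):
        with pytest.raises(ValueError):
            habit_experiment("RL_only", 0, accuracy_criterion=0.4)


def test_state_validation():
    with pytest.raises(ValueError):
        RLState.zeros(4, 4, 2, variant="HL_only")
    with pytest.raises(ValueError):
        RLState.zeros(4, 4, 2, tau_R=0.5)
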