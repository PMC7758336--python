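import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twopathway.patterns import generate_patterns, make_repetition_schedule
from twopathway.pathways import (PathwayDecomposition, TwoPathwayState,
                                 hebbian_update, lesion_test,
                                 population_similarity, present_pattern,
                                 repeated_pattern_error, train_two_pathway)
from twopathway.perceptron import sign, train_sequential


class TestHebbianUpdate:
    def test_direct_substitution(self):
        V = np.zeros((1, 2))
        hebbian_update(V, np.array([1.0, 1.0]), np.array([1.0]),
                       alpha=1.0, beta=1.0, n_mu=1, nbar=1.0)
        assert np.allclose(V[0], [np.sqrt(2) / 2, np.sqrt(2) / 2])

    def test_fixed_point_under_repetition(self, rng):
        y = rng.standard_normal(6)
        zhat = np.array([-1.0])
        V = np.zeros((1, 6))
        for _ in range(8000):
            hebbian_update(V, y, zhat, alpha=1.0, beta=0.5, n_mu=1, nbar=1.0)
        v_star = np.sqrt(2) * 0.5 * zhat[0] * y
        assert np.allclose(V[0], v_star, rtol=1e-6, atol=1e-9)

    def test_zero_rates_are_identity(self, rng):
        V = rng.standard_normal((3, 4))
        V0 = V.copy()
        hebbian_update(V, rng.standard_normal(4), np.array([1.0, -1.0, 1.0]),
                       alpha=0.0, beta=0.0)
        assert np.array_equal(V, V0)

    def test_empty_second_pathway_is_noop(self):
        V = np.zeros((2, 0))
        out = hebbian_update(V, np.zeros(0), np.array([1.0, -1.0]), 1.0, 1.0)
        assert out.shape == (2, 0)

    def test_aggregated_matches_repetition_factor(self):
        # one call with n_mu = n is the written form of the rule
        y = np.array([1.0, 2.0])
        V1 = np.zeros((1, 2))
        hebbian_update(V1, y, np.array([1.0]), alpha=0.0, beta=1.0,
                       n_mu=3, nbar=1.0)
        V2 = np.zeros((1, 2))
        for _ in range(3):
            hebbian_update(V2, y, np.array([1.0]), alpha=0.0, beta=1.0)
        assert np.allclose(V1, V2)  # exact when alpha == 0

    def test_norm_stays_bounded(self, rng):
        N_y = 40
        alpha, beta = 1.0, 2.0
        V = np.zeros((1, 40))
        y = rng.standard_normal(N_y)
        bound = 10 * (beta / alpha) * np.sqrt(2) * np.abs(y).max()
        for _ in range(10 * N_y):
            hebbian_update(V, y, np.array([1.0]), alpha, beta)
            assert np.abs(V).max() <= bound


class TestPathwayDecomposition:
    def test_alignment_zero_norm_convention(self):
        dec = PathwayDecomposition(m=np.zeros(3), h=np.ones(3))
        assert dec.alignment == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_alignment_bounded(self, seed):
        r = np.random.default_rng(seed)
        dec = PathwayDecomposition(m=r.standard_normal(8),
                                   h=r.standard_normal(8))
        assert -1.0 <= dec.alignment <= 1.0

    def test_control_ratio_conventions(self, rng):
        zhat = np.array([1.0, -1.0])
        m = rng.standard_normal(2)
        assert PathwayDecomposition(m=m, h=np.zeros(2)).control_ratio(zhat) == 0.0
        assert PathwayDecomposition(m=np.zeros(2), h=m).control_ratio(zhat) == 1.0


class TestPresentPattern:
    def test_first_repetition_attains_targets(self, rng):
        state = TwoPathwayState.zeros(30, 20, 4)
        x, y = rng.standard_normal(30), rng.standard_normal(20)
        zhat = np.array([1.0, -1.0, 1.0, 1.0])
        traces = present_pattern(state, x, y, zhat, n=1)
        assert np.all(traces[0].readout() == zhat)

    def test_alignment_and_control_grow_with_repetition(self):
        # population readout; stationary background first, then repeat a
        # probe pattern (from zero weights and a single pattern the two
        # currents are trivially parallel and alignment is meaningless)
        N, N_z = 300, 200
        ens = generate_patterns(N + 1, N, N, N_z, seed=11)
        state = TwoPathwayState.zeros(N, N, N_z)
        for mu in range(N):
            present_pattern(state, ens.X[mu], ens.Y[mu], ens.Zhat[mu])
        traces = present_pattern(state, ens.X[-1], ens.Y[-1], ens.Zhat[-1],
                                 n=12)
        align = [t.alignment for t in traces]
        ctrl = [t.control_ratio(ens.Zhat[-1]) for t in traces]
        assert align[-1] > align[0]
        assert ctrl[-1] > ctrl[0]
        assert np.all(np.diff(align) > -0.02)  # monotone up to tiny noise
        assert np.all(np.diff(ctrl) > -0.02)

    def test_aggregated_close_to_per_repetition_at_small_beta(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        zhat = np.array([1.0])
        states = {}
        for mode in ("per_repetition", "aggregated"):
            s = TwoPathwayState.zeros(20, 20, 1, alpha=0.01, beta=0.01,
                                      hebbian_application=mode)
            present_pattern(s, x, y, zhat, n=5)
            states[mode] = s
        assert np.allclose(states["per_repetition"].V,
                           states["aggregated"].V, rtol=0.02, atol=1e-4)


class TestTrainTwoPathway:
    def test_beta_zero_reduces_to_single_pathway(self):
        # same ensemble, beta = 0: the fast pathway sees identical updates
        ens = generate_patterns(30, 25, 15, 1, seed=6)
        state = TwoPathwayState.zeros(25, 15, 1, alpha=1.0, beta=0.0)
        train_two_pathway(ens, state=state)
        ens_x = generate_patterns(30, 25, 0, 1, seed=0)
        ens_x.X[:] = ens.X
        ens_x.Zhat[:] = ens.Zhat
        sp = train_sequential(ens_x)
        assert np.array_equal(state.W[0], sp.w)
        assert np.all(state.V == 0.0)

    def test_recorded_traces_schema(self):
        ens = generate_patterns(6, 10, 8, 1, seed=2)
        sched = make_repetition_schedule(6, {3: 3})
        state = TwoPathwayState.zeros(10, 8, 1, nbar=sched.nbar)
        _, traces = train_two_pathway(ens, sched, state, record=True)
        assert len(traces) == len(sched.order)
        assert traces[traces.pattern == 3].repetition.max() == 3
        assert set(traces.columns) >= {"pattern", "repetition", "alignment",
                                       "control_ratio"}

    def test_repeated_patterns_retained_longer(self):
        # repeated-pattern error at a fixed long lag decreases with n
        errs = {}
        for n_rep in (1, 10):
            c = repeated_pattern_error(150, 150, 1.0, 1.0, n_rep, [150],
                                       n_runs=150, seed=13)
            errs[n_rep] = c.error[0]
        assert errs[10] < errs[1]


@pytest.fixture(scope="module")
def trained():
    N, P, rep = 250, 250, 125
    ens = generate_patterns(P, N, N, 200, seed=21)
    sched = make_repetition_schedule(P, {rep: 15})
    state = TwoPathwayState.zeros(N, N, 200, nbar=sched.nbar)
    train_two_pathway(ens, sched, state)
    return ens, state, rep


class TestLesionTest:

    def test_intact_noiseless_matches_standard_readout(self, trained):
        ens, state, _ = trained
        err = lesion_test(state, ens, "intact", sigma_m=0.0)
        M = ens.X @ state.W.T + ens.Y @ state.V.T
        expected = np.mean(sign(M) != ens.Zhat, axis=1)
        assert np.array_equal(err, expected)

    def test_lesion_asymmetry_on_repeated_pattern(self, trained):
        ens, state, rep = trained
        err_m0 = lesion_test(state, ens, "m_zero")
        err_h0 = lesion_test(state, ens, "h_zero")
        assert err_m0[rep] < 0.1          # slow pathway carries the habit
        assert err_h0[rep] > 0.25         # fast pathway alone has lost it
        # unrepeated patterns are hurt by losing the fast pathway
        others = np.arange(ens.P) != rep
        assert err_m0[others].mean() > err_m0[rep] + 0.1

    def test_noise_degrades_gracefully(self, trained):
        ens, state, rep = trained
        errs = [lesion_test(state, ens, "intact", sigma_m=s, n_noise=20,
                            seed=3)[rep] for s in (0.0, 2.0, 8.0)]
        assert errs[0] <= errs[1] <= errs[2] + 0.02

    def test_unknown_mode_rejected(self, trained):
        ens, state, _ = trained
        with pytest.raises(ValueError):
            lesion_test(state, ens, "both_zero")
        with pytest.raises(ValueError):
            lesion_test(state, ens, "m_zero", sigma_m=1.0)


class TestPopulationSimilarity:
    def test_untrained_random_state_uncorrelated(self, rng):
        N_z = 400
        state = TwoPathwayState(W=rng.standard_normal((N_z, 50)),
                                V=rng.standard_normal((N_z, 50)))
        ov_mh, ov_mi = population_similarity(state, rng.standard_normal(50),
                                             rng.standard_normal(50))
        assert abs(ov_mh) < 4 / np.sqrt(N_z)

    def test_overlap_grows_with_repetition(self):
        # probe trained last: the similarity measures describe the state
        # right after practice, before the fast current is overwritten
        N, P = 200, 200
        overlaps = []
        for n_rep in (1, 30):
            ens = generate_patterns(P, N, N, 150, seed=31)
            sched = make_repetition_schedule(P, {P - 1: n_rep})
            state = TwoPathwayState.zeros(N, N, 150, nbar=sched.nbar)
            train_two_pathway(ens, sched, state)
            overlaps.append(population_similarity(
                state, ens.X[P - 1], ens.Y[P - 1]))
        assert overlaps[1][0] > overlaps[0][0]
        assert overlaps[1][1] > 0.9  # near-complete transfer at large n

    def test_requires_population(self):
        state = TwoPathwayState.zeros(5, 5, 1)
        with pytest.raises(ValueError):
            population_similarity(state, np.zeros(5), np.zeros(5))


def test_state_validation():
    with pytest.raises(ValueError):
        TwoPathwayState(W=np.zeros((2, 3)), V=np.zeros((3, 3)))
    with pytest.raises(ValueError):
        TwoPathwayState.zeros(3, 3, 1, alpha=-1.0)
    with pytest.raises(ValueError):
        TwoPathwayState.zeros(3, 3, 1, hebbian_application="sometimes")
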