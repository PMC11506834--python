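import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit as sig

from myostab import acrl
from myostab.acrl import Learner, LearnerParams, UpdateRecord
from myostab.ngn import BasisGrid, StateVector

P = LearnerParams()


def state_of(dtheta, dvel):
    return StateVector(np.asarray(dtheta, float), np.asarray(dvel, float))


class TestParams:
    def test_printed_defaults(self):
        assert (P.alpha_v, P.alpha_a, P.tau, P.kappa) == (0.3, 0.11, 0.05, 0.05)
        assert (P.c, P.sigma_r, P.A, P.B) == (0.01, 100.0, 1.0, -4.0)
        assert P.u_max_default == 1.0 and P.dt == 0.01

    def test_derived_factors_are_exactly_08(self):
        assert P.discount == pytest.approx(0.8, abs=1e-15)
        assert P.trace_decay == pytest.approx(0.8, abs=1e-15)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            LearnerParams(tau=0.005)  # tau must exceed dt
        with pytest.raises(ValueError):
            LearnerParams(kappa=0.0)


class TestReward:
    def test_zero_error_zero_activation(self):
        s = state_of(np.zeros(5), np.zeros(5))
        assert acrl.reward(s, np.zeros(8), P) == pytest.approx(10.0, abs=1e-12)

    def test_full_activation_cost(self):
        s = state_of(np.zeros(5), np.zeros(5))
        n_muscles = 14
        expected = 10.0 - 0.01 * n_muscles
        assert acrl.reward(s, np.ones(n_muscles), P) == pytest.approx(expected, abs=1e-12)

    def test_single_joint_closed_form(self):
        s = state_of([100.0], [0.0])
        assert acrl.reward(s, np.zeros(1), P) == pytest.approx(math.exp(-1) + 1, abs=1e-9)

    def test_bounds(self, rng):
        for _ in range(100):
            s = state_of(rng.uniform(-70, 70, 5), rng.uniform(-300, 300, 5))
            u = rng.uniform(0, 1, 10)
            r = acrl.reward(s, u, P)
            assert -P.c * 10 < r <= 10.0


class TestTdError:
    def test_discounted_self(self):
        assert acrl.td_error(0.0, 1.0, 1.0, P) == pytest.approx(-0.2, abs=1e-12)

    def test_pure_reward(self):
        assert acrl.td_error(10.0, 0.0, 0.0, P) == 10.0

    def test_next_value_only(self):
        assert acrl.td_error(0.0, 0.0, 1.0, P) == pytest.approx(0.8, abs=1e-12)


class TestTraces:
    def test_pure_decay(self):
        e = acrl.update_traces(np.ones(3), np.zeros(3), P)
        assert e == pytest.approx(0.8 * np.ones(3), abs=1e-12)

    def test_one_hot_accumulation(self):
        b = np.array([0.0, 1.0, 0.0])
        e = acrl.update_traces(np.zeros(3), b, P)
        assert e == pytest.approx([0.0, 0.01, 0.0], abs=1e-15)

    def test_five_step_decay(self):
        e = np.ones(1)
        for _ in range(5):
            e = acrl.update_traces(e, np.zeros(1), P)
        assert e[0] == pytest.approx(0.8 ** 5, abs=1e-12)
        assert e[0] == pytest.approx(0.32768, abs=1e-12)

    def test_impulse_response_exact(self):
        # one-hot basis at t0, zeros afterwards: e(t0 + j dt) = dt * 0.8^j
        e = acrl.update_traces(np.zeros(1), np.ones(1), P)
        for j in range(1, 8):
            e = acrl.update_traces(e, np.zeros(1), P)
            assert e[0] == pytest.approx(P.dt * 0.8 ** j, abs=1e-15)


class TestWeightUpdates:
    def test_critic_zero_delta_unchanged(self, rng):
        v = rng.normal(size=5)
        assert acrl.update_critic(v, 0.0, rng.normal(size=5), P) == pytest.approx(v)

    def test_critic_unit_step(self):
        v = acrl.update_critic(np.zeros(3), 1.0, np.ones(3), P)
        assert v == pytest.approx(0.3 * np.ones(3), abs=1e-12)

    def test_critic_elementwise_recomputation(self, rng):
        v, e = rng.normal(size=7), rng.normal(size=7)
        delta = rng.normal()
        out = acrl.update_critic(v, delta, e, P)
        for i in range(7):
            assert out[i] == pytest.approx(v[i] + 0.3 * delta * e[i], abs=1e-12)

    def test_actor_zero_delta_or_noise_unchanged(self, rng):
        w = rng.normal(size=(4, 3))
        b = rng.uniform(0, 1, 4)
        assert acrl.update_actor(w, 0.0, rng.uniform(0, 1, 3), 1.0, b, P) == pytest.approx(w)
        assert acrl.update_actor(w, 1.0, np.zeros(3), 1.0, b, P) == pytest.approx(w)

    def test_actor_unit_step(self):
        w = acrl.update_actor(np.zeros((1, 1)), 1.0, np.ones(1), 0.0, np.ones(1), P)
        assert w[0, 0] == pytest.approx(0.11, abs=1e-12)

    def test_actor_value_halving(self):
        # exp(-0.5 V) with V = 2 ln 2 halves the update relative to V = 0
        base = acrl.update_actor(np.zeros((1, 1)), 1.0, np.ones(1), 0.0, np.ones(1), P)
        halved = acrl.update_actor(np.zeros((1, 1)), 1.0, np.ones(1), 2 * math.log(2),
                                   np.ones(1), P)
        assert halved[0, 0] == pytest.approx(0.5 * base[0, 0], abs=1e-12)

    def test_actor_elementwise_recomputation(self, rng):
        w = rng.normal(size=(5, 4))
        b, n = rng.uniform(0, 1, 5), rng.uniform(0, 1, 4)
        delta, value = rng.normal(), rng.normal()
        out = acrl.update_actor(w, delta, n, value, b, P)
        for i in range(5):
            for m in range(4):
                assert out[i, m] == pytest.approx(
                    w[i, m] + 0.11 * delta * n[m] * math.exp(-0.5 * value) * b[i],
                    abs=1e-12)


class TestActivation:
    def test_baseline_sig4(self):
        u = acrl.activation(np.zeros(3), 5.0, np.zeros(3), 1.0, P)
        assert u == pytest.approx(sig(4.0) * np.ones(3), abs=1e-12)
        assert u[0] == pytest.approx(0.98201379, abs=1e-6)

    def test_actor_output_four_gives_half(self):
        u = acrl.activation(np.array([4.0]), 0.0, np.zeros(1), 0.7, P)
        assert u[0] == pytest.approx(0.35, abs=1e-12)

    def test_zero_ceiling_gives_zero(self):
        assert acrl.activation(np.zeros(2), 0.0, np.ones(2), 0.0, P) == pytest.approx(
            np.zeros(2))

    def test_larger_actor_output_decreases_activation(self):
        # the printed minus sign: a up -> u down
        u_low = acrl.activation(np.array([0.0]), 0.0, np.zeros(1), 1.0, P)
        u_high = acrl.activation(np.array([2.0]), 0.0, np.zeros(1), 1.0, P)
        assert u_high[0] < u_low[0]

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-25, 25), st.floats(-10, 50), st.floats(0, 1),
           st.floats(1e-6, 1.0))
    def test_bounds_property(self, a, value, n, u_max):
        # open interval (0, u_max); |a| kept where the sigmoid is strictly
        # inside (0, 1) in float64
        u = acrl.activation(np.array([a]), value, np.array([n]), u_max, P)
        assert 0.0 < u[0] < u_max


class TestNoise:
    def test_reproducible(self):
        a = acrl.noise(np.random.default_rng(7), 100)
        b = acrl.noise(np.random.default_rng(7), 100)
        assert np.array_equal(a, b)

    def test_bounds_and_mean(self):
        draws = acrl.noise(np.random.default_rng(1), 100_000)
        assert np.all((draws >= 0) & (draws <= 1))
        assert abs(draws.mean() - 0.5) < 0.01

    def test_noise_scale(self):
        assert acrl.noise_scale(0.0) == 1.0
        assert acrl.noise_scale(2.0) == pytest.approx(math.exp(-1.0), abs=1e-12)


class TestLearnerStep:
    def make(self, n_motions=1, n_muscles=2):
        grid = BasisGrid(n_motions=n_motions)
        return Learner(grid, n_muscles)

    def test_zero_reward_zero_noise_never_changes_weights(self):
        # a = 0 forever and r = 0 makes delta identically zero from step one
        learner = self.make()
        s = state_of([10.0], [0.0])
        for _ in range(20):
            u, inter = learner.act(s, 1.0, None, explore=False)
            rec = learner.learn(inter, u, s, s, reward_value=0.0)
            assert rec.delta == 0.0
        assert np.all(learner.critic.v == 0.0)
        assert np.all(learner.actor.w == 0.0)

    def test_single_step_reproduces_update_equations(self, rng):
        learner = self.make(n_motions=2, n_muscles=3)
        learner.critic.v = rng.normal(size=learner.grid.K)
        learner.actor.w = rng.normal(size=(learner.grid.K, 3))
        learner.traces = rng.normal(size=learner.grid.K)
        s_now = state_of([5.0, -10.0], [20.0, 0.0])
        s_next = state_of([4.0, -9.0], [15.0, 5.0])
        u, inter = learner.act(s_now, 1.0, np.random.default_rng(3))
        v0, w0, e0 = learner.critic.v.copy(), learner.actor.w.copy(), learner.traces.copy()
        rec = learner.learn(inter, u, s_now, s_next)
        # independent recomputation of the whole update
        b = learner.grid.evaluate(s_now)
        b_next = learner.grid.evaluate(s_next)
        r = acrl.reward(s_now, u, learner.params)
        delta = r + 0.8 * float(v0 @ b_next) - float(v0 @ b)
        e = e0 + 0.01 * (-e0 / 0.05 + b)
        assert rec.delta == pytest.approx(delta, abs=1e-12)
        assert learner.traces == pytest.approx(e, abs=1e-12)
        assert learner.critic.v == pytest.approx(v0 + 0.3 * delta * e, abs=1e-12)
        expected_w = w0 + 0.11 * delta * math.exp(-0.5 * float(v0 @ b)) * np.outer(
            b, inter["noise"])
        assert learner.actor.w == pytest.approx(expected_w, abs=1e-12)

    def test_traces_reset(self):
        learner = self.make()
        learner.traces[:] = 1.0
        learner.reset_traces()
        assert np.all(learner.traces == 0.0)
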