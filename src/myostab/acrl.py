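"""Continuous-time actor-critic learning step.

All learning primitives are pure functions on arrays; :class:`Learner`
bundles the network, traces and parameters and applies one update in the
documented order: observe s(t) -> V, a, u -> plant advances -> observe
s(t+1) -> reward from (s(t), u(t)) -> TD error -> traces with b(s(t)) ->
critic -> actor.

With the default step and time constants the TD discount (1 - dt/tau) and
the per-step trace decay (1 - dt/kappa) are both exactly 0.8.

Note the sign convention of the activation map: larger actor output
*decreases* the activation, u = u_max * sig(-A*(a + sigma*n) - B), which
with A = 1, B = -4 is sig(4 - a - sigma*n).  This is implemented exactly
as specified; no attempt is made to flip it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sig

from .ngn import Actor, BasisGrid, Critic, StateVector


@dataclass
class LearnerParams:
    """Hyperparameters; defaults are the published values."""

    alpha_v: float = 0.3        # critic learning rate
    alpha_a: float = 0.11       # actor learning rate
    tau: float = 0.05           # value time constant (s); discount = 1 - dt/tau
    kappa: float = 0.05         # eligibility-trace time constant (s)
    c: float = 0.01             # activation cost weight in the reward
    sigma_r: float = 100.0      # reward width (deg and deg/s)
    A: float = 1.0              # activation sigmoid gain
    B: float = -4.0             # activation sigmoid offset
    u_max_default: float = 1.0  # ceiling when no feedback model is active
    dt: float = 0.01            # control/integration step (s)

    def __post_init__(self):
        if not (self.tau > self.dt > 0):
            raise ValueError("require tau > dt > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    @property
    def discount(self) -> float:
        return 1.0 - self.dt / self.tau

    @property
    def trace_decay(self) -> float:
        return 1.0 - self.dt / self.kappa


def reward(s: StateVector, u: np.ndarray, p: LearnerParams) -> float:
    """Posture reward minus quadratic activation cost."""
    track = np.exp(-(s.dtheta / p.sigma_r) ** 2) + np.exp(-(s.dvel / p.sigma_r) ** 2)
    return float(track.sum() - p.c * np.sum(np.asarray(u, float) ** 2))


def td_error(r: float, v_now: float, v_next: float, p: LearnerParams) -> float:
    return r + p.discount * v_next - v_now


def update_traces(e: np.ndarray, b: np.ndarray, p: LearnerParams) -> np.ndarray:
    """Euler step of e' = -e/kappa + dV/dv (= b for a linear critic)."""
    return e + p.dt * (-e / p.kappa + b)


def update_critic(v: np.ndarray, delta: float, e: np.ndarray, p: LearnerParams) -> np.ndarray:
    return v + p.alpha_v * delta * e

def update_actor(w: np.ndarray, delta: float, n: np.ndarray, value: float,
                 b: np.ndarray, p: LearnerParams) -> np.ndarray:
    """Noise-correlation actor update, scaled by exp(-0.5 V)."""
    return w + p.alpha_a * delta * math.exp(-0.5 * value) * np.outer(b, n)


def noise_scale(value: float) -> float:
    """Value-modulated exploration amplitude sigma = exp(-0.5 V)."""
    return math.exp(-0.5 * value)


def activation(a: np.ndarray, value: float, n: np.ndarray, u_max, p: LearnerParams) -> np.ndarray:
    """Per-muscle activation u = u_max * sig(-A*(a + exp(-0.5V)*n) - B)."""
    return np.asarray(u_max, float) * sig(-p.A * (np.asarray(a, float)
                                                  + noise_scale(value) * np.asarray(n, float)) - p.B)


def noise(rng: np.random.Generator, n_muscles: int) -> np.ndarray:
    """Per-muscle exploration noise, i.i.d. uniform on [0, 1]."""
    return rng.uniform(0.0, 1.0, n_muscles)


@dataclass
class UpdateRecord:
    reward: float
    delta: float
    value: float
    sigma: float
    noise: np.ndarray
    activations: np.ndarray


class Learner:
    """Actor-critic state: basis grid, weights, traces, hyperparameters."""

    def __init__(self, grid: BasisGrid, n_muscles: int, params: LearnerParams | None = None):
        self.grid = grid
        self.params = params or LearnerParams()
        self.critic = Critic(grid.K)
        self.actor = Actor(grid.K, n_muscles)
        self.n_muscles = n_muscles
        self.traces = np.zeros(grid.K)

    def reset_traces(self) -> None:
        self.traces = np.zeros(self.grid.K)

    def act(self, s: StateVector, u_max, rng: np.random.Generator | None,
            explore: bool = True) -> tuple[np.ndarray, dict]:
        """Activations for state s; returns (u, intermediates)."""
        b = self.grid.evaluate(s)
        v_now = self.critic.value(b)
        a = self.actor.action(b)
        n = noise(rng, self.n_muscles) if (explore and rng is not None) else np.zeros(self.n_muscles)
        u = activation(a, v_now, n, u_max, self.params)
        return u, {"b": b, "value": v_now, "action": a, "noise": n,
                   "sigma": noise_scale(v_now)}

    def learn(self, inter: dict, u: np.ndarray, s_now: StateVector,
              s_next: StateVector, reward_value: float | None = None) -> UpdateRecord:
        """One TD update after the plant has advanced from s_now to s_next."""
        p = self.params
        b = inter["b"]
        v_now = inter["value"]
        b_next = self.grid.evaluate(s_next)
        v_next = self.critic.value(b_next)
        r = reward(s_now, u, p) if reward_value is None else reward_value
        delta = td_error(r, v_now, v_next, p)
        self.traces = update_traces(self.traces, b, p)
        self.critic.v = update_critic(self.critic.v, delta, self.traces, p)
        self.actor.w = update_actor(self.actor.w, delta, inter["noise"], v_now, b, p)
        return UpdateRecord(r, delta, v_now, inter["sigma"], inter["noise"], u)
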