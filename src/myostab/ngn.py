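"""Normalized Gaussian network shared by the critic and the actor.

The state is the concatenated (angle error, velocity error) of the
controlled joint motions, clipped to the supported box before basis
evaluation.  Basis weights are the normalized Gaussians

    b_i(s) = B_i(s) / sum_l B_l(s),
    B_i(s) = exp(-sum_k ((s_k - c_ik) / sigma_k)^2),

evaluated with a max-shifted exponent so the normalization never
underflows (equivalent to the nearest-center fallback in exact
arithmetic).  Critic and actor are plain linear read-outs of b.

Two center layouts are provided:

* ``shared`` (default): a single grid of K centers in the (dtheta,
  dtheta_dot) plane; each center's coordinates are replicated across every
  controlled joint motion and the squared distances summed, so K stays
  fixed regardless of the number of motions.
* ``per_motion``: each center lives on one joint motion's plane and only
  that motion's errors enter its exponent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

ANGLE_CLIP = 70.0      # degrees
VEL_CLIP = 300.0       # degrees/s
SIGMA_ANGLE = 26.5     # degrees
SIGMA_VEL = 163.6      # degrees/s


@dataclass
class StateVector:
    """Clipped per-motion errors: dtheta (deg) and dvel (deg/s)."""

    dtheta: np.ndarray
    dvel: np.ndarray

    @property
    def n_motions(self) -> int:
        return len(self.dtheta)

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.dtheta, self.dvel])


def make_state(angles, velocities, targets) -> StateVector:
    """Build the clipped error state; target velocities are zero."""
    dtheta = np.clip(np.asarray(angles, float) - np.asarray(targets, float),
                     -ANGLE_CLIP, ANGLE_CLIP)
    dvel = np.clip(np.asarray(velocities, float), -VEL_CLIP, VEL_CLIP)
    return StateVector(dtheta, dvel)


class BasisGrid:
    """Grid of normalized Gaussian basis functions over the error box."""

    def __init__(self, n_motions: int, n_angle: int = 12, n_vel: int = 12,
                 sigma_angle: float = SIGMA_ANGLE, sigma_vel: float = SIGMA_VEL,
                 layout: str = "shared",
                 angle_clip: float = ANGLE_CLIP, vel_clip: float = VEL_CLIP):
        if layout not in ("shared", "per_motion"):
            raise ValueError(f"unknown layout {layout!r}")
        if sigma_angle <= 0 or sigma_vel <= 0:
            raise ValueError("basis widths must be strictly positive")
        self.n_motions = n_motions
        self.n_angle = n_angle
        self.n_vel = n_vel
        self.sigma_angle = sigma_angle
        self.sigma_vel = sigma_vel
        self.layout = layout
        self.angle_clip = angle_clip
        self.vel_clip = vel_clip
        ca = np.linspace(-angle_clip, angle_clip, n_angle)
        cv = np.linspace(-vel_clip, vel_clip, n_vel)
        aa, vv = np.meshgrid(ca, cv, indexing="ij")
        if layout == "shared":
            self.centers_angle = aa.ravel()          # (K,)
            self.centers_vel = vv.ravel()
            self.motion_index = None
            self.K = n_angle * n_vel
        else:
            self.centers_angle = np.tile(aa.ravel(), n_motions)
            self.centers_vel = np.tile(vv.ravel(), n_motions)
            self.motion_index = np.repeat(np.arange(n_motions), n_angle * n_vel)
            self.K = n_motions * n_angle * n_vel

    def evaluate(self, s: StateVector) -> np.ndarray:
        """Normalized basis weights b, shape (K,), summing to 1."""
        if self.layout == "shared":
            # sum_j ((dth_j - c)/sa)^2 expands around the per-center term
            da = (s.dtheta[None, :] - self.centers_angle[:, None]) / self.sigma_angle
            dv = (s.dvel[None, :] - self.centers_vel[:, None]) / self.sigma_vel
            expo = -(da ** 2).sum(axis=1) - (dv ** 2).sum(axis=1)
        else:
            da = (s.dtheta[self.motion_index] - self.centers_angle) / self.sigma_angle
            dv = (s.dvel[self.motion_index] - self.centers_vel) / self.sigma_vel
            expo = -da ** 2 - dv ** 2
        b = np.exp(expo - expo.max())
        return b / b.sum()

    def to_dict(self) -> dict:
        return {
            "n_motions": self.n_motions, "n_angle": self.n_angle, "n_vel": self.n_vel,
            "sigma_angle": self.sigma_angle, "sigma_vel": self.sigma_vel,
            "layout": self.layout, "angle_clip": self.angle_clip, "vel_clip": self.vel_clip,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisGrid":
        return cls(**d)


class Critic:
    """Linear state-value read-out V = v . b, zero-initialized."""

    def __init__(self, K: int):
        self.v = np.zeros(K)

    def value(self, b: np.ndarray) -> float:
        return float(self.v @ b)


class Actor:
    """Per-muscle linear action read-out a_m = sum_i w_im b_i, zero-initialized."""

    def __init__(self, K: int, n_muscles: int):
        self.w = np.zeros((K, n_muscles))

    def action(self, b: np.ndarray) -> np.ndarray:
        return b @ self.w


def save_snapshot(path, grid: BasisGrid, critic: Critic, actor: Actor,
                  meta: dict | None = None) -> None:
    """Lossless JSON snapshot of grid definition and weights."""
    payload = {
        "grid": grid.to_dict(),
        "v": critic.v.tolist(),
        "w": actor.w.tolist(),
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_snapshot(path) -> tuple[BasisGrid, Critic, Actor, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    grid = BasisGrid.from_dict(payload["grid"])
    v = np.asarray(payload["v"], float)
    w = np.asarray(payload["w"], float)
    critic = Critic(len(v))
    critic.v = v
    actor = Actor(w.shape[0], w.shape[1])
    actor.w = w
    return grid, critic, actor, payload.get("meta", {})
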