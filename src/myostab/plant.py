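"""Gravity-loaded rigid-link chain actuated by muscle action lines.

Joint angles are exposed in degrees throughout the public API (all the
printed ranges and basis widths are in degrees); conversion to radians is
localized in :func:`deg2rad`.  Muscle geometry uses a constant-moment-arm
linearization: with signed arm ``r_j`` (metres) about joint ``j``,

    l = l_ref - sum_j r_j * (theta_j - theta_ref_j)      [theta in radians]

so a muscle *shortens* when a joint moves in the direction of a positive
arm, and the torque it applies about that joint is ``+r_j * F`` (a
contracting muscle drives the joints in the direction that shortens it).

Muscle force is simply ``u * F_max`` — no force-length/velocity scaling,
no activation lag, no tendon element.  Integration is semi-implicit Euler
at a fixed step (default 0.01 s); joint stops are hard clamps that zero
the velocity.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

DEFAULT_DT = 0.01


class ConfigurationError(ValueError):
    """A plant definition is internally inconsistent."""


class SimulationDivergedError(RuntimeError):
    """The integrator produced a non-finite state."""


def deg2rad(x):
    return np.asarray(x, dtype=float) * (math.pi / 180.0)


def rad2deg(x):
    return np.asarray(x, dtype=float) * (180.0 / math.pi)


@dataclass
class JointSpec:
    """One hinge-like joint motion of the chain.

    ``gravity_torque_coeff`` sets the applied gravity torque
    ``-coeff * sin(theta)`` (N·m, theta from the vertical), i.e. a positive
    coefficient pulls the joint toward 0 degrees like a hanging pendulum.
    ``reference_angle`` is the angle at which muscle reference lengths are
    measured.
    """

    name: str
    angle_range: tuple[float, float]
    target_angle: float
    inertia: float
    viscous_damping: float = 0.0
    gravity_torque_coeff: float = 0.0
    reference_angle: float = 0.0

    def __post_init__(self):
        self.angle_range = (float(self.angle_range[0]), float(self.angle_range[1]))
        lo, hi = self.angle_range
        if not lo < hi:
            raise ConfigurationError(
                f"joint {self.name!r}: angle_range min must be < max, got {self.angle_range}"
            )
        if not lo <= self.target_angle <= hi:
            raise ConfigurationError(
                f"joint {self.name!r}: target_angle {self.target_angle} outside range {self.angle_range}"
            )
        if not self.inertia > 0:
            raise ConfigurationError(f"joint {self.name!r}: inertia must be > 0")
        if self.viscous_damping < 0:
            raise ConfigurationError(f"joint {self.name!r}: viscous_damping must be >= 0")


@dataclass
class MuscleSpec:
    """A muscle action line with constant signed moment arms (m) per joint.

    ``equilibrium_length`` is the length at the target posture; it is
    filled in by :meth:`Plant.__init__` when left as ``None``.
    """

    name: str
    max_force: float
    reference_length: float
    moment_arms: dict[str, float]
    equilibrium_length: float | None = None

    def __post_init__(self):
        if not self.max_force > 0:
            raise ConfigurationError(f"muscle {self.name!r}: max_force must be > 0")
        if not self.reference_length > 0:
            raise ConfigurationError(f"muscle {self.name!r}: reference_length must be > 0")
        arms = {k: float(v) for k, v in self.moment_arms.items() if float(v) != 0.0}
        if not arms:
            raise ConfigurationError(f"muscle {self.name!r}: needs at least one nonzero moment arm")
        self.moment_arms = arms

    @property
    def is_multiarticular(self) -> bool:
        return len(self.moment_arms) >= 2


@dataclass
class PlantConfig:
    joints: list[JointSpec]
    muscles: list[MuscleSpec]
    gravity_scale: float = 1.0
    dt: float = DEFAULT_DT

    def __post_init__(self):
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate joint names")
        for m in self.muscles:
            unknown = set(m.moment_arms) - set(names)
            if unknown:
                raise ConfigurationError(
                    f"muscle {m.name!r}: moment arms reference unknown joints {sorted(unknown)}"
                )
        if not self.dt > 0:
            raise ConfigurationError("dt must be > 0")

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def target_angles(self) -> np.ndarray:
        return np.array([j.target_angle for j in self.joints])


@dataclass
class PlantState:
    """Instantaneous plant state; ``muscle_lengths`` is always derived."""

    time: float
    angles: np.ndarray      # degrees, one per joint
    velocities: np.ndarray  # degrees/s
    muscle_lengths: np.ndarray  # metres, one per muscle

    def copy(self) -> "PlantState":
        return PlantState(
            self.time, self.angles.copy(), self.velocities.copy(), self.muscle_lengths.copy()
        )


def muscle_length(muscle: MuscleSpec, angles: Mapping[str, float],
                  reference_angles: Mapping[str, float] | None = None) -> float:
    """Length of one muscle at the given joint angles (degrees).

    Standalone scalar version of the linear length model; the vectorized
    path lives in :meth:`Plant.muscle_lengths`.
    """
    ref = reference_angles or {}
    d = 0.0
    for joint, arm in muscle.moment_arms.items():
        d += arm * float(deg2rad(angles[joint] - ref.get(joint, 0.0)))
    length = muscle.reference_length - d
    if length <= 0:
        raise ConfigurationError(
            f"muscle {muscle.name!r}: computed non-positive length {length:.4g} m "
            "(moment arms too large for the angle range)"
        )
    return length


def length_rate(muscle: MuscleSpec, angles: Mapping[str, float],
                reference_angles: Mapping[str, float] | None = None) -> float:
    """Dimensionless fractional length change (l - l0)/l0 of one muscle."""
    if muscle.equilibrium_length is None:
        raise ConfigurationError(f"muscle {muscle.name!r}: equilibrium_length not set")
    return (muscle_length(muscle, angles, reference_angles) - muscle.equilibrium_length) / muscle.equilibrium_length


class Plant:
    """Vectorized forward simulator for a :class:`PlantConfig`."""

    def __init__(self, config: PlantConfig):
        self.config = config
        j = config.joints
        self.n_joints = len(j)
        self.n_muscles = len(config.muscles)
        self.joint_names = config.joint_names
        self.muscle_names = config.muscle_names
        self._jidx = {name: i for i, name in enumerate(self.joint_names)}
        self.inertia = np.array([x.inertia for x in j])
        self.damping = np.array([x.viscous_damping for x in j])
        self.gravity = np.array([x.gravity_torque_coeff for x in j]) * config.gravity_scale
        self.range_lo = np.array([x.angle_range[0] for x in j])
        self.range_hi = np.array([x.angle_range[1] for x in j])
        self.targets = config.target_angles
        self.ref_angles = np.array([x.reference_angle for x in j])
        # (M, J) signed moment arm matrix
        self.arms = np.zeros((self.n_muscles, self.n_joints))
        for mi, m in enumerate(config.muscles):
            for joint, arm in m.moment_arms.items():
                self.arms[mi, self._jidx[joint]] = arm
        self.max_force = np.array([m.max_force for m in config.muscles])
        self.ref_lengths = np.array([m.reference_length for m in config.muscles])
        self.dt = config.dt
        # equilibrium lengths at the target posture, filled back into the specs
        l0 = self.muscle_lengths(self.targets)
        for m, l in zip(config.muscles, l0):
            if m.equilibrium_length is None:
                m.equilibrium_length = float(l)
        self.equilibrium_lengths = np.array([m.equilibrium_length for m in config.muscles])
        # sanity: positive lengths over the whole admissible box (corner check
        # suffices for a linear length model)
        self._check_positive_lengths()

    def _check_positive_lengths(self):
        lo_r, hi_r = deg2rad(self.range_lo - self.ref_angles), deg2rad(self.range_hi - self.ref_angles)
        # worst-case excursion per muscle: each joint moved to whichever end
        # maximizes the length drop
        drop = np.where(self.arms > 0, self.arms * hi_r, self.arms * lo_r).sum(axis=1)
        worst = self.ref_lengths - drop
        if np.any(worst <= 0):
            bad = [self.muscle_names[i] for i in np.where(worst <= 0)[0]]
            raise ConfigurationError(
                f"muscles {bad} reach non-positive length inside the angle ranges"
            )

    # ---- kinematics -------------------------------------------------------

    def muscle_lengths(self, angles_deg: np.ndarray) -> np.ndarray:
        d = deg2rad(np.asarray(angles_deg, dtype=float) - self.ref_angles)
        lengths = self.ref_lengths - self.arms @ d
        if np.any(lengths <= 0):
            bad = self.muscle_names[int(np.argmin(lengths))]
            raise ConfigurationError(f"muscle {bad!r}: non-positive length at angles {angles_deg}")
        return lengths

    def length_rates(self, angles_deg: np.ndarray) -> np.ndarray:
        return (self.muscle_lengths(angles_deg) - self.equilibrium_lengths) / self.equilibrium_lengths

    # ---- dynamics ---------------------------------------------------------

    def initial_state(self, angles_deg: Sequence[float],
                      velocities_degps: Sequence[float] | None = None) -> PlantState:
        ang = np.array(angles_deg, dtype=float)
        if np.any(ang < self.range_lo) or np.any(ang > self.range_hi):
            warnings.warn("initial angles clamped to joint ranges")
            ang = np.clip(ang, self.range_lo, self.range_hi)
        vel = np.zeros(self.n_joints) if velocities_degps is None else np.array(velocities_degps, float)
        return PlantState(0.0, ang, vel, self.muscle_lengths(ang))

    def muscle_torques(self, activations: np.ndarray) -> np.ndarray:
        """Net joint torques (N·m) from the given activations in [0, 1]."""
        return self.arms.T @ (np.asarray(activations, float) * self.max_force)

    def gravity_torques(self, angles_deg: np.ndarray) -> np.ndarray:
        return -self.gravity * np.sin(deg2rad(angles_deg))

    def step(self, state: PlantState, activations: np.ndarray, dt: float | None = None) -> PlantState:
        dt = self.dt if dt is None else dt
        u = np.clip(np.asarray(activations, float), 0.0, 1.0)
        th = deg2rad(state.angles)
        om = deg2rad(state.velocities)
        tau = self.muscle_torques(u) + self.gravity_torques(state.angles) - self.damping * om
        om_new = om + dt * tau / self.inertia
        th_new = th + dt * om_new
        ang = rad2deg(th_new)
        vel = rad2deg(om_new)
        # hard stops: clamp and kill velocity at the limit
        below = ang < self.range_lo
        above = ang > self.range_hi
        ang = np.where(below, self.range_lo, np.where(above, self.range_hi, ang))
        vel = np.where(below | above, 0.0, vel)
        if not (np.all(np.isfinite(ang)) and np.all(np.isfinite(vel))):
            bad = int(np.argmax(~(np.isfinite(ang) & np.isfinite(vel))))
            raise SimulationDivergedError(
                f"non-finite state at joint {self.joint_names[bad]!r}, t={state.time + dt:.3f}s"
            )
        return PlantState(state.time + dt, ang, vel, self.muscle_lengths(ang))

    def mechanical_energy(self, state: PlantState) -> float:
        """Kinetic plus gravitational potential energy (J), passive plant."""
        om = deg2rad(state.velocities)
        ke = 0.5 * float(np.sum(self.inertia * om ** 2))
        pe = float(np.sum(self.gravity * (1.0 - np.cos(deg2rad(state.angles)))))
        return ke + pe


# ---- serialization --------------------------------------------------------

def config_to_dict(config: PlantConfig) -> dict:
    return {
        "gravity_scale": config.gravity_scale,
        "dt": config.dt,
        "joints": [
            {
                "name": j.name,
                "angle_range": list(j.angle_range),
                "target_angle": j.target_angle,
                "inertia": j.inertia,
                "viscous_damping": j.viscous_damping,
                "gravity_torque_coeff": j.gravity_torque_coeff,
                "reference_angle": j.reference_angle,
            }
            for j in config.joints
        ],
        "muscles": [
            {
                "name": m.name,
                "max_force": m.max_force,
                "reference_length": m.reference_length,
                "moment_arms": dict(m.moment_arms),
                "equilibrium_length": m.equilibrium_length,
            }
            for m in config.muscles
        ],
    }


def config_from_dict(data: Mapping) -> PlantConfig:
    joints = [JointSpec(
        name=d["name"],
        angle_range=tuple(d["angle_range"]),
        target_angle=float(d["target_angle"]),
        inertia=float(d["inertia"]),
        viscous_damping=float(d.get("viscous_damping", 0.0)),
        gravity_torque_coeff=float(d.get("gravity_torque_coeff", 0.0)),
        reference_angle=float(d.get("reference_angle", 0.0)),
    ) for d in data["joints"]]
    muscles = [MuscleSpec(
        name=d["name"],
        max_force=float(d["max_force"]),
        reference_length=float(d["reference_length"]),
        moment_arms=dict(d["moment_arms"]),
        equilibrium_length=(None if d.get("equilibrium_length") is None
                            else float(d["equilibrium_length"])),
    ) for d in data["muscles"]]
    return PlantConfig(
        joints=joints,
        muscles=muscles,
        gravity_scale=float(data.get("gravity_scale", 1.0)),
        dt=float(data.get("dt", DEFAULT_DT)),
    )


def save_config(config: PlantConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> PlantConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def write_trajectory_csv(path, times, angles, velocities, joint_names) -> None:
    """CSV with columns time_s, <joint>_deg ..., <joint>_degps ..., one row per step."""
    angles = np.asarray(angles)
    velocities = np.asarray(velocities)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + [f"{n}_deg" for n in joint_names] + [f"{n}_degps" for n in joint_names])
        for t, a, v in zip(times, angles, velocities):
            w.writerow([f"{t:.3f}"] + [f"{x:.6f}" for x in a] + [f"{x:.6f}" for x in v])
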