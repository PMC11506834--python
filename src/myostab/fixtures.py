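"""Desk-scale plant fixtures.

These stand in for a full anthropometric model: each controlled joint
motion is a damped, gravity-loaded hinge driven by an antagonist muscle
pair, plus multiarticular muscles that couple joints.  Targets are the
neutral-body-posture angles and the angle ranges are the printed
anatomical ranges (the knee inversion-eversion range is widened at the
top so its target is attainable).

Inertias, damping, gravity coefficients and muscle forces are artifact
choices, not published values; they are sized so a limb settles well
inside a 2 s episode (near-critically damped about the target, natural
frequency ~8 rad/s).

Contribution tables for joint-angle feedback are generated from the
moment-arm signs: the agonist of the angle-decreasing motion gets -0.5,
the angle-increasing one +0.5, and multiarticular muscles get +/-0.2 on
the joints they span (synergists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcm import AGONIST, SYNERGIST, ContributionTable
from .plant import ConfigurationError, JointSpec, MuscleSpec, Plant, PlantConfig

# neutral-body-posture target angles (degrees)
UPPER_NBP = {"ELV": -88.0, "ELW": 0.0, "SHU": -39.0, "SHV": -36.0, "SHW": 36.0}
LOWER_NBP = {"KNV": 43.0, "KNW": 20.0, "HPU": -12.0, "HPV": -52.0, "HPW": -9.0}

# printed anatomical angle ranges (degrees); KNW widened from (-40, 10) so
# the 20 deg target lies inside the admissible range
UPPER_RANGES = {"ELV": (-135.0, 17.0), "ELW": (0.0, 180.0), "SHU": (-120.0, 40.0),
                "SHV": (-170.0, 50.0), "SHW": (-90.0, 70.0)}
LOWER_RANGES = {"KNV": (-10.0, 150.0), "KNW": (-40.0, 30.0), "HPU": (-80.0, 30.0),
                "HPV": (-140.0, 20.0), "HPW": (-50.0, 40.0)}

PAIR_REF_LENGTH = 0.25   # m, mono-articular reference length
BIART_REF_LENGTH = 0.30  # m, multiarticular reference length


@dataclass
class Fixture:
    name: str
    config: PlantConfig
    table: ContributionTable

    @property
    def plant(self) -> Plant:
        return Plant(self.config)


def _joint(name, nbp, ranges, inertia, damping, gravity) -> JointSpec:
    return JointSpec(name=name, angle_range=ranges[name], target_angle=nbp[name],
                     inertia=inertia, viscous_damping=damping,
                     gravity_torque_coeff=gravity, reference_angle=nbp[name])


def _pair(joint: str, arm: float, force: float,
          names: tuple[str, str] | None = None) -> list[MuscleSpec]:
    """Antagonist pair with equal and opposite arms about one joint."""
    lo, hi = names or (f"{joint.lower()}_neg", f"{joint.lower()}_pos")
    return [
        MuscleSpec(lo, force, PAIR_REF_LENGTH, {joint: -arm}),
        MuscleSpec(hi, force, PAIR_REF_LENGTH, {joint: +arm}),
    ]


def _upper_config() -> PlantConfig:
    # Muscle forces are sized so the stretch-feedback spring still holds the
    # limb when the learner settles into its low co-activation regime (a few
    # per cent of the ceiling); gravity coefficients are small relative to
    # that suppressed torque scale or no activation level could hold posture.
    joints = [
        _joint("ELV", UPPER_NBP, UPPER_RANGES, 0.070, 0.60, 0.008),
        _joint("ELW", UPPER_NBP, UPPER_RANGES, 0.018, 0.15, 0.002),
        _joint("SHU", UPPER_NBP, UPPER_RANGES, 0.045, 0.38, 0.005),
        _joint("SHV", UPPER_NBP, UPPER_RANGES, 0.160, 1.40, 0.020),
        _joint("SHW", UPPER_NBP, UPPER_RANGES, 0.045, 0.38, 0.006),
    ]
    muscles = (
        _pair("ELV", 0.060, 650.0, ("elv_flex", "elv_ext"))
        + _pair("ELW", 0.040, 375.0, ("elw_inv", "elw_ev"))
        + _pair("SHU", 0.050, 600.0, ("shu_erot", "shu_irot"))
        + _pair("SHV", 0.070, 1100.0, ("shv_flex", "shv_ext"))
        + _pair("SHV", 0.040, 250.0, ("shv_flex2", "shv_ext2"))
        + _pair("SHW", 0.050, 600.0, ("shw_ev", "shw_inv"))
        + [
            # biarticular antagonists spanning elbow and shoulder flexion
            MuscleSpec("biart_flex", 150.0, BIART_REF_LENGTH,
                       {"ELV": -0.024, "SHV": -0.020}),
            MuscleSpec("biart_ext", 150.0, BIART_REF_LENGTH,
                       {"ELV": +0.024, "SHV": +0.020}),
        ]
    )
    return PlantConfig(joints=joints, muscles=muscles)


def _lower_config() -> PlantConfig:
    joints = [
        _joint("KNV", LOWER_NBP, LOWER_RANGES, 0.070, 0.60, 0.008),
        _joint("KNW", LOWER_NBP, LOWER_RANGES, 0.012, 0.10, 0.002),
        _joint("HPU", LOWER_NBP, LOWER_RANGES, 0.045, 0.38, 0.005),
        _joint("HPV", LOWER_NBP, LOWER_RANGES, 0.160, 1.40, 0.015),
        _joint("HPW", LOWER_NBP, LOWER_RANGES, 0.045, 0.38, 0.005),
    ]
    muscles = (
        _pair("KNV", 0.060, 650.0, ("knv_ext", "knv_flex"))
        + _pair("KNW", 0.024, 330.0, ("knw_ev", "knw_inv"))
        + _pair("HPU", 0.050, 600.0, ("hpu_erot", "hpu_irot"))
        + _pair("HPV", 0.070, 1100.0, ("hpv_flex", "hpv_ext"))
        + _pair("HPV", 0.040, 250.0, ("hpv_flex2", "hpv_ext2"))
        + _pair("HPW", 0.050, 600.0, ("hpw_ev", "hpw_inv"))
        + [
            # hip/knee biarticular antagonists (rectus/hamstring analogs)
            MuscleSpec("biart_rect", 150.0, BIART_REF_LENGTH,
                       {"HPV": -0.024, "KNV": -0.020}),
            MuscleSpec("biart_ham", 150.0, BIART_REF_LENGTH,
                       {"HPV": +0.024, "KNV": +0.020}),
            # knee-spanning biarticular muscles with asymmetric arms about
            # the inversion axis: their co-activation biases KNW at every
            # activation level, the mechanistic counterpart of the knee
            # inversion-eversion stabilization failure
            MuscleSpec("biart_gas_med", 320.0, BIART_REF_LENGTH,
                       {"KNV": +0.003, "KNW": +0.018}),
            MuscleSpec("biart_gas_lat", 320.0, BIART_REF_LENGTH,
                       {"KNV": +0.003, "KNW": -0.004}),
        ]
    )
    return PlantConfig(joints=joints, muscles=muscles)


def _two_link_config() -> PlantConfig:
    joints = [
        JointSpec("SH", (-90.0, 90.0), -30.0, 0.060, 0.51, 0.008, reference_angle=-30.0),
        JointSpec("EL", (-120.0, 60.0), 20.0, 0.030, 0.25, 0.005, reference_angle=20.0),
    ]
    muscles = (
        _pair("SH", 0.060, 550.0, ("sh_flex", "sh_ext"))
        + _pair("EL", 0.060, 275.0, ("el_flex", "el_ext"))
        + [
            MuscleSpec("biart_flex", 100.0, BIART_REF_LENGTH, {"SH": -0.024, "EL": -0.020}),
            MuscleSpec("biart_ext", 100.0, BIART_REF_LENGTH, {"SH": +0.024, "EL": +0.020}),
        ]
    )
    return PlantConfig(joints=joints, muscles=muscles)


def make_contribution_table(config: PlantConfig) -> ContributionTable:
    """Agonist/synergist table from moment-arm signs (see module docstring)."""
    motions = config.joint_names
    muscles = config.muscle_names
    mat = np.zeros((len(muscles), len(motions)))
    for mi, m in enumerate(config.muscles):
        mono = len(m.moment_arms) == 1
        for joint, arm in m.moment_arms.items():
            mag = AGONIST if mono else SYNERGIST
            mat[mi, motions.index(joint)] = mag * np.sign(arm)
    return ContributionTable(muscles, motions, mat)


_BUILDERS = {
    "upper_limb_analog": _upper_config,
    "lower_limb_analog": _lower_config,
    "two_link_arm": _two_link_config,
}

FIXTURE_NAMES = tuple(_BUILDERS)


def apply_overrides(config: PlantConfig, overrides: dict) -> PlantConfig:
    """Override joint/muscle fields or the gravity scale by name."""
    for jname, fields in (overrides.get("joints") or {}).items():
        matches = [j for j in config.joints if j.name == jname]
        if not matches:
            raise ConfigurationError(f"override names unknown joint {jname!r}")
        for k, v in fields.items():
            if not hasattr(matches[0], k):
                raise ConfigurationError(f"joint {jname!r}: unknown field {k!r}")
            setattr(matches[0], k, tuple(v) if k == "angle_range" else v)
        matches[0].__post_init__()
    for mname, fields in (overrides.get("muscles") or {}).items():
        matches = [m for m in config.muscles if m.name == mname]
        if not matches:
            raise ConfigurationError(f"override names unknown muscle {mname!r}")
        for k, v in fields.items():
            if not hasattr(matches[0], k):
                raise ConfigurationError(f"muscle {mname!r}: unknown field {k!r}")
            setattr(matches[0], k, v)
        matches[0].__post_init__()
    if "gravity_scale" in overrides:
        config.gravity_scale = float(overrides["gravity_scale"])
    return config


def build(name: str, overrides: dict | None = None) -> Fixture:
    """Build a named fixture; raises on unknown names or inconsistent overrides."""
    if name not in _BUILDERS:
        raise ConfigurationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    config = _BUILDERS[name]()
    if overrides:
        config = apply_overrides(config, overrides)
    Plant(config)  # validates geometry (positive lengths) and fills l0
    validate_controllability(config)
    return Fixture(name, config, make_contribution_table(config))


def validate_controllability(config: PlantConfig) -> None:
    """Every joint must be spanned by muscles pulling in both directions."""
    for j in config.joint_names:
        arms = [m.moment_arms.get(j, 0.0) for m in config.muscles]
        if not (any(a > 0 for a in arms) and any(a < 0 for a in arms)):
            raise ConfigurationError(f"joint {j!r} lacks an antagonist muscle pair")


def random_plant(rng: np.random.Generator, n_joints: int | None = None) -> PlantConfig:
    """Small randomized but valid plant for property tests."""
    n = int(n_joints or rng.integers(1, 4))
    joints, muscles = [], []
    for i in range(n):
        lo = float(rng.uniform(-90, -20))
        hi = float(rng.uniform(20, 90))
        trg = float(rng.uniform(lo + 5, hi - 5))
        joints.append(JointSpec(
            name=f"J{i}", angle_range=(lo, hi), target_angle=trg,
            inertia=float(rng.uniform(0.01, 0.1)),
            viscous_damping=float(rng.uniform(0.1, 1.0)),
            gravity_torque_coeff=float(rng.uniform(0.0, 0.3)),
            reference_angle=trg))
        arm = float(rng.uniform(0.01, 0.03))
        force = float(rng.uniform(50, 300))
        muscles += _pair(f"J{i}", arm, force, (f"j{i}_neg", f"j{i}_pos"))
    if n >= 2 and rng.random() < 0.5:
        a0, a1 = (float(rng.uniform(0.005, 0.015)) for _ in range(2))
        muscles += [
            MuscleSpec("bi_neg", float(rng.uniform(50, 150)), BIART_REF_LENGTH,
                       {"J0": -a0, "J1": -a1}),
            MuscleSpec("bi_pos", float(rng.uniform(50, 150)), BIART_REF_LENGTH,
                       {"J0": +a0, "J1": +a1}),
        ]
    config = PlantConfig(joints=joints, muscles=muscles)
    Plant(config)
    validate_controllability(config)
    return config


def perturb(config: PlantConfig, rng: np.random.Generator, scale: float = 0.2) -> PlantConfig:
    """Jitter inertias, damping, forces and arms by up to +/-scale,
    preserving signs and hence controllability."""
    from .plant import config_from_dict, config_to_dict

    d = config_to_dict(config)
    for j in d["joints"]:
        j["inertia"] *= 1 + scale * rng.uniform(-1, 1)
        j["viscous_damping"] *= 1 + scale * rng.uniform(-1, 1)
    for m in d["muscles"]:
        m["max_force"] *= 1 + scale * rng.uniform(-1, 1)
        m["moment_arms"] = {k: v * (1 + scale * rng.uniform(-1, 1))
                            for k, v in m["moment_arms"].items()}
        m["equilibrium_length"] = None  # recomputed for the new geometry
    out = config_from_dict(d)
    Plant(out)
    validate_controllability(out)
    return out
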