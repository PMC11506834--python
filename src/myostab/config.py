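"""Run configuration: YAML schema, validation, defaults and provenance.

A run config fully determines a training or prediction run.  Every field
has a default; defaults that reproduce published hyperparameters are
tagged ``published default`` in :data:`PROVENANCE`, everything else is an
``artifact choice``.  Unknown keys anywhere in the document are rejected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .acrl import LearnerParams
from .experiments import REPORT_TRIALS
from .fcm import ML_SIGNS, FeedbackModel
from .fixtures import FIXTURE_NAMES


class ConfigError(ValueError):
    """Schema violation in a run config; the message names key and constraint."""


PROVENANCE = {
    "learner.alpha_v": "published default",
    "learner.alpha_a": "published default",
    "learner.tau": "published default",
    "learner.kappa": "published default",
    "learner.c": "published default",
    "learner.sigma_r": "published default",
    "learner.A": "published default",
    "learner.B": "published default",
    "learner.u_max_default": "published default",
    "learner.dt": "published default",
    "protocol.episode_length": "published default",
    "protocol.dt": "published default",
    "protocol.n_trials": "published default",
    "protocol.report_trials": "published default",
    "ngn.sigma_angle": "published default",
    "ngn.n_angle": "artifact choice (12 x 12 grid reproduces K = 144)",
    "ngn.n_vel": "artifact choice (12 x 12 grid reproduces K = 144)",
    "ngn.layout": "artifact choice",
    "fcm.kind": "artifact choice",
    "fcm.ml_sign": "artifact choice (printed form vs prose account)",
    "plant": "artifact choice",
    "seed": "artifact choice",
}


@dataclass
class RunConfig:
    plant: str | dict = "upper_limb_analog"     # fixture name, inline dict, or path
    plant_overrides: dict = field(default_factory=dict)
    learner: dict = field(default_factory=dict)  # LearnerParams overrides
    ngn: dict = field(default_factory=dict)      # BasisGrid overrides
    fcm: dict = field(default_factory=dict)      # kind, ml_sign, table
    protocol: dict = field(default_factory=dict)
    reward_targets: dict = field(default_factory=dict)  # joint -> target override
    seed: int = 0
    out_dir: str = "runs"

    def learner_params(self) -> LearnerParams:
        return LearnerParams(**self.learner)


_TOP_KEYS = {"plant", "plant_overrides", "learner", "ngn", "fcm", "protocol",
             "reward_targets", "seed", "out_dir"}
_LEARNER_KEYS = {"alpha_v", "alpha_a", "tau", "kappa", "c", "sigma_r", "A", "B",
                 "u_max_default", "dt"}
_NGN_KEYS = {"n_angle", "n_vel", "sigma_angle", "sigma_vel", "layout"}
_FCM_KEYS = {"kind", "ml_sign", "table"}
_PROTOCOL_KEYS = {"episode_length", "dt", "n_trials", "report_trials", "seed"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def validate(data: dict) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("top level: config must be a mapping")
    _check_keys(data, _TOP_KEYS, "top level")
    _check_keys(data.get("learner") or {}, _LEARNER_KEYS, "learner")
    _check_keys(data.get("ngn") or {}, _NGN_KEYS, "ngn")
    _check_keys(data.get("fcm") or {}, _FCM_KEYS, "fcm")
    _check_keys(data.get("protocol") or {}, _PROTOCOL_KEYS, "protocol")
    fcm = data.get("fcm") or {}
    if "kind" in fcm and fcm["kind"] not in FeedbackModel.KINDS:
        raise ConfigError(f"fcm.kind: must be one of {FeedbackModel.KINDS}")
    if "ml_sign" in fcm and fcm["ml_sign"] not in ML_SIGNS:
        raise ConfigError(f"fcm.ml_sign: must be one of {ML_SIGNS}")
    plant = data.get("plant", "upper_limb_analog")
    if isinstance(plant, str) and "/" not in plant and not plant.endswith(".yaml") \
            and plant not in FIXTURE_NAMES:
        raise ConfigError(f"plant: unknown fixture {plant!r}; choose from {FIXTURE_NAMES} "
                          "or give a YAML path/inline mapping")
    cfg = RunConfig(**{k: data[k] for k in data})
    cfg.learner_params()  # surfaces bad learner values early
    return cfg


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return validate(yaml.safe_load(fh))


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def defaults_summary() -> dict:
    """Fully resolved defaults with provenance, for run metadata files."""
    lp = LearnerParams()
    return {
        "learner": asdict(lp),
        "protocol": {"episode_length": 2.0, "dt": 0.01, "n_trials": 300,
                     "report_trials": list(REPORT_TRIALS)},
        "provenance": dict(PROVENANCE),
    }
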