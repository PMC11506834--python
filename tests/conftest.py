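import numpy as np
import pytest

from myostab.acrl import Learner, LearnerParams
from myostab.experiments import TrialProtocol, run_training
from myostab.fcm import FeedbackModel
from myostab.fixtures import build
from myostab.ngn import BasisGrid


class ZeroNoiseRng:
    """Stub generator: noise identically zero (turns exploration off)."""

    def uniform(self, lo, hi, size=None):
        return np.zeros(size) if size is not None else 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def upper_fixture():
    return build("upper_limb_analog")


@pytest.fixture(scope="session")
def lower_fixture():
    return build("lower_limb_analog")


@pytest.fixture(scope="session")
def two_link_fixture():
    return build("two_link_arm")


def make_learner(plant, **grid_kwargs):
    grid = BasisGrid(n_motions=plant.n_joints, **grid_kwargs)
    return Learner(grid, plant.n_muscles, LearnerParams())


def train_condition(fixture_name, kind, seed, ml_sign="narrative", n_trials=300,
                    reward_target_overrides=None):
    """One full training run; returns (plant, learner, TrainingResult)."""
    fx = build(fixture_name)
    plant = fx.plant
    learner = make_learner(plant)
    fbm = FeedbackModel(kind, plant=plant, table=fx.table, ml_sign=ml_sign)
    report = tuple(t for t in (1, 2, 3, 20, 300) if t <= n_trials)
    proto = TrialProtocol(n_trials=n_trials, seed=seed, report_trials=report)
    targets = None
    if reward_target_overrides:
        targets = plant.targets.copy()
        for joint, value in reward_target_overrides.items():
            targets[plant.joint_names.index(joint)] = float(value)
    result = run_training(plant, learner, fbm, proto, targets=targets,
                          keep_report_histories=False,
                          condition={"algorithm": "acrl-ngn", "fcm": kind,
                                     "fixture": fixture_name, "seed": seed})
    return plant, learner, result


@pytest.fixture(scope="session")
def upper_ml_runs():
    """FCM-ML training on the upper analog, seeds 0-2 (shared across tests)."""
    return {seed: train_condition("upper_limb_analog", "ml", seed)
            for seed in (0, 1, 2)}


@pytest.fixture(scope="session")
def upper_ja_runs():
    return {seed: train_condition("upper_limb_analog", "ja", seed)
            for seed in (0, 1, 2)}


@pytest.fixture(scope="session")
def upper_none_runs():
    return {seed: train_condition("upper_limb_analog", "none", seed)
            for seed in (0, 1, 2)}


@pytest.fixture(scope="session")
def lower_ml_runs():
    return {seed: train_condition("lower_limb_analog", "ml", seed)
            for seed in (0, 1, 2)}
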