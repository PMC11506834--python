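"""Training and prediction protocols.

Two modes:

1. repeated 2 s trials (200 steps at 0.01 s) from uniformly random initial
   postures, with weights persisting across trials and traces reset at
   every trial start; a joint motion counts as stabilized when the mean
   signed error over the final 0.2 s of the episode lies within +/-5 deg
   (inclusive);
2. frozen-policy rollouts from fixed initial postures (no weight updates,
   value-modulated noise still active).

Summary rows follow the report-trial layout (1st/2nd/3rd/20th/300th).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acrl import Learner
from .fcm import FeedbackModel
from .ngn import make_state
from .plant import Plant, PlantState, SimulationDivergedError

STAB_TOL_DEG = 5.0
STAB_WINDOW_S = 0.2
REPORT_TRIALS = (1, 2, 3, 20, 300)


@dataclass
class TrialProtocol:
    episode_length: float = 2.0
    dt: float = 0.01
    n_trials: int = 300
    report_trials: tuple[int, ...] = REPORT_TRIALS
    seed: int = 0

    def __post_init__(self):
        n = self.episode_length / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("episode_length must be an integral number of steps")
        if any(t < 1 or t > self.n_trials for t in self.report_trials):
            raise ValueError("report_trials must lie in 1..n_trials")

    @property
    def n_steps(self) -> int:
        return int(round(self.episode_length / self.dt))


@dataclass
class TrialResult:
    trial: int
    initial_angles: np.ndarray
    times: np.ndarray            # (T+1,)
    angles: np.ndarray           # (T+1, J) degrees
    velocities: np.ndarray       # (T+1, J) degrees/s
    activations: np.ndarray      # (T, M)
    rewards: np.ndarray          # (T,)
    deltas: np.ndarray           # (T,)
    values: np.ndarray           # (T,)
    final_errors: np.ndarray     # (J,) windowed mean signed error, degrees
    stabilized: int
    diverged: bool = False


def final_errors(angles: np.ndarray, targets: np.ndarray, dt: float,
                 window: float = STAB_WINDOW_S) -> np.ndarray:
    """Mean signed error per joint over the trailing window of the episode."""
    k = max(1, int(round(window / dt)))
    return np.asarray(angles)[-k:].mean(axis=0) - np.asarray(targets, float)


def count_stabilized(errors: np.ndarray, tol: float = STAB_TOL_DEG) -> int:
    """Joints whose windowed |error| is within tol degrees, inclusive."""
    return int(np.sum(np.abs(np.asarray(errors, float)) <= tol))


def run_trial(plant: Plant, learner: Learner, fbm: FeedbackModel,
              initial_angles: np.ndarray, rng: np.random.Generator | None,
              protocol: TrialProtocol | None = None, trial_index: int = 0,
              targets: np.ndarray | None = None, learn: bool = True,
              record_history: bool = True) -> TrialResult:
    """One 2 s episode.  ``targets`` overrides the reward/state targets
    (the length-feedback equilibrium stays anchored to the plant's own
    target posture).  With ``learn=False`` the weights are left untouched
    (frozen-policy prediction); noise remains active either way.
    """
    proto = protocol or TrialProtocol()
    targets = plant.targets if targets is None else np.asarray(targets, float)
    n_steps = proto.n_steps
    learner.reset_traces()
    state = plant.initial_state(initial_angles)

    J, M = plant.n_joints, plant.n_muscles
    angles = np.empty((n_steps + 1, J))
    vels = np.empty((n_steps + 1, J))
    acts = np.empty((n_steps, M))
    rews = np.empty(n_steps)
    dels = np.empty(n_steps)
    vals = np.empty(n_steps)
    angles[0] = state.angles
    vels[0] = state.velocities

    diverged = False
    t = 0
    for t in range(n_steps):
        s_now = make_state(state.angles, state.velocities, targets)
        u_max = fbm.ceilings(state.angles, s_now)
        u, inter = learner.act(s_now, u_max, rng)
        try:
            new_state = plant.step(state, u)
        except SimulationDivergedError:
            diverged = True
            angles[t + 1:] = state.angles
            vels[t + 1:] = 0.0
            acts[t:] = 0.0
            rews[t:] = np.nan
            dels[t:] = np.nan
            vals[t:] = np.nan
            break
        s_next = make_state(new_state.angles, new_state.velocities, targets)
        if learn:
            rec = learner.learn(inter, u, s_now, s_next)
            rews[t], dels[t], vals[t] = rec.reward, rec.delta, rec.value
        else:
            from .acrl import reward as _reward
            rews[t] = _reward(s_now, u, learner.params)
            dels[t] = np.nan
            vals[t] = inter["value"]
        acts[t] = u
        angles[t + 1] = new_state.angles
        vels[t + 1] = new_state.velocities
        state = new_state

    times = np.arange(n_steps + 1) * proto.dt
    if diverged:
        errs = np.full(J, np.inf)
        stab = 0
    else:
        errs = final_errors(angles, targets, proto.dt)
        stab = count_stabilized(errs)
    result = TrialResult(trial_index, np.asarray(initial_angles, float), times,
                         angles, vels, acts, rews, dels, vals, errs, stab,
                         diverged)
    if not record_history:
        result.times = result.times[[0, -1]]
        result.angles = result.angles[[0, -1]]
        result.velocities = result.velocities[[0, -1]]
        result.activations = result.activations[:0]
        result.rewards = result.rewards[:0]
        result.deltas = result.deltas[:0]
        result.values = result.values[:0]
        # stabilized/final_errors computed before truncation, unchanged
    return result


@dataclass
class TrainingResult:
    condition: dict
    report_counts: dict[int, int]            # report trial -> stabilized count
    final_errors: np.ndarray                 # (n_trials, J)
    stabilized: np.ndarray                   # (n_trials,)
    snapshots: dict[int, dict]               # report trial -> {"v": ..., "w": ...}
    report_results: dict[int, TrialResult]


def draw_initial_angles(plant: Plant, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(plant.range_lo, plant.range_hi)


def run_training(plant: Plant, learner: Learner, fbm: FeedbackModel,
                 protocol: TrialProtocol, targets: np.ndarray | None = None,
                 keep_report_histories: bool = True,
                 condition: dict | None = None) -> TrainingResult:
    """Sequential trials with persistent weights; snapshots at report trials."""
    ss = np.random.SeedSequence(protocol.seed)
    init_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    n_trials = protocol.n_trials
    J = plant.n_joints
    errs = np.empty((n_trials, J))
    counts = np.empty(n_trials, dtype=int)
    snapshots: dict[int, dict] = {}
    report_results: dict[int, TrialResult] = {}
    report = set(protocol.report_trials)
    for trial in range(1, n_trials + 1):
        init = draw_initial_angles(plant, init_rng)
        res = run_trial(plant, learner, fbm, init, noise_rng, protocol,
                        trial_index=trial, targets=targets,
                        record_history=(keep_report_histories and trial in report))
        errs[trial - 1] = res.final_errors
        counts[trial - 1] = res.stabilized
        if trial in report:
            snapshots[trial] = {"v": learner.critic.v.copy(), "w": learner.actor.w.copy()}
            report_results[trial] = res
    report_counts = {t: int(counts[t - 1]) for t in sorted(report)}
    return TrainingResult(condition or {}, report_counts, errs, counts,
                          snapshots, report_results)


def predict_posture(plant: Plant, learner: Learner, fbm: FeedbackModel,
                    initial_angles: np.ndarray, seed: int = 0,
                    protocol: TrialProtocol | None = None) -> TrialResult:
    """Frozen-policy 2 s rollout from a fixed posture; never mutates weights."""
    rng = np.random.default_rng(seed)
    v_before = learner.critic.v.copy()
    w_before = learner.actor.w.copy()
    res = run_trial(plant, learner, fbm, initial_angles, rng,
                    protocol or TrialProtocol(), learn=False)
    assert np.array_equal(learner.critic.v, v_before)
    assert np.array_equal(learner.actor.w, w_before)
    return res


# ---- summary table --------------------------------------------------------

@dataclass
class SummaryTable:
    """Report-trial stabilized counts, one row per (algorithm, fcm, fixture)."""

    report_trials: tuple[int, ...] = REPORT_TRIALS
    rows: list[dict] = field(default_factory=list)

    def add_row(self, algorithm: str, fcm: str, fixture: str,
                counts: dict[int, int]) -> None:
        self.rows.append({
            "algorithm": algorithm, "fcm": fcm, "fixture": fixture,
            "counts": {int(t): int(counts[t]) for t in self.report_trials},
        })

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {"algorithm": r["algorithm"], "fcm": r["fcm"], "fixture": r["fixture"]}
            rec.update({f"trial_{t}": r["counts"][t] for t in self.report_trials})
            records.append(rec)
        cols = ["algorithm", "fcm", "fixture"] + [f"trial_{t}" for t in self.report_trials]
        return pd.DataFrame(records, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {"report_trials": list(self.report_trials), "rows": self.rows}
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, text_or_path) -> "SummaryTable":
        if isinstance(text_or_path, str) and text_or_path.lstrip().startswith("{"):
            payload = json.loads(text_or_path)
        else:
            with open(text_or_path) as fh:
                payload = json.load(fh)
        table = cls(tuple(payload["report_trials"]))
        for r in payload["rows"]:
            table.add_row(r["algorithm"], r["fcm"], r["fixture"],
                          {int(k): v for k, v in r["counts"].items()})
        return table


def summarize(results: list[TrainingResult],
              report_trials: tuple[int, ...] = REPORT_TRIALS) -> SummaryTable:
    table = SummaryTable(report_trials)
    for res in results:
        cond = res.condition
        table.add_row(cond.get("algorithm", "acrl-ngn"), cond.get("fcm", "?"),
                      cond.get("fixture", "?"), res.report_counts)
    return table
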