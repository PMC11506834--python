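"""Feedback control models that set each muscle's activation ceiling.

Three models:

* muscle-length feedback ("ml"): ceiling from the fractional length
  change relative to the equilibrium length at the target posture;
* joint-angle feedback ("ja"): ceiling from a signed, weighted sum of
  joint-angle errors using an agonist/synergist contribution table;
* none: constant ceiling of 1.

The printed form of the length-feedback law, sig(-500*dl + 5), gives a
*stretched* muscle (dl > 0) a lower ceiling; the prose account of the
mechanism describes the opposite (a stretch reflex, larger dl -> more
activation).  Both are available through ``ml_sign``:
``as_printed`` -> sig(-500*dl + 5); ``narrative`` -> sig(+500*dl + 5).
Neither is endorsed here; the default is the printed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit as sig

from .ngn import StateVector
from .plant import Plant

ML_GAIN = 500.0
ML_OFFSET = 5.0
ML_SIGNS = ("as_printed", "narrative")

AGONIST = 0.5
SYNERGIST = 0.2


class FCMError(ValueError):
    """Feedback-model configuration problem."""


def fcm_ml(delta_l, ml_sign: str = "as_printed"):
    """Activation ceiling from the fractional muscle length change."""
    if ml_sign not in ML_SIGNS:
        raise FCMError(f"ml_sign must be one of {ML_SIGNS}, got {ml_sign!r}")
    slope = -ML_GAIN if ml_sign == "as_printed" else ML_GAIN
    return sig(slope * np.asarray(delta_l, float) + ML_OFFSET)


def fcm_none():
    return 1.0


@dataclass
class ContributionTable:
    """Signed percentage contributions pcm of each muscle to each motion.

    Magnitudes are 0.5 for agonists and 0.2 for synergists; zero where the
    muscle does not contribute.  Stored as a dense (muscles x motions)
    matrix with explicit name lists.
    """

    muscles: list[str]
    motions: list[str]
    matrix: np.ndarray  # (M, J)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(self.muscles), len(self.motions)):
            raise FCMError("contribution matrix shape does not match name lists")
        allowed = {0.0, AGONIST, -AGONIST, SYNERGIST, -SYNERGIST}
        vals = set(np.round(np.abs(self.matrix), 12).ravel().tolist())
        if not vals <= {0.0, AGONIST, SYNERGIST}:
            raise FCMError(f"contribution magnitudes must be in {sorted(allowed)}")

    def row(self, muscle: str) -> np.ndarray:
        try:
            return self.matrix[self.muscles.index(muscle)]
        except ValueError:
            raise FCMError(f"muscle {muscle!r} absent from contribution table") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.muscles, columns=self.motions)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="muscle")

    @classmethod
    def from_csv(cls, path) -> "ContributionTable":
        df = pd.read_csv(path, index_col="muscle")
        return cls(list(df.index), list(df.columns), df.to_numpy(float))


def fcm_ja(s: StateVector, table: ContributionTable, muscle: str) -> float:
    """Ceiling sig(sum_jm pcm * dtheta_jm) for one muscle (dtheta in deg)."""
    return float(sig(table.row(muscle) @ s.dtheta))


class FeedbackModel:
    """Vectorized ceiling provider for a whole plant, kind 'ml'|'ja'|'none'."""

    KINDS = ("ml", "ja", "none")

    def __init__(self, kind: str, plant: Plant | None = None,
                 table: ContributionTable | None = None,
                 ml_sign: str = "as_printed"):
        if kind not in self.KINDS:
            raise FCMError(f"fcm kind must be one of {self.KINDS}, got {kind!r}")
        if kind == "ml":
            if plant is None:
                raise FCMError("fcm 'ml' needs the plant for muscle lengths")
            if ml_sign not in ML_SIGNS:
                raise FCMError(f"ml_sign must be one of {ML_SIGNS}, got {ml_sign!r}")
        if kind == "ja":
            if table is None:
                raise FCMError("fcm 'ja' needs a contribution table")
            if plant is not None:
                missing = set(plant.muscle_names) - set(table.muscles)
                if missing:
                    raise FCMError(f"muscles missing from contribution table: {sorted(missing)}")
                self._perm = [table.muscles.index(m) for m in plant.muscle_names]
                self._motion_perm = [table.motions.index(j) for j in plant.joint_names]
        self.kind = kind
        self.plant = plant
        self.table = table
        self.ml_sign = ml_sign

    def ceilings(self, angles_deg: np.ndarray, s: StateVector) -> np.ndarray:
        """Per-muscle u_max for the current plant angles / error state."""
        if self.kind == "none":
            n = self.plant.n_muscles if self.plant is not None else len(s.dtheta)
            return np.ones(n)
        if self.kind == "ml":
            return fcm_ml(self.plant.length_rates(angles_deg), self.ml_sign)
        mat = self.table.matrix[np.ix_(self._perm, self._motion_perm)]
        return sig(mat @ s.dtheta)
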