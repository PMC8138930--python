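"""Kinematics of a patient in six-dimensional vital-sign space.

A patient at hour t is a point r_A(t) whose coordinates are the six
(normalized) vital signs.  A single static *sepsis position* r_B — the
component-wise median of the positive patients' vitals at their sepsis
onset — acts as the target of the motion.  With a one-hour sampling step
the relative kinematics are plain first differences:

    r_{A/B}(t) = r_A(t) - r_B
    v_{A/B}(t) = r_{A/B}(t) - r_{A/B}(t-1)          (= the patient's own velocity,
    a_{A/B}(t) = v_{A/B}(t) - v_{A/B}(t-1)             since r_B is static)

The eight *kinematics features* per hour are the unit vector
e(t) = r_{A/B}(t) / |r_{A/B}(t)| (six components) plus the scalar
projections ProjV = v_{A/B} . e and ProjA = a_{A/B} . e.  A negative ProjV
means the patient is closing in on the sepsis position; a positive one,
moving away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import PatientSeries
from .psv import VITAL_SIGNS

#: Column names of the per-hour kinematics feature matrix.
KF_COLUMNS: tuple[str, ...] = (
    "e.HR", "e.O2Sat", "e.Temp", "e.SBP", "e.DBP", "e.Resp", "ProjV", "ProjA",
)

#: Distances below this are treated as "patient at the sepsis point".
ZERO_DISTANCE_EPS = 1e-12


@dataclass
class SepsisPosition:
    """The estimated target point in vital-sign space.

    ``components`` follow the canonical sign order; ``estimator`` records how
    the point was built (only the static median-at-onset is implemented, but
    the tag leaves room for moving or per-group variants).
    """

    components: np.ndarray
    n_positives_used: int
    estimator: str = "median_at_onset"

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (len(VITAL_SIGNS),):
            raise ValueError("sepsis position needs one component per vital sign")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "components": dict(zip(VITAL_SIGNS, map(float, self.components))),
            "n_positives_used": self.n_positives_used,
            "estimator": self.estimator,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SepsisPosition":
        payload = json.loads(Path(path).read_text())
        comps = [payload["components"][s] for s in VITAL_SIGNS]
        return cls(np.array(comps), payload["n_positives_used"], payload["estimator"])


@dataclass
class RelativeKinematics:
    """Per-hour relative position/velocity/acceleration and distance."""

    position: np.ndarray      # (T, 6) patient minus sepsis point
    distance: np.ndarray      # (T,)  Euclidean norm of position
    velocity: np.ndarray      # (T, 6) first difference; v(0) = 0
    acceleration: np.ndarray  # (T, 6) second difference; a(0) = a(1) = 0


@dataclass
class KinematicsMatrix:
    """A patient's (48, 8) kinematics feature matrix with its label."""

    patient_id: str
    values: np.ndarray
    label: int
    columns: tuple[str, ...] = field(default=KF_COLUMNS)


def estimate_sepsis_position(
    positives: Sequence[PatientSeries] | Sequence[np.ndarray],
    onset_rows: Sequence[int] | None = None,
) -> SepsisPosition:
    """Median of the positive patients' vital signs at sepsis onset.

    ``positives`` may be windowed :class:`PatientSeries` (onset defaults to
    the last row, where onset-truncated windows place it) or raw matrices
    with explicit per-patient ``onset_rows``.  Even counts take the midpoint
    of the two central order statistics.
    """
    if len(positives) == 0:
        raise ValueError("sepsis position needs at least one positive patient")
    onset_values = []
    for i, p in enumerate(positives):
        matrix = p.matrix if isinstance(p, PatientSeries) else np.asarray(p, float)
        row = onset_rows[i] if onset_rows is not None else len(matrix) - 1
        onset_values.append(matrix[row])
    components = np.median(np.stack(onset_values), axis=0)
    return SepsisPosition(components, n_positives_used=len(positives))


def unit_vector(relative_position: np.ndarray, distance: float) -> np.ndarray:
    """Direction from the sepsis point to the patient; zero vector at distance ~0."""
    if distance <= ZERO_DISTANCE_EPS:
        return np.zeros_like(np.asarray(relative_position, dtype=float))
    return np.asarray(relative_position, dtype=float) / distance


def project_onto_unit(vector: np.ndarray, unit: np.ndarray) -> float:
    """Scalar projection of ``vector`` onto a unit (or zero) direction."""
    return float(np.dot(vector, unit))


def relative_kinematics(
    series: PatientSeries | np.ndarray, sepsis: SepsisPosition
) -> RelativeKinematics:
    """Relative position, distance, velocity and acceleration over the window.

    First differences use a one-hour step; the boundary convention v(0) = 0
    and a(0) = a(1) = 0 keeps every output the full window length.
    """
    matrix = series.matrix if isinstance(series, PatientSeries) else np.asarray(series, float)
    position = matrix - sepsis.components
    distance = np.linalg.norm(position, axis=1)
    velocity = np.zeros_like(position)
    velocity[1:] = position[1:] - position[:-1]
    acceleration = np.zeros_like(position)
    acceleration[2:] = velocity[2:] - velocity[1:-1]
    return RelativeKinematics(position, distance, velocity, acceleration)


def assemble_kf(series: PatientSeries, sepsis: SepsisPosition) -> KinematicsMatrix:
    """Build the per-hour 8-column kinematics feature matrix for one patient.

    Columns 1-6 are the unit relative-position vector, column 7 the velocity
    projection ProjV, column 8 the acceleration projection ProjA.
    """
    rel = relative_kinematics(series, sepsis)
    t_len = len(rel.position)
    out = np.zeros((t_len, len(KF_COLUMNS)))
    for t in range(t_len):
        e = unit_vector(rel.position[t], rel.distance[t])
        out[t, :6] = e
        out[t, 6] = project_onto_unit(rel.velocity[t], e)
        out[t, 7] = project_onto_unit(rel.acceleration[t], e)
    return KinematicsMatrix(series.patient_id, out, series.label)


def cohort_kf(
    cohort: Sequence[PatientSeries], sepsis: SepsisPosition
) -> list[KinematicsMatrix]:
    """Kinematics features for every patient against one shared sepsis point."""
    return [assemble_kf(s, sepsis) for s in cohort]
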