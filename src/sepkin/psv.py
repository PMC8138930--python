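"""Reading and writing per-patient hourly records in the pipe-separated dialect.

Each patient is one ``.psv`` file: a pipe-separated header line followed by
one line per hour.  Files may carry dozens of clinical columns; this package
uses the six bedside vital signs (:data:`VITAL_SIGNS`) plus the binary
``SepsisLabel`` column and ignores the rest.  Missing measurements are the
literal ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The six monitored vital signs, in canonical column order:
#: heart rate (beats/min), pulse oximetry (%), temperature (degC),
#: systolic and diastolic blood pressure (mm Hg), respiration rate (breaths/min).
VITAL_SIGNS: tuple[str, ...] = ("HR", "O2Sat", "Temp", "SBP", "DBP", "Resp")

#: Per-row binary sepsis flag column.
LABEL_COLUMN = "SepsisLabel"


class PsvFormatError(ValueError):
    """A patient file violates the pipe-separated dialect or schema."""


@dataclass
class RawPatientRecord:
    """One patient's hourly record as read from disk.

    ``frame`` holds every declared column as float (missing -> NaN), one row
    per hour in original order; the implicit row index is the hour 0..T-1.
    """

    patient_id: str
    frame: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def read_patient_file(path: str | Path) -> RawPatientRecord:
    """Parse one pipe-separated patient file.

    Unparseable numeric cells and the literal ``NaN`` become missing values.
    Raises :class:`PsvFormatError` naming the column if any of the six vital
    signs or the label column is absent, and on empty files.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="|", header=0)
    except pd.errors.EmptyDataError as exc:
        raise PsvFormatError(f"{path}: empty file") from exc
    missing = [c for c in (*VITAL_SIGNS, LABEL_COLUMN) if c not in frame.columns]
    if missing:
        raise PsvFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    frame = frame.apply(pd.to_numeric, errors="coerce").astype(float)
    labels = frame[LABEL_COLUMN].to_numpy()
    observed = labels[~np.isnan(labels)]
    if not np.isin(observed, (0.0, 1.0)).all():
        raise PsvFormatError(f"{path}: {LABEL_COLUMN} values must be 0 or 1")
    return RawPatientRecord(patient_id=path.stem, frame=frame)


def write_patient_file(record: RawPatientRecord, path: str | Path) -> None:
    """Write a record back to the pipe-separated dialect (missing -> ``NaN``).

    Round-trip safe: ``read_patient_file(write_patient_file(r))`` reproduces
    values, missingness pattern and column order.
    """
    record.frame.to_csv(path, sep="|", index=False, na_rep="NaN")


def extract_vitals(record: RawPatientRecord) -> tuple[np.ndarray, np.ndarray]:
    """Select the six-vital-sign sub-table and the aligned label sequence.

    Returns ``(vitals, labels)`` where ``vitals`` is a (T, 6) float array in
    :data:`VITAL_SIGNS` order and ``labels`` a (T,) 0/1 integer array.  Time
    order and numeric values are untouched; all other columns are dropped.
    A missing label is treated as 0 (no sepsis flag on that row).
    """
    vitals = record.frame[list(VITAL_SIGNS)].to_numpy(dtype=float)
    raw = record.frame[LABEL_COLUMN].to_numpy(dtype=float)
    labels = np.where(np.isnan(raw), 0.0, raw).astype(int)
    return vitals, labels


def truncate_at_onset(
    vitals: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, bool, int | None]:
    """Cut a positive patient's series at sepsis onset.

    Onset is the first row flagged 1; every strictly later row is discarded,
    so for positives the onset becomes the last row of the series.  Negative
    series (no flag) pass through unchanged.

    Returns ``(vitals, is_positive, onset_index)``.
    """
    if len(vitals) != len(labels):
        raise ValueError("labels must align with vitals")
    flagged = np.flatnonzero(np.asarray(labels) == 1)
    if flagged.size == 0:
        return vitals, False, None
    onset = int(flagged[0])
    return vitals[: onset + 1], True, onset
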