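"""Seeded synthetic ICU cohorts in the pipe-separated per-patient dialect.

The generator emulates the statistical structure the kinematics method
assumes, with planted ground truth so every downstream stage is testable
without real data:

* negatives fluctuate around baseline vital signs with AR(1) hourly noise;
* positives follow the same process, but over their final ``drift_hours``
  the mean path moves linearly from baseline to a planted sepsis point, and
  the last row carries the sepsis flag;
* cells go missing at a configurable rate, and a small fraction are replaced
  by out-of-range sensor spikes that the limit-clipping step should catch.

Each patient draws from an independent substream of the master seed, so the
cohort is byte-reproducible and individual patients are unaffected by cohort
composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .psv import LABEL_COLUMN, VITAL_SIGNS, RawPatientRecord

#: Typical resting baselines (sign units): HR, O2Sat, Temp, SBP, DBP, Resp.
DEFAULT_BASELINE = (85.65, 97.39, 37.10, 120.87, 60.26, 18.40)

#: Planted sepsis point: tachycardia, mild desaturation, low-grade fever,
#: hypotension (SBP <= 100) and tachypnea (Resp >= 22) — the classic
#: deteriorating-patient picture.
DEFAULT_SEPSIS_POINT = (98.0, 95.5, 37.9, 90.91, 55.0, 21.65)

#: Marginal AR(1) noise standard deviation per sign.
DEFAULT_NOISE_SIGMA = (5.0, 0.8, 0.17, 6.0, 3.5, 1.5)


@dataclass
class SimConfig:
    """Cohort sizes, drift/noise/corruption parameters and the master seed."""

    n_positive: int = 100
    n_negative: int = 218
    length_range: tuple[int, int] = (30, 120)
    sepsis_point: tuple[float, ...] = DEFAULT_SEPSIS_POINT
    baseline: tuple[float, ...] = DEFAULT_BASELINE
    noise_sigma: tuple[float, ...] = DEFAULT_NOISE_SIGMA
    ar_coeff: float = 0.8
    drift_hours: int = 12
    missing_rate: float = 0.10
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.drift_hours < 1:
            raise ValueError("drift_hours must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        for key in ("sepsis_point", "baseline", "noise_sigma"):
            d[key] = list(d[key])
        return d


@dataclass
class TruthEntry:
    """Planted ground truth for one generated patient."""

    patient_id: str
    label: int
    length: int
    onset_row: int | None
    clean: np.ndarray = field(repr=False)  # trajectory before corruption


@dataclass
class PlantedTruth:
    sepsis_point: np.ndarray
    entries: list[TruthEntry]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sepsis_point": dict(zip(VITAL_SIGNS, map(float, self.sepsis_point))),
            "patients": [
                {
                    "patient_id": e.patient_id,
                    "label": e.label,
                    "length": e.length,
                    "onset_row": e.onset_row,
                    "clean_final_row": [float(v) for v in e.clean[-1]],
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _ar1_noise(
    rng: np.random.Generator, length: int, sigma: np.ndarray, phi: float
) -> np.ndarray:
    """Stationary AR(1) noise, marginal std ``sigma`` per sign: (length, 6)."""
    out = np.empty((length, len(sigma)))
    out[0] = rng.normal(0.0, 1.0, size=len(sigma)) * sigma
    innov_scale = sigma * np.sqrt(max(1.0 - phi * phi, 0.0))
    for t in range(1, length):
        out[t] = phi * out[t - 1] + rng.normal(0.0, 1.0, size=len(sigma)) * innov_scale
    return out


def simulate_patient(
    config: SimConfig,
    label: int,
    rng: np.random.Generator,
    patient_id: str = "sim",
) -> tuple[RawPatientRecord, TruthEntry]:
    """One synthetic patient record plus its planted truth.

    The clean trajectory is mean path + AR(1) noise; for positives the mean
    path interpolates linearly from baseline to the planted sepsis point over
    the final ``drift_hours`` rows, so with zero noise the last row *is* the
    planted point.  Corruption (missingness, spikes) is applied afterwards.
    """
    lo, hi = config.length_range
    length = int(rng.integers(lo, hi + 1))
    baseline = np.asarray(config.baseline, dtype=float)
    point = np.asarray(config.sepsis_point, dtype=float)
    sigma = np.asarray(config.noise_sigma, dtype=float)

    mean_path = np.tile(baseline, (length, 1))
    if label == 1:
        drift = min(config.drift_hours, length - 1) if length > 1 else 0
        for step in range(drift + 1):
            w = step / drift if drift else 1.0
            mean_path[length - 1 - drift + step] = baseline + w * (point - baseline)
    clean = mean_path + _ar1_noise(rng, length, sigma, config.ar_coeff)
    # O2Sat is physically capped at 100%
    clean[:, 1] = np.minimum(clean[:, 1], 100.0)

    corrupted = clean.copy()
    if config.error_rate > 0:
        spikes = rng.random(corrupted.shape) < config.error_rate
        spike_values = np.array([900.0, 350.0, 99.0, 900.0, 600.0, 250.0])
        corrupted[spikes] = np.broadcast_to(spike_values, corrupted.shape)[spikes]
    if config.missing_rate > 0:
        corrupted[rng.random(corrupted.shape) < config.missing_rate] = np.nan

    labels = np.zeros(length)
    onset_row: int | None = None
    if label == 1:
        onset_row = length - 1
        labels[onset_row] = 1.0
    frame = pd.DataFrame(corrupted, columns=list(VITAL_SIGNS))
    frame["Age"] = float(int(rng.integers(40, 90)))      # extra columns mimic
    frame["ICULOS"] = np.arange(1, length + 1, dtype=float)  # the real files
    frame[LABEL_COLUMN] = labels
    record = RawPatientRecord(patient_id=patient_id, frame=frame)
    truth = TruthEntry(patient_id, label, length, onset_row, clean)
    return record, truth


def simulate_cohort(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[RawPatientRecord], PlantedTruth]:
    """Generate the full cohort; optionally write PSV files and truth JSON.

    Per-patient generators are spawned from the master seed, so any single
    patient's data is invariant to the rest of the cohort.
    """
    n_total = config.n_positive + config.n_negative
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    records: list[RawPatientRecord] = []
    entries: list[TruthEntry] = []
    for i in range(n_total):
        label = 1 if i < config.n_positive else 0
        tag = f"sim_p{i:05d}" if label else f"sim_n{i:05d}"
        record, truth = simulate_patient(
            config, label, np.random.default_rng(streams[i]), patient_id=tag
        )
        records.append(record)
        entries.append(truth)
    planted = PlantedTruth(np.asarray(config.sepsis_point, float), entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .psv import write_patient_file

        for record in records:
            write_patient_file(record, out_dir / f"{record.patient_id}.psv")
        planted.to_json(out_dir / "truth.json")
    return records, planted


def onset_matrix(records_truth: Sequence[TruthEntry]) -> np.ndarray:
    """Stack the clean (uncorrupted) onset rows of the positive patients."""
    rows = [e.clean[e.onset_row] for e in records_truth if e.label == 1]
    if not rows:
        raise ValueError("no positive patients in truth")
    return np.stack(rows)
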