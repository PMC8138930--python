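"""Cohort exclusions and the preprocessing cascade for hourly vital signs.

The cascade turns ragged, gappy per-patient series into fixed-length clean
matrices suitable for feature engineering:

1. exclusions — drop patients with fewer than 36 hourly registers, then
   patients with any vital sign entirely missing;
2. limit clipping — physiologically impossible readings (sensor or typing
   errors) become missing;
3. windowing — keep the last 48 h; shorter series are front-padded with
   missing rows;
4. hourly-mean imputation — a missing cell is filled with the cohort mean of
   that sign at that window hour;
5. linear interpolation — remaining gaps are interpolated against the hour
   index (nearest-value extension at the edges);
6. smoothing — trailing 3-point moving average (window shrinks at the start
   so the series keeps its length);
7. max-normalization — each sign divided by its cohort-wide maximum, mapping
   everything into [0, 1] with an implicit minimum of zero;
8. balancing — a seeded random subsample of the negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .psv import VITAL_SIGNS

#: Default operating limits per vital sign (closed intervals, sign units).
#: These are deliberately wide plausibility bounds meant to catch sensor and
#: transcription errors, not clinical alarm thresholds; substitute your own
#: table when the acquisition context calls for it.
DEFAULT_LIMITS: dict[str, tuple[float, float]] = {
    "HR": (20.0, 300.0),
    "O2Sat": (50.0, 100.0),
    "Temp": (30.0, 45.0),
    "SBP": (40.0, 300.0),
    "DBP": (20.0, 200.0),
    "Resp": (4.0, 60.0),
}


@dataclass(frozen=True)
class LimitsTable:
    """Closed [lower, upper] operating limits for each vital sign."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LIMITS)
    )

    def __post_init__(self) -> None:
        for sign in VITAL_SIGNS:
            if sign not in self.bounds:
                raise ValueError(f"limits table missing sign {sign}")
            lo, hi = self.bounds[sign]
            if not lo < hi:
                raise ValueError(f"{sign}: lower bound must be < upper bound")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[s][0] for s in VITAL_SIGNS])
        hi = np.array([self.bounds[s][1] for s in VITAL_SIGNS])
        return lo, hi


@dataclass
class VitalSeries:
    """A patient's (T, 6) vital-sign matrix before windowing (NaN = missing)."""

    patient_id: str
    values: np.ndarray
    label: int


@dataclass
class PatientSeries:
    """A fixed-length windowed patient matrix (48 rows x 6 signs)."""

    patient_id: str
    matrix: np.ndarray
    label: int
    is_normalized: bool = False


@dataclass
class PreprocessReport:
    """Counts along the exclusion/processing funnel plus normalization maxima."""

    n_input: int = 0
    n_excluded_short: int = 0
    n_excluded_all_missing: int = 0
    n_survivors: int = 0
    n_positive: int = 0
    n_negative: int = 0
    n_negative_after_balance: int | None = None
    normalization_maxima: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PreprocessConfig:
    limits: LimitsTable = field(default_factory=LimitsTable)
    min_rows: int = 36
    window: int = 48
    smooth_width: int = 3
    balance_target: int | None = None
    balance_seed: int = 0


def apply_exclusions(
    cohort: Sequence[VitalSeries], min_rows: int = 36
) -> tuple[list[VitalSeries], PreprocessReport]:
    """Drop too-short patients, then patients with an entirely-missing sign.

    The short-series rule is applied first, so a patient failing both rules is
    counted once under it.  Returns the retained cohort and a report with the
    funnel counts filled in.
    """
    report = PreprocessReport(n_input=len(cohort))
    kept: list[VitalSeries] = []
    for patient in cohort:
        if len(patient.values) < min_rows:
            report.n_excluded_short += 1
            continue
        if np.isnan(patient.values).all(axis=0).any():
            report.n_excluded_all_missing += 1
            continue
        kept.append(patient)
    report.n_survivors = len(kept)
    report.n_positive = sum(p.label == 1 for p in kept)
    report.n_negative = sum(p.label == 0 for p in kept)
    return kept, report


def clip_to_limits(values: np.ndarray, limits: LimitsTable) -> np.ndarray:
    """Replace readings outside their sign's closed operating interval with NaN."""
    lo, hi = limits.as_arrays()
    values = np.asarray(values, dtype=float)
    out = values.copy()
    with np.errstate(invalid="ignore"):
        out[(values < lo) | (values > hi)] = np.nan
    return out


def window_last_48(values: np.ndarray, window: int = 48) -> np.ndarray:
    """Keep the last ``window`` rows; front-pad shorter series with NaN rows."""
    values = np.asarray(values, dtype=float)
    t = len(values)
    if t >= window:
        return values[t - window :].copy()
    pad = np.full((window - t, values.shape[1]), np.nan)
    return np.vstack([pad, values])


def impute_hourly_means(matrices: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Fill each missing cell with the cohort mean of that sign at that hour.

    All matrices must share the window length so row index t means the same
    window hour for everyone.  Cells at (sign, hour) positions where *no*
    patient has a value stay missing; interpolation handles them next.
    Originally present values are untouched.
    """
    if not matrices:
        return []
    stack = np.stack(matrices)  # (n_patients, T, 6)
    counts = (~np.isnan(stack)).sum(axis=0)
    sums = np.nansum(stack, axis=0)
    # (T, 6) per-hour means; NaN where nobody measured
    hourly = np.divide(sums, counts, out=np.full(counts.shape, np.nan), where=counts > 0)
    out = []
    for m in matrices:
        filled = m.copy()
        gaps = np.isnan(m)
        filled[gaps] = hourly[gaps]
        out.append(filled)
    return out


def interpolate_remaining(values: np.ndarray) -> np.ndarray:
    """Linearly interpolate leftover gaps against the hour index, per sign.

    Leading/trailing gaps take the nearest present value.  A sign with no
    present value at all cannot be filled and raises ``ValueError`` (the
    exclusion step makes that impossible in the normal pipeline).
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    hours = np.arange(len(values), dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        present = ~np.isnan(col)
        if not present.any():
            raise ValueError(f"sign {VITAL_SIGNS[j]} has no observed values")
        if present.all():
            continue
        # np.interp clamps outside the observed range = nearest-value extension
        out[:, j] = np.interp(hours, hours[present], col[present])
    return out


def smooth_ma3(values: np.ndarray, width: int = 3) -> np.ndarray:
    """Trailing moving average over the last ``width`` hours.

    output(t) = mean(input(t-width+1..t)); the window shrinks near t=0 so the
    series keeps its full length.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for t in range(len(values)):
        out[t] = values[max(0, t - width + 1) : t + 1].mean(axis=0)
    return out


def normalize_by_max(
    matrices: Sequence[np.ndarray],
) -> tuple[list[np.ndarray], np.ndarray]:
    """Divide every value by its sign's maximum over the whole cohort.

    The minimum is fixed at zero, so outputs land in [0, 1] as long as the
    inputs are non-negative.  Returns the scaled matrices and the (6,) maxima
    used; call it on a training subset for a leakage-free variant, then apply
    the returned maxima to held-out data with :func:`apply_maxima`.
    """
    if not matrices:
        raise ValueError("cannot normalize an empty cohort")
    maxima = np.stack(matrices).max(axis=(0, 1))
    if (maxima <= 0).any():
        bad = [VITAL_SIGNS[j] for j in np.flatnonzero(maxima <= 0)]
        raise ValueError(f"degenerate scale: non-positive maximum for {', '.join(bad)}")
    return [m / maxima for m in matrices], maxima


def apply_maxima(values: np.ndarray, maxima: np.ndarray) -> np.ndarray:
    """Scale one matrix by previously fitted per-sign maxima."""
    return np.asarray(values, dtype=float) / np.asarray(maxima, dtype=float)


def balance_cohort(
    positives: Sequence[PatientSeries],
    negatives: Sequence[PatientSeries],
    target_negative_count: int,
    seed: int,
) -> list[PatientSeries]:
    """Keep all positives and a seeded uniform subsample of the negatives."""
    if target_negative_count > len(negatives):
        raise ValueError(
            f"target {target_negative_count} exceeds negative pool {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=target_negative_count, replace=False)
    sampled = [negatives[i] for i in sorted(idx)]
    return list(positives) + sampled


def run_preprocessing(
    cohort: Sequence[VitalSeries], config: PreprocessConfig | None = None
) -> tuple[list[PatientSeries], PreprocessReport]:
    """Run the whole cascade: exclusions through normalization and balancing."""
    config = config or PreprocessConfig()
    kept, report = apply_exclusions(cohort, min_rows=config.min_rows)
    if not kept:
        return [], report

    windowed = [
        window_last_48(clip_to_limits(p.values, config.limits), config.window)
        for p in kept
    ]
    imputed = impute_hourly_means(windowed)
    clean = [smooth_ma3(interpolate_remaining(m), config.smooth_width) for m in imputed]
    normalized, maxima = normalize_by_max(clean)
    report.normalization_maxima = dict(
        zip(VITAL_SIGNS, (float(x) for x in maxima))
    )

    series = [
        PatientSeries(p.patient_id, m, p.label, is_normalized=True)
        for p, m in zip(kept, normalized)
    ]
    if config.balance_target is not None:
        positives = [s for s in series if s.label == 1]
        negatives = [s for s in series if s.label == 0]
        series = balance_cohort(
            positives, negatives, config.balance_target, config.balance_seed
        )
        report.n_negative_after_balance = config.balance_target
    return series, report
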