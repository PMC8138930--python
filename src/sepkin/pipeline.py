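"""End-to-end workflow: simulate -> preprocess -> features -> evaluate -> report.

Each stage writes plain-text artifacts (CSV/JSON) that re-parse through the
package's own readers, and the run is summarized in a :class:`RunManifest`
with the configuration snapshot, seeds, per-stage counts and output paths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CVReport, ModelSpec, compare_models, truncate_to_hbs
from .kinematics import (
    KF_COLUMNS,
    KinematicsMatrix,
    SepsisPosition,
    cohort_kf,
    estimate_sepsis_position,
)
from .preprocess import (
    LimitsTable,
    PatientSeries,
    PreprocessConfig,
    PreprocessReport,
    VitalSeries,
    run_preprocessing,
)
from .psv import VITAL_SIGNS, extract_vitals, read_patient_file, truncate_at_onset
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger("sepkin")


class ConfigError(ValueError):
    """The run configuration is malformed."""


class DataError(RuntimeError):
    """A pipeline stage failed on the data it was given."""


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str = __version__
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "counts": self.counts,
            "outputs": self.outputs,
            "completed_stages": self.completed_stages,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    try:
        config = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(config, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return config


def _preprocess_config(config: dict) -> PreprocessConfig:
    section = config.get("preprocess", {}) or {}
    limits = section.get("limits")
    table = LimitsTable({k: tuple(v) for k, v in limits.items()}) if limits else LimitsTable()
    try:
        return PreprocessConfig(
            limits=table,
            min_rows=int(section.get("min_rows", 36)),
            window=int(section.get("window", 48)),
            smooth_width=int(section.get("smooth_width", 3)),
            balance_target=section.get("balance_target"),
            balance_seed=int(section.get("balance_seed", config.get("seed", 0))),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad preprocess section: {exc}") from exc


def cohort_from_records(records) -> list[VitalSeries]:
    """Extract vitals and truncate at onset for in-memory patient records."""
    cohort = []
    for record in records:
        vitals, labels = extract_vitals(record)
        vitals, is_positive, _ = truncate_at_onset(vitals, labels)
        cohort.append(VitalSeries(record.patient_id, vitals, int(is_positive)))
    return cohort


def load_cohort(input_dir: str | Path) -> list[VitalSeries]:
    """Read every ``.psv`` file, extract vitals, and truncate at sepsis onset."""
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*.psv"))
    if not paths:
        raise DataError(f"no .psv files in {input_dir}")
    return cohort_from_records(read_patient_file(p) for p in paths)


def series_to_frame(cohort: Sequence[PatientSeries]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        frame = pd.DataFrame(s.matrix, columns=list(VITAL_SIGNS))
        frame.insert(0, "patient_id", s.patient_id)
        frame.insert(1, "hour", np.arange(len(s.matrix)))
        frame["label"] = s.label
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def kf_to_frame(matrices: Sequence[KinematicsMatrix]) -> pd.DataFrame:
    rows = []
    for m in matrices:
        frame = pd.DataFrame(m.values, columns=list(KF_COLUMNS))
        frame.insert(0, "patient_id", m.patient_id)
        frame.insert(1, "hour", np.arange(len(m.values)))
        frame["label"] = m.label
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def build_model_specs(config: dict) -> list[ModelSpec]:
    section = config.get("evaluate", {}) or {}
    kinds = section.get("models", ["lstm", "cnn", "linear_nn",
                                   "logistic_regression", "decision_tree"])
    seed = int(config.get("seed", 0))
    overrides = section.get("hyperparameters", {}) or {}
    try:
        return [ModelSpec(kind, dict(overrides.get(kind, {})), seed=seed) for kind in kinds]
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the configured stages in order and write all artifacts.

    Raises :class:`ConfigError` / :class:`DataError` naming the failing stage;
    a partially written run is recoverable from the manifest's stage list.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "sepkin_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_jsonable(config))
    manifest_path = out_dir / "manifest.json"

    # --- simulate or load -------------------------------------------------
    if "simulate" in config:
        sim_section = dict(config["simulate"] or {})
        if "seed" in config and "seed" not in sim_section:
            sim_section["seed"] = int(config["seed"])
        try:
            sim_config = SimConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim_section.items()
            })
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"stage simulate: {exc}") from exc
        cohort_dir = out_dir / "cohort"
        records, _ = simulate_cohort(sim_config, out_dir=cohort_dir)
        log.info("simulate: wrote %d patients to %s", len(records), cohort_dir)
        manifest.counts["simulated_patients"] = len(records)
        manifest.outputs["cohort_dir"] = str(cohort_dir)
        input_dir = cohort_dir
    else:
        input_dir = config.get("input_dir")
        if not input_dir:
            raise ConfigError("config needs either a simulate section or input_dir")
    manifest.completed_stages.append("simulate" if "simulate" in config else "load")

    # --- preprocess -------------------------------------------------------
    try:
        cohort = load_cohort(input_dir)
        series, report = run_preprocessing(cohort, _preprocess_config(config))
    except ConfigError:
        raise
    except Exception as exc:
        raise DataError(f"stage preprocess: {exc}") from exc
    if not series:
        raise DataError("stage preprocess: no patients survived the exclusions")
    report_path = out_dir / "preprocess_report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2))
    vs_path = out_dir / "vitals_normalized.csv"
    series_to_frame(series).to_csv(vs_path, index=False)
    manifest.counts.update(report.to_dict())
    manifest.outputs["preprocess_report"] = str(report_path)
    manifest.outputs["vitals_csv"] = str(vs_path)
    manifest.completed_stages.append("preprocess")
    log.info("preprocess: %d survivors (%d positive / %d negative)",
             report.n_survivors, report.n_positive, report.n_negative)

    # --- features ---------------------------------------------------------
    positives = [s for s in series if s.label == 1]
    if not positives:
        raise DataError("stage features: no positive patients to place the sepsis point")
    try:
        sepsis = estimate_sepsis_position(positives)
        matrices = cohort_kf(series, sepsis)
    except Exception as exc:
        raise DataError(f"stage features: {exc}") from exc
    sepsis_path = out_dir / "sepsis_position.json"
    sepsis.to_json(sepsis_path)
    kf_path = out_dir / "kinematics_features.csv"
    kf_to_frame(matrices).to_csv(kf_path, index=False)
    manifest.counts["kf_patients"] = len(matrices)
    manifest.outputs["sepsis_position"] = str(sepsis_path)
    manifest.outputs["kf_csv"] = str(kf_path)
    manifest.completed_stages.append("features")
    log.info("features: sepsis position from %d positives", sepsis.n_positives_used)

    # --- evaluate ---------------------------------------------------------
    cv_report = evaluate_cohort(series, matrices, config)
    cv_path = out_dir / "cv_report.csv"
    cv_report.to_csv(cv_path)
    calib_path = out_dir / "calibration.csv"
    cv_report.calibration_frame().to_csv(calib_path, index=False)
    manifest.outputs["cv_report"] = str(cv_path)
    manifest.outputs["calibration"] = str(calib_path)
    manifest.completed_stages.append("evaluate")
    log.info("evaluate: %d model(s) compared", len(cv_report.table))

    manifest.to_json(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def evaluate_cohort(
    series: Sequence[PatientSeries],
    matrices: Sequence[KinematicsMatrix],
    config: dict,
) -> CVReport:
    """Cross-validate every configured model on KF and VS representations."""
    section = config.get("evaluate", {}) or {}
    hbs = int(section.get("hbs", 6))
    k = int(section.get("k", 5))
    window = int((config.get("preprocess", {}) or {}).get("window", 48))
    split_seed = int(section.get("split_seed", config.get("seed", 0)))
    specs = build_model_specs(config)
    try:
        kf_inputs = np.stack([truncate_to_hbs(m.values, hbs, window) for m in matrices])
        vs_inputs = np.stack([truncate_to_hbs(s.matrix, hbs, window) for s in series])
    except ValueError as exc:
        raise ConfigError(f"stage evaluate (truncation): {exc}") from exc
    labels = np.array([s.label for s in series])
    try:
        return compare_models(kf_inputs, vs_inputs, labels, specs, k=k,
                              split_seed=split_seed,
                              n_bins=int(section.get("n_bins", 5)))
    except ValueError as exc:
        raise DataError(f"stage evaluate: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
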