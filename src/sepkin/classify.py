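"""Classifier comparison harness: kinematics features versus raw vital signs.

Five binary classifiers — LSTM, CNN, linear NN, logistic regression, decision
tree — are trained on per-patient matrices truncated ``hbs`` hours before the
window's last timestamp (HBS = hours before sepsis; HBS=6 over a 48-h window
leaves 42 rows).  Evaluation is stratified k-fold cross-validation with the
*same* fold partition for every model and input representation, so the KF/VS
accuracy differences are paired comparisons.  Calibration curves come from
the pooled out-of-fold probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import calibration_curve as _sk_calibration_curve
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .nn import ConvClassifier, LinearClassifier, LSTMClassifier

MODEL_KINDS = ("lstm", "cnn", "linear_nn", "logistic_regression", "decision_tree")

#: Display names used in the comparison report, keyed by model kind.
MODEL_NAMES = {
    "lstm": "LSTM",
    "cnn": "CNN",
    "linear_nn": "Linear NN",
    "logistic_regression": "Logist. Regres",
    "decision_tree": "Decision Tree",
}

_NN_DEFAULTS = {
    "lstm": {"hidden_units": 128, "dropout": 0.2, "batch_size": 64,
             "lr": 0.1, "epochs": 50, "patience": 5},
    "cnn": {"filters": 64, "kernel_size": 3, "batch_size": 64,
            "lr": 0.1, "epochs": 50, "patience": 5},
    "linear_nn": {"batch_size": 64, "lr": 0.1, "epochs": 50, "patience": 5},
}


@dataclass
class ModelSpec:
    """A classifier kind plus hyperparameter overrides and a training seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}"
            )


class _FlatSklearnClassifier:
    """Adapts an sklearn estimator to the (n, T, C) tensor interface.

    Non-sequence models see the flattened T*C vector per patient.
    """

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, x, y):
        self.estimator.fit(np.asarray(x).reshape(len(x), -1), np.asarray(y))
        return self

    def predict_proba(self, x):
        return self.estimator.predict_proba(np.asarray(x).reshape(len(x), -1))[:, 1]

    def predict(self, x):
        return (self.predict_proba(x) >= 0.5).astype(int)


def truncate_to_hbs(matrix: np.ndarray, hbs: int, window: int = 48) -> np.ndarray:
    """Withhold the last ``hbs`` hours: keep the first ``window - hbs`` rows."""
    matrix = np.asarray(matrix)
    if not 0 <= hbs < window:
        raise ValueError(f"hbs must be in [0, {window}); got {hbs}")
    return matrix[: window - hbs]


def build_classifier(spec: ModelSpec, input_shape: tuple[int, int] | None = None):
    """Instantiate a trainable classifier exposing fit / predict_proba.

    ``input_shape`` is (T, C); it is only needed to validate the CNN kernel
    against very short windows and is otherwise informational.
    """
    hp = dict(spec.hyperparameters)
    if spec.kind in _NN_DEFAULTS:
        merged = {**_NN_DEFAULTS[spec.kind], **hp, "seed": spec.seed}
        cls = {"lstm": LSTMClassifier, "cnn": ConvClassifier,
               "linear_nn": LinearClassifier}[spec.kind]
        return cls(**merged)
    if spec.kind == "logistic_regression":
        return _FlatSklearnClassifier(
            LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
        )
    if spec.kind == "decision_tree":
        return _FlatSklearnClassifier(
            DecisionTreeClassifier(random_state=spec.seed, **hp)
        )
    raise ValueError(f"unknown model kind {spec.kind!r}")  # pragma: no cover


def make_folds(
    labels: Sequence[int], k: int, split_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition, reproducible under ``split_seed``.

    The partition depends only on the labels and the seed, so the same folds
    are reused across every model and input representation.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(labels) < k:
        raise ValueError(f"need at least k={k} patients, got {len(labels)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def kfold_cross_validate(
    x: np.ndarray,
    y: Sequence[int],
    spec: ModelSpec,
    k: int = 5,
    split_seed: int = 0,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold held-out accuracies plus pooled out-of-fold probabilities.

    Accuracy is the fraction of correct predictions at the 0.5 threshold.
    Returns ``(fold_accuracies, oof_probabilities)`` with the probabilities
    aligned to the input patient order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if folds is None:
        folds = make_folds(y, k, split_seed)
    accs = []
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in folds:
        clf = build_classifier(spec, input_shape=x.shape[1:])
        clf.fit(x[train_idx], y[train_idx])
        proba = np.asarray(clf.predict_proba(x[test_idx])).ravel()
        oof[test_idx] = proba
        accs.append(float(np.mean((proba >= 0.5).astype(int) == y[test_idx])))
    return np.array(accs), oof


def calibration_points(
    probabilities: np.ndarray, labels: Sequence[int], n_bins: int = 5
) -> np.ndarray:
    """Reliability-curve points over equal-width probability bins.

    Returns an (m, 2) array of (mean predicted probability, observed positive
    fraction), one row per non-empty bin.  A well-calibrated classifier's
    points lie on the diagonal.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.size and (probabilities.min() < 0 or probabilities.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    frac_pos, mean_pred = _sk_calibration_curve(
        np.asarray(labels), probabilities, n_bins=n_bins, strategy="uniform"
    )
    return np.column_stack([mean_pred, frac_pos])


@dataclass
class CVReport:
    """Cross-validated comparison of KF-input versus VS-input classifiers."""

    table: pd.DataFrame                      # one row per model, KF-sorted
    fold_accuracies: dict[tuple[str, str], np.ndarray]   # (kind, rep) -> (k,)
    calibration: dict[tuple[str, str], np.ndarray]       # (kind, rep) -> (m, 2)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def calibration_frame(self) -> pd.DataFrame:
        rows = []
        for (kind, rep), pts in self.calibration.items():
            for mean_pred, frac_pos in pts:
                rows.append(
                    {"classifier": MODEL_NAMES[kind], "representation": rep,
                     "mean_predicted": mean_pred, "observed_fraction": frac_pos}
                )
        return pd.DataFrame(rows)


def compare_models(
    kf_inputs: np.ndarray,
    vs_inputs: np.ndarray,
    labels: Sequence[int],
    specs: Sequence[ModelSpec],
    k: int = 5,
    split_seed: int = 0,
    n_bins: int = 5,
) -> CVReport:
    """Run every model on both representations over one shared fold partition.

    Both input tensors must describe the same patients in the same order.
    The report table carries, per model, the KF and VS mean accuracies, their
    difference (KF - VS), and the fold standard deviations, sorted by KF
    accuracy descending.
    """
    labels = np.asarray(labels)
    if len(kf_inputs) != len(vs_inputs) or len(kf_inputs) != len(labels):
        raise ValueError("KF inputs, VS inputs and labels must align")
    folds = make_folds(labels, k, split_seed)
    fold_accs: dict[tuple[str, str], np.ndarray] = {}
    calib: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    for spec in specs:
        per_rep_mean = {}
        per_rep_std = {}
        for rep, x in (("KF", kf_inputs), ("VS", vs_inputs)):
            accs, oof = kfold_cross_validate(x, labels, spec, folds=folds)
            fold_accs[(spec.kind, rep)] = accs
            calib[(spec.kind, rep)] = calibration_points(oof, labels, n_bins=n_bins)
            per_rep_mean[rep] = float(accs.mean())
            per_rep_std[rep] = float(accs.std(ddof=0))
        rows.append(
            {
                "classifier": MODEL_NAMES[spec.kind],
                "mean_acc_kf": per_rep_mean["KF"],
                "mean_acc_vs": per_rep_mean["VS"],
                "mean_diff": per_rep_mean["KF"] - per_rep_mean["VS"],
                "std_kf": per_rep_std["KF"],
                "std_vs": per_rep_std["VS"],
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("mean_acc_kf", ascending=False)
        .reset_index(drop=True)
    )
    return CVReport(table=table, fold_accuracies=fold_accs, calibration=calib)
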