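"""Multilayer-perceptron posture classification and session-wise cross-testing.

The evaluation protocol mirrors a ten-session recording day: at training
level ``TRNk`` the classifier is trained on ``k`` consecutive sessions
(contiguous rotation over session indices, 10 folds) and tested on the
remaining ``10 - k`` sessions, so every fold's train and test sets are
disjoint sessions.  Per-fold threshold calibration and feature normalization
use only that fold's training sessions — no leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from . import features as feat
from .signal_io import (
    POSTURES,
    REST_CALIBRATION,
    FilterSpec,
    SEMGRecording,
    ValidationError,
    WindowSpec,
    bandpass_filter,
    segment_dataset,
)

N_SESSIONS = 10


@dataclass(frozen=True)
class ClassifierSpec:
    """Multilayer-perceptron hyperparameters.

    A single 64-unit hidden layer with early stopping on an automatically
    partitioned validation split carved from the training data.
    """

    hidden_layers: tuple[int, ...] = (64,)
    max_epochs: int = 200
    patience: int = 10
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) < 1 or any(h < 1 for h in self.hidden_layers):
            raise ValidationError("need >= 1 hidden layer with positive unit counts")
        if not 0 < self.validation_fraction < 0.5:
            raise ValidationError("validation_fraction must lie in (0, 0.5)")


class TrainedModel:
    """A fitted MLP plus the column normalization statistics it was trained
    with (z-score per column from training data only) and its label order."""

    def __init__(self, mlp: MLPClassifier, mean: np.ndarray, std: np.ndarray, classes: np.ndarray):
        self.mlp = mlp
        self.mean = mean
        self.std = std
        self.classes = classes

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.mlp.predict(self._transform(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.mlp.predict_proba(self._transform(X))


def train_classifier(fm: feat.FeatureMatrix, spec: ClassifierSpec = ClassifierSpec()) -> TrainedModel:
    """Fit the MLP on a feature matrix; deterministic given (data, seed)."""
    classes = np.unique(fm.labels)
    if len(classes) < 2:
        raise ValidationError("training requires at least 2 classes")
    if fm.n_windows < 10 * len(classes):
        warnings.warn(
            f"only {fm.n_windows} training windows for {len(classes)} classes",
            stacklevel=2,
        )
    mean = fm.X.mean(axis=0)
    std = fm.X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    mlp = MLPClassifier(
        hidden_layer_sizes=tuple(spec.hidden_layers),
        max_iter=spec.max_epochs,
        early_stopping=True,
        n_iter_no_change=spec.patience,
        validation_fraction=spec.validation_fraction,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        mlp.fit((fm.X - mean) / std, fm.labels)
    return TrainedModel(mlp, mean, std, mlp.classes_)


# ---------------------------------------------------------------------------
# cross-test plan
# ---------------------------------------------------------------------------

def crosstest_folds(k: int, n_sessions: int = N_SESSIONS) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """The ten-fold rotation at training level ``k``: fold ``f`` trains on
    sessions ``{f, f+1, ..., f+k-1} (mod n)`` (1-based) and tests on the rest."""
    if not 1 <= k <= n_sessions - 1:
        raise ValidationError(f"trn level k must lie in 1..{n_sessions - 1}, got {k}")
    folds = []
    for f in range(n_sessions):
        train = tuple(sorted((f + j) % n_sessions + 1 for j in range(k)))
        test = tuple(s for s in range(1, n_sessions + 1) if s not in train)
        folds.append((train, test))
    return folds


@dataclass
class EvaluationResult:
    """Per-fold accuracies, their mean/SD, and a pooled row-normalized
    confusion matrix over the posture vocabulary (percent)."""

    fold_accuracies: np.ndarray  # percent
    confusion: np.ndarray        # rows: true posture, cols: predicted, in %
    labels: tuple[str, ...]
    feature_set: str
    R: float
    day: int
    trn_level: int
    empty_rows: tuple[int, ...] = ()
    fold_artifacts: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] = POSTURES,
    counts: bool = False,
) -> np.ndarray:
    """Row-normalized confusion matrix in percent (or raw counts).

    Entry ``(i, j)`` is the share of true-class-``i`` windows predicted as
    class ``j``; a true class with no windows yields a row of zeros.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValidationError("label vectors must have the same length")
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = (set(true_labels) | set(predicted_labels)) - set(labels)
    if unknown:
        raise ValidationError(f"labels outside the vocabulary: {sorted(unknown)}")
    n = len(labels)
    tally = np.zeros((n, n))
    for t, p in zip(true_labels, predicted_labels):
        tally[index[t], index[p]] += 1
    if counts:
        return tally
    sums = tally.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(sums > 0, 100.0 * tally / sums, 0.0)
    return pct


def cross_test(
    recordings: Sequence[SEMGRecording],
    k: int,
    feature_config: feat.FeatureConfig = feat.FeatureConfig(),
    classifier_spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
    window_spec: WindowSpec = WindowSpec(),
    filter_spec: FilterSpec | None = FilterSpec(),
    labels: Sequence[str] | None = None,
    collect_fold_artifacts: bool = False,
) -> EvaluationResult:
    """Run the ten-fold session rotation at training level ``k`` on one day.

    Each fold filters nothing twice (conditioning is per-trial), calibrates
    the ZC/SSC threshold from the rest trials of its own training sessions,
    z-scores features with training statistics, trains the MLP, and scores
    the held-out sessions.  Fold confusions are pooled as counts, then
    row-normalized.
    """
    recordings = list(recordings)
    days = {r.day_id for r in recordings}
    if len(days) != 1:
        raise ValidationError(f"cross_test expects one day of data, got days {sorted(days)}")
    day = days.pop()
    sessions = sorted({r.session_id for r in recordings})
    if len(sessions) != N_SESSIONS:
        raise ValidationError(
            f"cross_test requires exactly {N_SESSIONS} sessions, got {len(sessions)}"
        )
    if labels is None:
        labels = tuple(
            p for p in POSTURES if p in {r.posture for r in recordings if r.posture != REST_CALIBRATION}
        )

    # condition and window once (per-trial operations; no cross-session state)
    filtered = [
        bandpass_filter(r, filter_spec) if filter_spec is not None else r for r in recordings
    ]
    posture_windows = segment_dataset(filtered, window_spec, filter_spec=None)
    rest_by_session: dict[int, list[SEMGRecording]] = {}
    for r in filtered:
        if r.posture == REST_CALIBRATION:
            rest_by_session.setdefault(r.session_id, []).append(r)

    all_fm_zero = feat.extract_features(posture_windows, feat.FeatureConfig(feat.MAV_ONLY, 0.0))
    session_of_row = all_fm_zero.session_ids

    fold_acc = []
    fold_artifacts: list[dict] = []
    pooled = np.zeros((len(labels), len(labels)))
    rng = np.random.SeedSequence(seed)
    fold_seeds = rng.generate_state(N_SESSIONS) % (2**31)
    for fold, (train_sessions, test_sessions) in enumerate(crosstest_folds(k)):
        train_mask = np.isin(session_of_row, train_sessions)
        test_mask = np.isin(session_of_row, test_sessions)
        if feature_config.feature_set == feat.HUDGINS:
            rest = [r for s in train_sessions for r in rest_by_session.get(s, [])]
            if not rest:
                raise ValidationError(
                    f"fold {fold}: no rest-calibration trial in training sessions {train_sessions}"
                )
            thresholds = feat.calibrate_threshold(rest, feature_config.R)
        else:
            thresholds = None
        fm = feat.extract_features(posture_windows, feature_config, thresholds)
        train_fm = fm.subset(train_mask)
        test_fm = fm.subset(test_mask)
        spec = ClassifierSpec(
            hidden_layers=classifier_spec.hidden_layers,
            max_epochs=classifier_spec.max_epochs,
            patience=classifier_spec.patience,
            validation_fraction=classifier_spec.validation_fraction,
            seed=int(fold_seeds[fold]),
        )
        model = train_classifier(train_fm, spec)
        pred = model.predict(test_fm.X)
        fold_acc.append(100.0 * float(np.mean(pred == test_fm.labels)))
        pooled += confusion_matrix(test_fm.labels, pred, labels, counts=True)
        if collect_fold_artifacts:
            fold_artifacts.append(
                {
                    "train_sessions": train_sessions,
                    "test_sessions": test_sessions,
                    "thresholds": None if thresholds is None else thresholds.copy(),
                    "norm_mean": model.mean.copy(),
                    "norm_std": model.std.copy(),
                    "weights": [w.copy() for w in model.mlp.coefs_],
                    "biases": [b.copy() for b in model.mlp.intercepts_],
                }
            )

    sums = pooled.sum(axis=1, keepdims=True)
    empty = tuple(int(i) for i in np.flatnonzero(sums.ravel() == 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(sums > 0, 100.0 * pooled / sums, 0.0)
    result = EvaluationResult(
        fold_accuracies=np.array(fold_acc),
        confusion=confusion,
        labels=tuple(labels),
        feature_set=feature_config.feature_set,
        R=feature_config.R,
        day=day,
        trn_level=k,
        empty_rows=empty,
    )
    if collect_fold_artifacts:
        result.fold_artifacts = fold_artifacts
    return result


def accuracy_trend(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Long-format summary: one row per (day, trn_level, feature_set)."""
    rows = [
        {
            "day": r.day,
            "trn_level": r.trn_level,
            "feature_set": r.feature_set,
            "mean": r.mean_accuracy,
            "sd": r.sd_accuracy,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["day", "trn_level", "feature_set", "mean", "sd"])
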