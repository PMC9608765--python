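"""Time-domain feature extraction with rest-calibrated thresholds.

Implements the classic four-feature Hudgins set over analysis windows of a
conditioned sEMG signal ``x_1..x_N``:

* ``MAV = (1/N) sum |x_i|`` -- amplitude
* ``WL  = sum |x_{i+1} - x_i|`` -- cumulative waveform length
* ``ZC``  -- zero crossings: pairs with opposite sign and ``|x_i - x_{i+1}|``
  at or above a noise-rejection threshold
* ``SSC`` -- slope sign changes: interior samples where
  ``(x_i - x_{i-1}) * (x_i - x_{i+1})`` reaches the threshold

The threshold is calibrated per channel as ``R x RMS(rest signal)`` with the
multiplier ``R`` swept over the grid 0.0, 0.5, ..., 10.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .signal_io import (
    REST_CALIBRATION,
    SEMGRecording,
    ValidationError,
    Window,
    bandpass_filter,
)

#: The 21-value threshold-multiplier grid.
R_GRID: tuple[float, ...] = tuple(np.arange(0.0, 10.0 + 0.25, 0.5).tolist())

MAV_ONLY = "MAV_ONLY"
HUDGINS = "HUDGINS"

#: Per-channel feature order in a Hudgins feature matrix.
HUDGINS_ORDER: tuple[str, ...] = ("MAV", "WL", "ZC", "SSC")


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-set choice plus the threshold multiplier ``R``."""

    feature_set: str = HUDGINS
    R: float = 0.0

    def __post_init__(self) -> None:
        if self.feature_set not in (MAV_ONLY, HUDGINS):
            raise ValidationError(
                f"feature_set must be {MAV_ONLY} or {HUDGINS}, got {self.feature_set!r}"
            )
        if self.R < 0:
            raise ValidationError("R must be >= 0")

    @property
    def on_grid(self) -> bool:
        return any(abs(self.R - g) < 1e-12 for g in R_GRID)

    @property
    def n_features_per_channel(self) -> int:
        return 4 if self.feature_set == HUDGINS else 1


@dataclass
class FeatureMatrix:
    """Windows x (channels x features) table with row-aligned metadata.

    Columns are ordered channel-major: for the Hudgins set, channel ``c``
    contributes the block (MAV, WL, ZC, SSC) at columns ``4c..4c+3``.
    """

    X: np.ndarray
    columns: tuple[str, ...]
    labels: np.ndarray
    session_ids: np.ndarray
    day_ids: np.ndarray
    feature_set: str
    R: float

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.session_ids) == len(self.day_ids) == n):
            raise ValidationError("metadata vectors must align with feature rows")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[mask],
            columns=self.columns,
            labels=self.labels[mask],
            session_ids=self.session_ids[mask],
            day_ids=self.day_ids[mask],
            feature_set=self.feature_set,
            R=self.R,
        )


# ---------------------------------------------------------------------------
# scalar features (reference semantics; the batch path below vectorizes them)
# ---------------------------------------------------------------------------

def mav(window) -> float:
    x = np.asarray(window, dtype=np.float64)
    if x.size < 1:
        raise ValidationError("MAV requires a nonempty window")
    return float(np.mean(np.abs(x)))


def wl(window) -> float:
    x = np.asarray(window, dtype=np.float64)
    if x.size < 2:
        raise ValidationError("WL requires at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def zc(window, threshold: float = 0.0) -> int:
    x = np.asarray(window, dtype=np.float64)
    if x.size < 2:
        raise ValidationError("ZC requires at least 2 samples")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    sign_opposed = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= threshold
    return int(np.count_nonzero(sign_opposed & big_enough))


def ssc(window, threshold: float = 0.0) -> int:
    x = np.asarray(window, dtype=np.float64)
    if x.size < 3:
        raise ValidationError("SSC requires at least 3 samples")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.count_nonzero(prod >= threshold))


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def calibrate_threshold(rest_recording: SEMGRecording | Sequence[SEMGRecording], R: float) -> np.ndarray:
    """Per-channel threshold ``R x RMS`` of the rest-calibration signal.

    Accepts one rest recording or several (concatenated along time, e.g. the
    rest trials of every training session in a fold).
    """
    if R < 0:
        raise ValidationError("R must be >= 0")
    recs = [rest_recording] if isinstance(rest_recording, SEMGRecording) else list(rest_recording)
    if not recs:
        raise ValidationError("no calibration trial: a rest-calibration recording is required")
    for rec in recs:
        if rec.posture != REST_CALIBRATION:
            raise ValidationError(
                f"calibration requires posture {REST_CALIBRATION!r}, got {rec.posture!r}"
            )
    data = np.concatenate([r.samples for r in recs], axis=1)
    rms = np.sqrt(np.mean(data**2, axis=1))
    return R * rms


# ---------------------------------------------------------------------------
# batch extraction
# ---------------------------------------------------------------------------

def _stack_windows(windows: Sequence[Window]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.stack([w.samples for w in windows])  # (n, channels, N)
    labels = np.array([w.posture for w in windows])
    sessions = np.array([w.session_id for w in windows])
    days = np.array([w.day_id for w in windows])
    return arr, labels, sessions, days


def extract_features(
    windows: Sequence[Window],
    config: FeatureConfig = FeatureConfig(),
    thresholds: np.ndarray | None = None,
) -> FeatureMatrix:
    """Compute the configured feature set for every window.

    ``thresholds`` is the per-channel ZC/SSC threshold vector from
    :func:`calibrate_threshold`; required only for the Hudgins set (an
    all-zero vector is used when omitted, i.e. R = 0).
    """
    windows = list(windows)
    if not windows:
        raise ValidationError("extract_features requires at least one window")
    arr, labels, sessions, days = _stack_windows(windows)
    n, n_ch, N = arr.shape
    names = windows[0].channel_names

    mav_cols = np.mean(np.abs(arr), axis=2)  # (n, channels)
    if config.feature_set == MAV_ONLY:
        X = mav_cols
        columns = tuple(f"{c}:MAV" for c in names)
        return FeatureMatrix(X, columns, labels, sessions, days, config.feature_set, config.R)

    if thresholds is None:
        thresholds = np.zeros(n_ch)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.shape != (n_ch,):
        raise ValidationError(
            f"threshold vector length {thresholds.shape} does not match {n_ch} channels"
        )
    if N < 3:
        raise ValidationError("Hudgins features require windows of at least 3 samples")

    diff = np.diff(arr, axis=2)
    wl_cols = np.sum(np.abs(diff), axis=2)
    thr = thresholds[None, :, None]
    zc_cols = np.count_nonzero(
        (arr[:, :, :-1] * arr[:, :, 1:] < 0) & (np.abs(diff) >= thr), axis=2
    ).astype(np.float64)
    prod = (arr[:, :, 1:-1] - arr[:, :, :-2]) * (arr[:, :, 1:-1] - arr[:, :, 2:])
    ssc_cols = np.count_nonzero(prod >= thr, axis=2).astype(np.float64)

    X = np.empty((n, 4 * n_ch))
    X[:, 0::4] = mav_cols
    X[:, 1::4] = wl_cols
    X[:, 2::4] = zc_cols
    X[:, 3::4] = ssc_cols
    columns = tuple(f"{c}:{f}" for c in names for f in HUDGINS_ORDER)
    return FeatureMatrix(X, columns, labels, sessions, days, config.feature_set, config.R)


# ---------------------------------------------------------------------------
# R optimization
# ---------------------------------------------------------------------------

def optimize_R(
    recordings: Sequence[SEMGRecording],
    grid: Sequence[float] = R_GRID,
    classifier_spec=None,
    seed: int = 0,
    window_spec=None,
    filter_spec=None,
):
    """Pick the grid ``R`` maximizing held-out-session validation accuracy.

    The last training session is held out; a Hudgins-set classifier is
    trained on the remaining sessions for every candidate ``R`` and scored on
    the held-out session.  Ties break toward the smaller ``R`` (noise
    robustness).  Returns ``(best_R, sweep_table)`` where the sweep table is
    a list of ``(R, validation_accuracy_pct)`` pairs for audit.
    """
    from . import classify  # local import: avoid a module cycle
    from .signal_io import FilterSpec, WindowSpec, segment_dataset

    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValidationError("R grid must not be empty")
    recordings = list(recordings)
    sessions = sorted({r.session_id for r in recordings})
    if len(sessions) < 2:
        raise ValidationError(
            "optimize_R needs >= 2 training sessions (one is held out for "
            "validation); pass a fixed R instead"
        )
    window_spec = window_spec or WindowSpec()
    filter_spec = filter_spec if filter_spec is not None else FilterSpec()
    spec = classifier_spec or classify.ClassifierSpec(seed=seed)

    val_session = sessions[-1]
    train_recs = [r for r in recordings if r.session_id != val_session]
    val_recs = [r for r in recordings if r.session_id == val_session]
    rest = [r for r in train_recs if r.posture == REST_CALIBRATION]
    if not rest:
        raise ValidationError("no calibration trial among the training sessions")
    train_windows = segment_dataset(train_recs, window_spec, filter_spec)
    val_windows = segment_dataset(val_recs, window_spec, filter_spec)
    filtered_rest = [
        r if filter_spec is None else bandpass_filter(r, filter_spec) for r in rest
    ]

    table: list[tuple[float, float]] = []
    best_R, best_acc = None, -np.inf
    for R in grid:
        thr = calibrate_threshold(filtered_rest, R)
        cfg = FeatureConfig(HUDGINS, R)
        train_fm = extract_features(train_windows, cfg, thr)
        val_fm = extract_features(val_windows, cfg, thr)
        model = classify.train_classifier(train_fm, spec)
        acc = 100.0 * float(np.mean(model.predict(val_fm.X) == val_fm.labels))
        table.append((R, acc))
        if acc > best_acc:  # strict: ties keep the earlier (smaller) R
            best_R, best_acc = R, acc
    return best_R, table
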