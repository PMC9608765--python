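"""Recording data model, on-disk dataset format, band-pass conditioning, windowing.

A trial is a multichannel surface-EMG recording stored as a channels x time
matrix at a fixed sampling rate (the reference acquisition runs at 1926 Hz).
Datasets live on disk as one delimited text file per trial plus a JSON
manifest, so fixtures stay human-readable and round-trip bit-exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("semgkit")

MANIFEST_NAME = "manifest.json"
FORMAT_VERSION = 1

#: The closed 12-posture vocabulary, in the fixed order shared by confusion
#: matrices and radar patterns.
POSTURES: tuple[str, ...] = (
    "rest",
    "spread",
    "finger pointing",
    "scissor sign",
    "V sign",
    "O.K. sign",
    "thumb up (hook)",
    "cylindrical grasp",
    "spherical grasp",
    "lateral pinch",
    "palmar pinch",
    "tip pinch",
)

#: Label reserved for the per-session rest trial used to calibrate the
#: ZC/SSC noise-rejection threshold; not a classification target.
REST_CALIBRATION = "rest-calibration"

#: Default 9-channel forearm montage (healthy-adult setup).
DEFAULT_CHANNELS_9: tuple[str, ...] = (
    "FDS", "ED", "EDM", "EP", "FCR", "FCU", "ECR", "ECU", "BR",
)

#: 8-channel residual-limb montage.
DEFAULT_CHANNELS_8: tuple[str, ...] = (
    "BR", "FCR", "ECR", "ED", "ECU", "FDP", "FDS", "FCU",
)


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


def _as_2d(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ValidationError(f"samples must be a channels x time matrix, got ndim={arr.ndim}")
    return arr


@dataclass
class SEMGRecording:
    """One trial: ``channels x time`` samples plus acquisition metadata.

    Parameters
    ----------
    samples
        Channels x time matrix, arbitrary (unitless) amplitude.
    fs
        Sampling rate in Hz.
    posture
        Label from :data:`POSTURES` or :data:`REST_CALIBRATION`.
    session_id
        Session index within a day, 1..10 in the reference protocol.
    day_id
        Training day, 1-based.
    subject_id
        Free-form subject identifier.
    channel_names
        One muscle label per channel (e.g. FDS, ED, ECU).
    """

    samples: np.ndarray
    fs: float
    posture: str
    session_id: int
    day_id: int
    subject_id: str
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = _as_2d(self.samples)
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValidationError("recording must contain at least one channel and one sample")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        allowed = set(POSTURES) | {REST_CALIBRATION}
        if self.posture not in allowed:
            raise ValidationError(
                f"unknown posture label {self.posture!r}; allowed labels: "
                + ", ".join(sorted(allowed))
            )
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i + 1}" for i in range(self.n_channels))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "SEMGRecording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (defaults 10-500 Hz, order 4)."""

    low_hz: float = 10.0
    high_hz: float = 500.0
    order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= fs / 2:
            raise ValidationError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency {fs / 2}"
            )
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
        )


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window layout: length (ms), overlap fraction, edge trim (s).

    The 250 ms / 50 % defaults follow common myoelectric-control practice;
    0.5 s is trimmed from each trial end to isolate steady-state contraction.
    """

    length_ms: float = 250.0
    overlap_fraction: float = 0.5
    trim_s: float = 0.5

    def validate(self) -> None:
        if self.length_ms <= 0:
            raise ValidationError("window length must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValidationError("overlap_fraction must lie in [0, 1)")
        if self.trim_s < 0:
            raise ValidationError("trim_s must be nonnegative")

    def n_samples(self, fs: float) -> int:
        n = int(round(self.length_ms * fs / 1000.0))
        if n < 2:
            raise ValidationError(f"window of {self.length_ms} ms at fs={fs} has {n} < 2 samples")
        return n

    def hop(self, fs: float) -> int:
        return max(1, int(self.n_samples(fs) * (1.0 - self.overlap_fraction)))


@dataclass
class Window:
    """One analysis window (channels x N) with inherited trial metadata."""

    samples: np.ndarray
    posture: str
    session_id: int
    day_id: int
    subject_id: str
    channel_names: tuple[str, ...]
    start_index: int


# ---------------------------------------------------------------------------
# dataset persistence
# ---------------------------------------------------------------------------

def save_dataset(recordings: Sequence[SEMGRecording], root_path) -> Path:
    """Write trials as per-trial CSV files plus a JSON manifest.

    Samples are written with 17 significant digits so that
    ``load_dataset(save_dataset(x))`` reproduces them bit-identically.
    Returns the manifest path.
    """
    recordings = list(recordings)
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    if recordings:
        fs = recordings[0].fs
        channels = recordings[0].channel_names
        subject = recordings[0].subject_id
        for rec in recordings:
            if rec.fs != fs:
                raise ValidationError("all recordings in a dataset must share the sampling rate")
            if rec.channel_names != channels:
                raise ValidationError("all recordings in a dataset must share channel names")
    else:
        fs, channels, subject = 0.0, (), ""
    trials = []
    for idx, rec in enumerate(recordings):
        fname = f"trial_{idx:04d}.csv"
        np.savetxt(root / fname, rec.samples.T, delimiter=",", fmt="%.17g")
        trials.append(
            {
                "file": fname,
                "posture": rec.posture,
                "session_id": rec.session_id,
                "day_id": rec.day_id,
            }
        )
    manifest = {
        "format_version": FORMAT_VERSION,
        "subject_id": subject,
        "fs_hz": fs,
        "channel_names": list(channels),
        "trials": trials,
    }
    manifest_path = root / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_dataset(root_path) -> list[SEMGRecording]:
    """Load every trial referenced by the manifest under ``root_path``.

    Fails atomically: any missing file, bad label, or column mismatch raises
    before a partial dataset is returned.
    """
    root = Path(root_path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} found in {root}")
    manifest = json.loads(manifest_path.read_text())
    channels = tuple(manifest["channel_names"])
    fs = float(manifest["fs_hz"])
    subject = manifest["subject_id"]
    recordings: list[SEMGRecording] = []
    for trial in manifest["trials"]:
        path = root / trial["file"]
        if not path.exists():
            raise FileNotFoundError(f"trial file missing: {path}")
        samples = np.loadtxt(path, delimiter=",", ndmin=2).T
        if channels and samples.shape[0] != len(channels):
            raise ValidationError(
                f"{path.name}: {samples.shape[0]} columns, expected {len(channels)} channels"
            )
        recordings.append(
            SEMGRecording(
                samples=samples,
                fs=fs,
                posture=trial["posture"],
                session_id=int(trial["session_id"]),
                day_id=int(trial["day_id"]),
                subject_id=subject,
                channel_names=channels,
            )
        )
    if not recordings:
        warnings.warn(f"dataset at {root} contains no trials", stacklevel=2)
    return recordings


# ---------------------------------------------------------------------------
# conditioning and windowing
# ---------------------------------------------------------------------------

def bandpass_filter(
    recording: SEMGRecording, spec: FilterSpec = FilterSpec(), causal: bool = False
) -> SEMGRecording:
    """Band-pass every channel with a Butterworth filter; removes DC.

    Zero-phase (forward-backward) by default since analysis is offline;
    ``causal=True`` applies a single forward pass for real-time emulation.
    """
    sos = spec.sos(recording.fs)
    if causal:
        filtered = sps.sosfilt(sos, recording.samples, axis=1)
    else:
        filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return recording.with_samples(np.asarray(filtered))


def segment_windows(recording: SEMGRecording, spec: WindowSpec = WindowSpec()) -> list[Window]:
    """Slice a trial into fixed-length, possibly overlapping windows.

    After trimming ``trim_s`` seconds from each end, windows of exactly
    ``N = round(length_ms * fs / 1000)`` samples are taken at a hop of
    ``floor(N * (1 - overlap_fraction))`` (at least 1); a trailing partial
    window is discarded.
    """
    spec.validate()
    n = spec.n_samples(recording.fs)
    hop = spec.hop(recording.fs)
    trim = int(round(spec.trim_s * recording.fs))
    usable = recording.n_samples - 2 * trim
    if usable < n:
        raise ValidationError(
            f"trial too short: {usable} usable samples after trimming "
            f"{spec.trim_s} s from each end; at least {n} required"
        )
    data = recording.samples[:, trim: recording.n_samples - trim]
    starts = range(0, usable - n + 1, hop)
    return [
        Window(
            samples=data[:, s: s + n],
            posture=recording.posture,
            session_id=recording.session_id,
            day_id=recording.day_id,
            subject_id=recording.subject_id,
            channel_names=recording.channel_names,
            start_index=trim + s,
        )
        for s in starts
    ]


def segment_dataset(
    recordings: Iterable[SEMGRecording],
    window_spec: WindowSpec = WindowSpec(),
    filter_spec: FilterSpec | None = FilterSpec(),
    include_rest: bool = False,
) -> list[Window]:
    """Filter and window a collection of trials.

    Rest-calibration trials are excluded unless ``include_rest``; pass
    ``filter_spec=None`` to skip conditioning (already-filtered data).
    """
    out: list[Window] = []
    for rec in recordings:
        if rec.posture == REST_CALIBRATION and not include_rest:
            continue
        if filter_spec is not None:
            rec = bandpass_filter(rec, filter_spec)
        out.extend(segment_windows(rec, window_spec))
    return out
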