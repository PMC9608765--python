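"""Synthetic multichannel sEMG generator.

The simulator produces interference-pattern sEMG as amplitude-modulated
band-limited Gaussian noise: channel ``c`` of posture ``p`` is unit-RMS noise
band-passed around a per-(posture, channel) spectral centroid, scaled to a
target RMS ``amplitude_matrix[p, c] * exp(eps)`` with trial-to-trial
log-normal dispersion ``eps ~ Normal(0, sigma_trial[day]^2)``, then linearly
mixed across channels to model electrode crosstalk.  Shrinking the per-day
dispersion schedule emulates the variability reduction produced by
visual-feedback posture training; no motor-unit-level physiology is modeled.

Each simulated day holds ``sessions_per_day`` sessions; a session contains
one 5 s trial per posture in a seeded random order plus one low-amplitude
rest trial for threshold calibration.  Generation is bit-reproducible from
the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import (
    DEFAULT_CHANNELS_8,
    DEFAULT_CHANNELS_9,
    POSTURES,
    REST_CALIBRATION,
    SEMGRecording,
    ValidationError,
)

#: Relative bandwidth of the per-channel noise carrier: the band-pass spans
#: centroid * (1 +/- REL_BANDWIDTH / 2).  Wide enough that ZC/SSC carry real
#: spectral information, narrow enough that centroids stay distinguishable.
REL_BANDWIDTH = 0.6

_NOISE_FILTER_ORDER = 4


def _default_amplitude_matrix() -> np.ndarray:
    """12 postures x 9 channels of target RMS activations (unitless).

    Channel order: FDS, ED, EDM, EP, FCR, FCU, ECR, ECU, BR.  The block
    structure makes (cylindrical vs spherical grasp) and (palmar vs tip
    pinch) the two hardest pairs: each pair differs only slightly in
    amplitude, mirroring the confusion structure typical of grasp postures.
    """
    return np.array(
        [
            # FDS   ED    EDM   EP    FCR   FCU   ECR   ECU   BR
            [0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05],  # rest
            [0.15, 0.85, 0.80, 0.55, 0.10, 0.10, 0.55, 0.60, 0.20],  # spread
            [0.45, 0.75, 0.30, 0.25, 0.15, 0.20, 0.40, 0.35, 0.20],  # finger pointing
            [0.55, 0.60, 0.55, 0.30, 0.20, 0.25, 0.30, 0.45, 0.25],  # scissor sign
            [0.50, 0.70, 0.65, 0.35, 0.15, 0.15, 0.45, 0.40, 0.20],  # V sign
            [0.60, 0.40, 0.25, 0.60, 0.35, 0.20, 0.35, 0.25, 0.30],  # O.K. sign
            [0.55, 0.35, 0.30, 0.70, 0.25, 0.35, 0.50, 0.30, 0.45],  # thumb up (hook)
            [0.80, 0.45, 0.30, 0.35, 0.55, 0.50, 0.40, 0.45, 0.55],  # cylindrical grasp
            [0.75, 0.50, 0.35, 0.40, 0.50, 0.45, 0.45, 0.50, 0.50],  # spherical grasp
            [0.65, 0.30, 0.20, 0.50, 0.45, 0.55, 0.30, 0.40, 0.35],  # lateral pinch
            [0.60, 0.35, 0.25, 0.45, 0.40, 0.30, 0.35, 0.30, 0.30],  # palmar pinch
            [0.58, 0.38, 0.28, 0.48, 0.36, 0.28, 0.38, 0.33, 0.28],  # tip pinch
        ]
    )


def _default_centroid_matrix(n_postures: int = 12) -> np.ndarray:
    """12 x 9 spectral centroids in Hz.

    Each channel has a base centroid in the 80-130 Hz sEMG range; postures
    shift it by up to +/-15 %, so the spectrally informed features (ZC, SSC,
    WL) carry discriminative content that amplitude alone does not -- in
    particular the two amplitude-twin grasp/pinch pairs are pulled apart in
    frequency.
    """
    base = np.array([90.0, 120.0, 130.0, 110.0, 85.0, 80.0, 115.0, 125.0, 95.0])
    scale = np.linspace(0.85, 1.15, n_postures)[:, None]
    mat = base[None, :] * scale
    # widen the spectral gap inside the two hard amplitude pairs
    mat[7] *= 0.90   # cylindrical grasp
    mat[8] *= 1.10   # spherical grasp
    mat[10] *= 0.90  # palmar pinch
    mat[11] *= 1.10  # tip pinch
    return mat


@dataclass
class SynthConfig:
    """Full parameterization of the simulator.

    ``sigma_trial`` is the per-day multiplicative log-normal amplitude
    dispersion; its length sets the number of simulated days.  The default
    (0.5, 0.25, 0.1) schedule emulates an untrained first day followed by
    two feedback-training days.
    """

    channel_names: tuple[str, ...] = DEFAULT_CHANNELS_9
    postures: tuple[str, ...] = POSTURES
    amplitude_matrix: np.ndarray = field(default_factory=_default_amplitude_matrix)
    spectral_centroid_matrix: np.ndarray = field(default_factory=_default_centroid_matrix)
    sigma_trial: tuple[float, ...] = (0.5, 0.25, 0.1)
    crosstalk_lambda: float = 0.1
    rest_amplitude: float = 0.05
    fs: float = 1926.0
    trial_s: float = 5.0
    sessions_per_day: int = 10
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.postures = tuple(self.postures)
        self.amplitude_matrix = np.asarray(self.amplitude_matrix, dtype=np.float64)
        self.spectral_centroid_matrix = np.asarray(
            self.spectral_centroid_matrix, dtype=np.float64
        )
        self.sigma_trial = tuple(float(s) for s in self.sigma_trial)
        self.validate()

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_days(self) -> int:
        return len(self.sigma_trial)

    def validate(self) -> None:
        if not self.postures:
            raise ValidationError("posture set must not be empty")
        unknown = set(self.postures) - set(POSTURES)
        if unknown:
            raise ValidationError(f"unknown postures: {sorted(unknown)}")
        shape = (len(self.postures), self.n_channels)
        if self.amplitude_matrix.shape != shape:
            raise ValidationError(
                f"amplitude_matrix shape {self.amplitude_matrix.shape} != {shape}"
            )
        if self.spectral_centroid_matrix.shape != shape:
            raise ValidationError(
                f"spectral_centroid_matrix shape {self.spectral_centroid_matrix.shape} != {shape}"
            )
        if np.any(self.amplitude_matrix < 0):
            raise ValidationError("amplitude_matrix must be nonnegative")
        nyq = self.fs / 2
        cent = self.spectral_centroid_matrix
        if np.any(cent * (1 + REL_BANDWIDTH / 2) >= nyq) or np.any(
            cent * (1 - REL_BANDWIDTH / 2) <= 0
        ):
            raise ValidationError("spectral centroids place the noise band outside (0, fs/2)")
        if any(s < 0 for s in self.sigma_trial):
            raise ValidationError("sigma_trial entries must be >= 0")
        if not self.sigma_trial:
            raise ValidationError("sigma_trial schedule must contain at least one day")
        if not 0 <= self.crosstalk_lambda < 0.5:
            raise ValidationError("crosstalk_lambda must lie in [0, 0.5)")
        if self.rest_amplitude < 0:
            raise ValidationError("rest_amplitude must be >= 0")
        if self.sessions_per_day < 1:
            raise ValidationError("sessions_per_day must be >= 1")
        if self.trial_s <= 0 or self.fs <= 0:
            raise ValidationError("trial_s and fs must be positive")

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["amplitude_matrix"] = self.amplitude_matrix.tolist()
        d["spectral_centroid_matrix"] = self.spectral_centroid_matrix.tolist()
        d["channel_names"] = list(self.channel_names)
        d["postures"] = list(self.postures)
        d["sigma_trial"] = list(self.sigma_trial)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SynthConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized per-trial generation record (one per trial, rest included)."""

    posture: str
    day_id: int
    session_id: int
    realized_amplitudes: np.ndarray
    seed_lineage: tuple[int, ...]


def crosstalk_matrix(n_channels: int, lam: float) -> np.ndarray:
    """Row-stochastic mixing matrix: ``1 - lam`` on the diagonal and
    ``lam / (C - 1)`` off-diagonal."""
    if not 0 <= lam < 0.5:
        raise ValidationError(f"crosstalk lambda must lie in [0, 0.5), got {lam}")
    if n_channels == 1:
        return np.ones((1, 1))
    off = lam / (n_channels - 1)
    m = np.full((n_channels, n_channels), off)
    np.fill_diagonal(m, 1.0 - lam)
    return m


def apply_crosstalk(trial_matrix: np.ndarray, lam: float) -> np.ndarray:
    """Mix channels linearly to emulate inter-electrode crosstalk."""
    trial_matrix = np.atleast_2d(np.asarray(trial_matrix, dtype=np.float64))
    m = crosstalk_matrix(trial_matrix.shape[0], lam)
    return m @ trial_matrix


_sos_cache: dict[tuple[float, float], np.ndarray] = {}


def _carrier_sos(centroid: float, fs: float) -> np.ndarray:
    key = (round(float(centroid), 9), float(fs))
    if key not in _sos_cache:
        low = centroid * (1 - REL_BANDWIDTH / 2)
        high = centroid * (1 + REL_BANDWIDTH / 2)
        _sos_cache[key] = sps.butter(
            _NOISE_FILTER_ORDER, [low, high], btype="bandpass", fs=fs, output="sos"
        )
    return _sos_cache[key]


def _bandlimited_unit_noise(rng: np.random.Generator, n: int, fs: float, centroid: float) -> np.ndarray:
    """Gaussian noise band-passed around ``centroid``, normalized to exact unit RMS."""
    pad = int(fs)  # discard one second of filter transient
    x = rng.standard_normal(n + pad)
    y = sps.sosfilt(_carrier_sos(centroid, fs), x)[pad:]
    rms = np.sqrt(np.mean(y**2))
    return y / rms


def _trial_samples(
    rng: np.random.Generator,
    amplitudes: np.ndarray,
    centroids: np.ndarray,
    n: int,
    fs: float,
    lam: float,
) -> np.ndarray:
    chans = np.empty((len(amplitudes), n))
    for c, (a, fc) in enumerate(zip(amplitudes, centroids)):
        if a == 0:
            chans[c] = 0.0
            # keep the RNG stream aligned regardless of amplitude
            _ = rng.standard_normal(n + int(fs))
        else:
            chans[c] = a * _bandlimited_unit_noise(rng, n, fs, fc)
    return apply_crosstalk(chans, lam) if lam > 0 else chans


def generate_dataset(
    config: SynthConfig, days: Sequence[int] | None = None
) -> tuple[list[SEMGRecording], list[GroundTruth]]:
    """Simulate the full protocol: per day and session, one trial per posture
    in seeded random order plus one rest-calibration trial.

    Returns the recordings and a ground-truth record per trial.  Regenerating
    with the same config (and days) is bit-identical.
    """
    config.validate()
    if days is None:
        days = range(1, config.n_days + 1)
    days = list(days)
    if any(d < 1 or d > config.n_days for d in days):
        raise ValidationError(
            f"requested days {days} outside the {config.n_days}-day sigma_trial schedule"
        )
    n = int(round(config.trial_s * config.fs))
    centroids = config.spectral_centroid_matrix
    rest_centroids = centroids.mean(axis=0)
    recordings: list[SEMGRecording] = []
    truth: list[GroundTruth] = []
    for day in days:
        sigma = config.sigma_trial[day - 1]
        for session in range(1, config.sessions_per_day + 1):
            order_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, day, session, 0])
            )
            order = order_rng.permutation(len(config.postures))
            for slot, p_idx in enumerate(order, start=1):
                lineage = (config.seed, day, session, slot)
                rng = np.random.default_rng(np.random.SeedSequence(list(lineage)))
                eps = rng.normal(0.0, sigma, size=config.n_channels) if sigma > 0 else np.zeros(config.n_channels)
                amps = config.amplitude_matrix[p_idx] * np.exp(eps)
                samples = _trial_samples(
                    rng, amps, centroids[p_idx], n, config.fs, config.crosstalk_lambda
                )
                recordings.append(
                    SEMGRecording(
                        samples=samples,
                        fs=config.fs,
                        posture=config.postures[p_idx],
                        session_id=session,
                        day_id=day,
                        subject_id=config.subject_id,
                        channel_names=config.channel_names,
                    )
                )
                truth.append(
                    GroundTruth(
                        posture=config.postures[p_idx],
                        day_id=day,
                        session_id=session,
                        realized_amplitudes=amps,
                        seed_lineage=lineage,
                    )
                )
            # rest-calibration trial closes each session
            lineage = (config.seed, day, session, len(config.postures) + 1)
            rng = np.random.default_rng(np.random.SeedSequence(list(lineage)))
            rest_amps = np.full(config.n_channels, config.rest_amplitude)
            samples = _trial_samples(
                rng, rest_amps, rest_centroids, n, config.fs, config.crosstalk_lambda
            )
            recordings.append(
                SEMGRecording(
                    samples=samples,
                    fs=config.fs,
                    posture=REST_CALIBRATION,
                    session_id=session,
                    day_id=day,
                    subject_id=config.subject_id,
                    channel_names=config.channel_names,
                )
            )
            truth.append(
                GroundTruth(
                    posture=REST_CALIBRATION,
                    day_id=day,
                    session_id=session,
                    realized_amplitudes=rest_amps,
                    seed_lineage=lineage,
                )
            )
    return recordings, truth


def amputee_mode(config: SynthConfig, lost_channels: Sequence[int]) -> SynthConfig:
    """Remove channels (muscle loss) and re-normalize the amplitude matrix.

    Postures whose discriminative signal lived only on the lost channels
    become statistically confusable downstream.  The surviving matrix is
    rescaled so its global maximum matches the original's, preserving the
    overall amplitude scale.  An empty ``lost_channels`` returns the config
    unchanged.
    """
    lost = sorted(set(int(i) for i in lost_channels))
    if not lost:
        return config
    if any(i < 0 or i >= config.n_channels for i in lost):
        raise ValidationError(f"lost_channels {lost} outside 0..{config.n_channels - 1}")
    keep = [i for i in range(config.n_channels) if i not in lost]
    if not keep:
        raise ValidationError("cannot remove every channel")
    amp = config.amplitude_matrix[:, keep]
    old_max = config.amplitude_matrix.max()
    new_max = amp.max()
    if new_max > 0 and old_max > 0:
        amp = amp * (old_max / new_max)
    return replace(
        config,
        channel_names=tuple(config.channel_names[i] for i in keep),
        amplitude_matrix=amp,
        spectral_centroid_matrix=config.spectral_centroid_matrix[:, keep],
    )


def healthy_config(**overrides) -> SynthConfig:
    """The shipped healthy-adult scenario: 9 channels, 12 postures, 3-day
    sigma schedule (0.5, 0.25, 0.1), 10 sessions/day."""
    return SynthConfig(**overrides)


def amputee_config(**overrides) -> SynthConfig:
    """The shipped residual-limb scenario: 8 channels (BR, FCR, ECR, ED, ECU,
    FDP, FDS, FCU), higher initial variability over a 5-day schedule.

    This is an illustrative scenario, not a reconstruction of any particular
    subject's signal statistics: the FDP column is a deep-flexor profile
    correlated with FDS, and the grasp/pinch amplitude twins remain the hard
    pairs.
    """
    healthy = _default_amplitude_matrix()
    cent = _default_centroid_matrix()
    name_to_col = {n: i for i, n in enumerate(DEFAULT_CHANNELS_9)}
    amp_cols, cent_cols = [], []
    for name in DEFAULT_CHANNELS_8:
        if name == "FDP":
            amp_cols.append(0.85 * healthy[:, name_to_col["FDS"]])
            cent_cols.append(0.95 * cent[:, name_to_col["FDS"]])
        else:
            amp_cols.append(healthy[:, name_to_col[name]])
            cent_cols.append(cent[:, name_to_col[name]])
    defaults = dict(
        channel_names=DEFAULT_CHANNELS_8,
        amplitude_matrix=np.column_stack(amp_cols),
        spectral_centroid_matrix=np.column_stack(cent_cols),
        sigma_trial=(0.7, 0.5, 0.35, 0.2, 0.1),
        subject_id="synthetic-amputee",
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


def load_fixture_config(name: str) -> SynthConfig:
    """Load a shipped simulator fixture (``healthy_9ch`` or ``amputee_8ch``)."""
    path = Path(__file__).parent / "fixtures" / f"{name}.json"
    if not path.exists():
        raise FileNotFoundError(f"no shipped fixture named {name!r}")
    return SynthConfig.from_json(path)
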