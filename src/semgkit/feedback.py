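"""Radar-plot biofeedback targets and the end-to-end experiment pipeline.

Visual-feedback posture training shows the user a per-posture radar plot of
normalized channel activations; the user contracts muscles to match the
displayed shape.  This module computes those target patterns (mean per-window
MAV per channel, scaled by the maximum channel so the shape is
amplitude-free), scores a live activation vector against a target with a
clipped cosine similarity, renders static radar plots, and orchestrates the
full synthetic experiment: simulate -> condition -> features -> cross-test ->
cluster variability -> radar patterns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import classify, features as feat, synthetic_data, variability
from .signal_io import (
    REST_CALIBRATION,
    FilterSpec,
    SEMGRecording,
    ValidationError,
    WindowSpec,
    segment_dataset,
)


@dataclass
class RadarPattern:
    """Per-channel normalized activation in [0, 1] for one posture."""

    posture: str
    values: np.ndarray
    channel_names: tuple[str, ...]
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.channel_names):
            raise ValidationError("pattern length must equal channel count")


@dataclass
class MatchScore:
    score: float
    deviations: np.ndarray
    no_activation: bool = False


def compute_target_pattern(
    recordings: Sequence[SEMGRecording],
    posture: str,
    window_spec: WindowSpec = WindowSpec(),
) -> RadarPattern:
    """Mean per-window MAV per channel for the posture, scaled by the channel
    maximum.  Recordings are assumed already conditioned."""
    trials = [r for r in recordings if r.posture == posture]
    if not trials:
        raise ValidationError(f"no trials of posture {posture!r}")
    windows = segment_dataset(trials, window_spec, filter_spec=None, include_rest=True)
    fm = feat.extract_features(windows, feat.FeatureConfig(feat.MAV_ONLY, 0.0))
    mean_mav = fm.X.mean(axis=0)
    peak = mean_mav.max()
    if peak <= 0:
        warnings.warn(f"posture {posture!r} shows no activation; all-zero pattern", stacklevel=2)
        return RadarPattern(posture, np.zeros_like(mean_mav), trials[0].channel_names, all_zero=True)
    return RadarPattern(posture, mean_mav / peak, trials[0].channel_names)


def match_score(live_mav: np.ndarray, target: RadarPattern) -> MatchScore:
    """Cosine similarity (clipped to [0, 1]) between a live MAV vector and
    the target pattern, plus per-channel normalized deviations."""
    live = np.asarray(live_mav, dtype=np.float64).ravel()
    if live.shape != target.values.shape:
        raise ValidationError("live vector length must match the target pattern")
    if target.all_zero or target.values.max() <= 0:
        raise ValidationError("target pattern is all-zero; cannot score against it")
    live_norm = np.linalg.norm(live)
    if live_norm == 0:
        return MatchScore(0.0, target.values.copy(), no_activation=True)
    cos = float(live @ target.values / (live_norm * np.linalg.norm(target.values)))
    live_scaled = live / live.max() if live.max() > 0 else live
    return MatchScore(float(np.clip(cos, 0.0, 1.0)), np.abs(live_scaled - target.values))


def render_radar(pattern: RadarPattern, out_path) -> Path:
    """Export the pattern as a radar (polar polygon) plot; a sidecar CSV with
    the raw axis values is always written for headless testing.

    ``out_path`` ending in ``.csv`` writes only the CSV; any other suffix is
    handed to matplotlib (``.svg``, ``.png``...).
    """
    out = Path(out_path)
    csv_path = out if out.suffix == ".csv" else out.with_suffix(out.suffix + ".csv")
    header = ",".join(pattern.channel_names)
    values = ",".join(f"{v:.17g}" for v in pattern.values)
    csv_path.write_text(f"{header}\n{values}\n")
    if out.suffix == ".csv":
        return out
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(pattern.values)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    closed = np.concatenate([pattern.values, pattern.values[:1]])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.plot(np.concatenate([angles, angles[:1]]), closed, lw=1.5)
    ax.fill(np.concatenate([angles, angles[:1]]), closed, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(pattern.channel_names)
    ax.set_ylim(0, 1.05)
    ax.set_title(pattern.posture)
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return out


def read_radar_csv(path) -> tuple[tuple[str, ...], np.ndarray]:
    lines = Path(path).read_text().strip().splitlines()
    names = tuple(lines[0].split(","))
    values = np.array([float(v) for v in lines[1].split(",")])
    return names, values


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE = {
    "fixture": "healthy_9ch",
    "trn_levels": [1, 9],
    "feature_sets": [feat.MAV_ONLY, feat.HUDGINS],
    "R": 0.5,
    "window": {"length_ms": 250.0, "overlap_fraction": 0.5, "trim_s": 0.5},
    "filter": {"low_hz": 10.0, "high_hz": 500.0, "order": 4},
    "classifier": {"hidden_layers": [64], "max_epochs": 200},
    "silhouette": {"metric": "mahalanobis", "shrinkage": 0.1},
    "seed": 0,
}


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full synthetic experiment and return (and optionally write)
    the report: per-day / per-TRN-level / per-feature-set accuracies,
    confusion matrices, SC values, and radar patterns.

    The report is bit-reproducible from its manifest (config + seeds); any
    stage failure aborts with the stage name.
    """
    cfg = dict(DEFAULT_PIPELINE)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    stage = "configure"
    try:
        if "synth" in cfg:
            synth = synthetic_data.SynthConfig(**cfg["synth"])
        else:
            synth = synthetic_data.load_fixture_config(cfg["fixture"])
        synth = synthetic_data.SynthConfig(
            **{**json.loads(synth.to_json()), "seed": seed}
        )
        window_spec = WindowSpec(**cfg["window"])
        filter_spec = FilterSpec(**cfg["filter"])
        clf_spec = classify.ClassifierSpec(
            hidden_layers=tuple(cfg["classifier"]["hidden_layers"]),
            max_epochs=int(cfg["classifier"].get("max_epochs", 200)),
        )

        stage = "simulate"
        recordings, _ = synthetic_data.generate_dataset(synth)

        report: dict = {
            "config": cfg,
            "synth_config": json.loads(synth.to_json()),
            "seed": seed,
            "days": {},
        }
        for day in range(1, synth.n_days + 1):
            stage = f"day {day}"
            day_recs = [r for r in recordings if r.day_id == day]
            day_report: dict = {"accuracy": [], "confusion": {}, "sc": None}

            stage = f"day {day}: variability"
            from .signal_io import bandpass_filter

            filtered = [bandpass_filter(r, filter_spec) for r in day_recs]
            windows = segment_dataset(filtered, window_spec, filter_spec=None)
            fm = feat.extract_features(windows, feat.FeatureConfig(feat.MAV_ONLY, 0.0))
            points = variability.mav_pointset(fm)
            sc, rep = variability.silhouette_coefficient(
                points,
                metric=cfg["silhouette"]["metric"],
                shrinkage=cfg["silhouette"]["shrinkage"],
            )
            day_report["sc"] = sc
            day_report["mean_silhouette"] = rep.mean_silhouette

            for feature_set in cfg["feature_sets"]:
                fcfg = feat.FeatureConfig(feature_set, float(cfg["R"]))
                for k in cfg["trn_levels"]:
                    stage = f"day {day}: cross-test {feature_set} TRN{k}"
                    res = classify.cross_test(
                        day_recs, k, fcfg, clf_spec, seed=seed,
                        window_spec=window_spec, filter_spec=filter_spec,
                    )
                    day_report["accuracy"].append(
                        {
                            "feature_set": feature_set,
                            "trn_level": k,
                            "mean": res.mean_accuracy,
                            "sd": res.sd_accuracy,
                            "folds": res.fold_accuracies.tolist(),
                        }
                    )
                    day_report["confusion"][f"{feature_set}_TRN{k}"] = res.confusion.tolist()

            stage = f"day {day}: radar patterns"
            patterns = {}
            for posture in synth.postures:
                pat = compute_target_pattern(filtered, posture, window_spec)
                patterns[posture] = pat.values.tolist()
            day_report["radar_patterns"] = patterns
            report["days"][str(day)] = day_report
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest = {"config": cfg, "seed": seed, "fixture": cfg.get("fixture")}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        report["out_dir"] = str(out)
    return report
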