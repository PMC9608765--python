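"""Shared fixtures: small synthetic scenarios and independent oracles."""

import numpy as np
import pytest

import semgkit as sk
from semgkit.synthetic_data import SynthConfig


def make_config(
    postures=("rest", "spread", "cylindrical grasp", "tip pinch"),
    n_channels=3,
    sigma=(0.15,),
    sessions=10,
    trial_s=2.0,
    seed=7,
    amplitude=None,
    centroids=None,
    **kw,
):
    """Compact simulator config for fast tests."""
    p, c = len(postures), n_channels
    if amplitude is None:
        rng = np.random.default_rng(0)
        amplitude = 0.2 + 0.8 * rng.random((p, c))
        if "rest" in postures:
            amplitude[list(postures).index("rest")] = 0.05
    if centroids is None:
        centroids = np.linspace(80, 160, p)[:, None] * np.linspace(0.9, 1.1, c)[None, :]
    return SynthConfig(
        channel_names=tuple(f"ch{i+1}" for i in range(c)),
        postures=tuple(postures),
        amplitude_matrix=np.asarray(amplitude, dtype=float),
        spectral_centroid_matrix=np.asarray(centroids, dtype=float),
        sigma_trial=tuple(sigma),
        sessions_per_day=sessions,
        trial_s=trial_s,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 postures x 10 sessions x 1 day, 3 channels, 2 s trials."""
    cfg = make_config()
    recordings, truth = sk.generate_dataset(cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def tiny_windows(tiny_dataset):
    _, recordings, _ = tiny_dataset
    return sk.segment_dataset(recordings[:30])


# ---------------------------------------------------------------------------
# independent naive-loop oracles
# ---------------------------------------------------------------------------

def mav_oracle(x):
    return sum(abs(float(v)) for v in x) / len(x)


def wl_oracle(x):
    return sum(abs(float(x[i + 1]) - float(x[i])) for i in range(len(x) - 1))


def zc_oracle(x, threshold):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= threshold:
            count += 1
    return count


def ssc_oracle(x, threshold):
    count = 0
    for i in range(1, len(x) - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= threshold:
            count += 1
    return count


def silhouette_oracle(D, labels):
    """Brute-force per-point silhouettes from a precomputed distance matrix."""
    labels = np.asarray(labels)
    n = len(labels)
    uniq = sorted(set(labels.tolist()))
    s = np.zeros(n)
    for i in range(n):
        mine = labels[i]
        same = [j for j in range(n) if labels[j] == mine and j != i]
        if not same:
            s[i] = 0.0
            continue
        a = sum(D[i, j] for j in same) / len(same)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == other) / sum(labels == other)
            for other in uniq
            if other != mine
        )
        s[i] = (b - a) / max(a, b)
    cluster_means = {c: float(np.mean(s[labels == c])) for c in uniq}
    return s, cluster_means, max(cluster_means.values())
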