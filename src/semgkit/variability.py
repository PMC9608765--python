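"""Posture-cluster variability: Mahalanobis distances, silhouettes, embedding.

Points are per-window MAV vectors (one dimension per channel), labeled by
posture.  For point ``i`` in cluster ``C_I``:

* ``a_i`` -- mean distance to the other members of its own cluster
  (divisor ``|C_I| - 1``),
* ``b_i`` -- the minimum over other clusters of the mean distance to that
  cluster's members,
* ``s_i = (b_i - a_i) / max(a_i, b_i)`` when ``|C_I| > 1``, else ``s_i = 0``.

The scalar summary ``SC`` is the **maximum** per-cluster mean silhouette —
note this differs from the more common all-point mean, which is reported
alongside.  Distances default to Mahalanobis with a single covariance pooled
over all points and shrunk toward a scaled identity for stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from . import features as feat
from .signal_io import ValidationError

EUCLIDEAN = "euclidean"
MAHALANOBIS = "mahalanobis"


@dataclass
class PointSet:
    """n x d points with cluster (posture) labels and optional metadata."""

    points: np.ndarray
    labels: np.ndarray
    session_ids: np.ndarray | None = None
    day_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.labels = np.asarray(self.labels)
        if self.points.shape[0] != len(self.labels):
            raise ValidationError("one label per point required")
        if self.points.shape[0] < 2:
            raise ValidationError("need at least 2 points")


def mav_pointset(fm: feat.FeatureMatrix) -> PointSet:
    """Per-window MAV vectors (d = channel count) from a feature matrix."""
    if fm.feature_set == feat.MAV_ONLY:
        X = fm.X
    else:
        X = fm.X[:, 0::4]  # MAV occupies the first slot of each channel block
    return PointSet(X, fm.labels, fm.session_ids, fm.day_ids)


@dataclass
class SilhouetteReport:
    """Per-point silhouette decomposition plus the scalar SC."""

    s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    cluster_means: dict[str, float]
    sc: float
    mean_silhouette: float
    metric: str
    shrinkage: float | None
    condition_number: float | None


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pooled_covariance(points: np.ndarray, shrinkage: float = 0.1) -> tuple[np.ndarray, np.ndarray, float]:
    """Shrunk pooled covariance ``(1 - g) S + g (tr S / d) I`` and its inverse.

    Returns ``(cov, inv_cov, condition_number)``.  Full shrinkage (g = 1)
    gives an exact scaled identity; g = 0 on degenerate data raises with
    advice to use g > 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not 0 <= shrinkage <= 1:
        raise ValidationError("shrinkage must lie in [0, 1]")
    n, d = points.shape
    if n < 2:
        raise ValidationError("covariance needs at least 2 points")
    S = np.cov(points, rowvar=False).reshape(d, d)
    target = (np.trace(S) / d) * np.eye(d)
    cov = (1.0 - shrinkage) * S + shrinkage * target
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or not np.isfinite(eigvals).all():
        raise ValidationError(
            "pooled covariance is singular (zero-variance data?); use shrinkage > 0"
        )
    cond = float(eigvals[-1] / eigvals[0])
    return cov, np.linalg.inv(cov), cond


def mahalanobis_distance(x, y, inverse_covariance: np.ndarray) -> float:
    """``sqrt((x - y)^T VI (x - y))`` for a positive-definite ``VI``."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    vi = np.asarray(inverse_covariance, dtype=np.float64)
    if x.shape != y.shape or vi.shape != (x.size, x.size):
        raise ValidationError(
            f"dimension mismatch: x {x.shape}, y {y.shape}, VI {vi.shape}"
        )
    delta = x - y
    return float(np.sqrt(delta @ vi @ delta))


def pairwise_distances(
    points: np.ndarray, metric: str = EUCLIDEAN, inverse_covariance: np.ndarray | None = None
) -> np.ndarray:
    """Full n x n distance matrix, Euclidean or Mahalanobis."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if metric == EUCLIDEAN:
        return cdist(points, points)
    if metric == MAHALANOBIS:
        if inverse_covariance is None:
            raise ValidationError("Mahalanobis metric requires an inverse covariance")
        return cdist(points, points, metric="mahalanobis", VI=inverse_covariance)
    raise ValidationError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# silhouettes
# ---------------------------------------------------------------------------

def silhouette_values(
    point_set: PointSet,
    metric: str = MAHALANOBIS,
    shrinkage: float = 0.1,
    distance_matrix: np.ndarray | None = None,
) -> SilhouetteReport:
    """Per-point silhouettes and per-cluster means under the chosen metric.

    ``a_i`` excludes the point itself; singleton clusters get ``s_i = 0``.
    A precomputed ``distance_matrix`` overrides the metric machinery.
    """
    labels = point_set.labels
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError(
            "silhouette requires >= 2 clusters (b_i is a minimum over other clusters)"
        )
    cond = None
    shr = None
    if distance_matrix is not None:
        D = np.asarray(distance_matrix, dtype=np.float64)
        metric = "precomputed"
    elif metric == MAHALANOBIS:
        _, vi, cond = pooled_covariance(point_set.points, shrinkage)
        shr = shrinkage
        D = pairwise_distances(point_set.points, MAHALANOBIS, vi)
    else:
        D = pairwise_distances(point_set.points, EUCLIDEAN)

    n = len(labels)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}
    # mean distance from every point to every cluster, (n, n_clusters)
    mean_to = np.column_stack([D[:, masks[c]].mean(axis=1) for c in uniq])
    col = {c: j for j, c in enumerate(uniq)}

    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for c in uniq:
        m = masks[c]
        size = sizes[c]
        j = col[c]
        others = [col[o] for o in uniq if o != c]
        b[m] = mean_to[np.ix_(m, others)].min(axis=1)
        if size > 1:
            # remove the self term from the within-cluster mean
            a[m] = (mean_to[m, j] * size) / (size - 1)
            s[m] = (b[m] - a[m]) / np.maximum(a[m], b[m])
        else:
            a[m] = 0.0
            s[m] = 0.0  # singleton branch
    cluster_means = {str(c): float(s[masks[c]].mean()) for c in uniq}
    sc = max(cluster_means.values())
    return SilhouetteReport(
        s=s,
        a=a,
        b=b,
        cluster_means=cluster_means,
        sc=float(sc),
        mean_silhouette=float(s.mean()),
        metric=metric,
        shrinkage=shr,
        condition_number=cond,
    )


def silhouette_coefficient(
    point_set: PointSet,
    metric: str = MAHALANOBIS,
    shrinkage: float = 0.1,
    distance_matrix: np.ndarray | None = None,
) -> tuple[float, SilhouetteReport]:
    """The scalar SC (maximum per-cluster mean silhouette) with its report."""
    report = silhouette_values(point_set, metric, shrinkage, distance_matrix)
    return report.sc, report


# ---------------------------------------------------------------------------
# 2-D embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    perplexity: float
    seed: int
    kl_divergence: float


def embed_2d(point_set: PointSet, perplexity: float = 30.0, seed: int = 0) -> EmbeddingResult:
    """t-SNE projection to 2-D for cluster visualization; deterministic given
    the seed; coordinates are centered at the origin."""
    n = point_set.points.shape[0]
    if n <= 3 * perplexity:
        raise ValidationError(
            f"perplexity {perplexity} too large for n={n}; need n > 3 x perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=500,
    )
    coords = np.asarray(tsne.fit_transform(point_set.points), dtype=np.float64)
    coords = coords - coords.mean(axis=0)
    return EmbeddingResult(
        coordinates=coords,
        perplexity=perplexity,
        seed=seed,
        kl_divergence=float(tsne.kl_divergence_),
    )
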