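"""Posterior k-means clustering of reconstructed images (k = 4).

Pixels of a regularized EIT image fall into four populations: the
object core, the blurred object boundary (artifact-object mixture),
residual artifacts, and the background.  Clustering the interior-pixel
values with k = 4 recovers these populations without per-image
thresholds.  After convergence the clusters are relabelled by
descending centre so that label 1 is always *Object*, 2
*Artifact-Object Mixture*, 3 *Artifact*, and 4 *Background*.

The implementation is Lloyd's algorithm on the (scalar) pixel values
with seeded k-means++ initialization: assignment ties go to the lowest
cluster index, an emptied cluster is re-seeded at the point farthest
from its current centre, and iteration stops when the assignments no
longer change.  Images with fewer than four distinct values collapse to
the distinct-value partition, with empty clusters recorded as NaN
centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OBJECT",
    "MIXTURE",
    "ARTIFACT",
    "BACKGROUND",
    "ClusterResult",
    "kmeans4",
]

OBJECT, MIXTURE, ARTIFACT, BACKGROUND = 1, 2, 3, 4
_K = 4


@dataclass(eq=False)
class ClusterResult:
    """Result of the posterior clustering.

    ``labels`` holds 1..4 per pixel (1 = largest centre).  ``centers``
    is sorted descending; entries of empty (degenerate) clusters are
    NaN.  ``inertia_history`` records the within-cluster sum of squares
    after every Lloyd update.
    """

    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    n_iter: int
    inertia_history: np.ndarray

    @property
    def w(self) -> np.ndarray:
        """One-hot assignment matrix (n_pixels, 4)."""
        w = np.zeros((self.labels.shape[0], _K))
        w[np.arange(self.labels.shape[0]), self.labels - 1] = 1.0
        return w

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _kmeanspp_init(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard k-means++ seeding on scalar data."""
    centers = np.empty(_K)
    centers[0] = v[rng.integers(len(v))]
    d2 = (v - centers[0]) ** 2
    for j in range(1, _K):
        total = d2.sum()
        if total == 0:
            centers[j:] = v[rng.integers(len(v), size=_K - j)]
            break
        probs = d2 / total
        centers[j] = v[rng.choice(len(v), p=probs)]
        d2 = np.minimum(d2, (v - centers[j]) ** 2)
    return centers


def _assign(v: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin breaks ties toward the lowest cluster index
    return np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)


def _degenerate(v: np.ndarray) -> ClusterResult:
    """Fewer than 4 distinct values: the distinct-value partition."""
    distinct = np.unique(v)[::-1]  # descending
    centers = np.full(_K, np.nan)
    centers[: len(distinct)] = distinct
    labels = np.searchsorted(-distinct, -v) + 1
    return ClusterResult(
        labels=labels.astype(np.intp),
        centers=centers,
        inertia=0.0,
        n_iter=0,
        inertia_history=np.zeros(1),
    )


def kmeans4(
    values: np.ndarray,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 0.0,
    init: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster scalar pixel values into the four-type taxonomy.

    Parameters
    ----------
    values : array
        Interior-pixel values (flattened).
    seed : int
        Seed for the k-means++ initialization.
    max_iter : int
        Iteration cap for Lloyd's algorithm.
    tol : float
        Optional early stop on the inertia decrease (0 = exact
        stop on unchanged assignments).
    init : array, optional
        Explicit initial centres (length 4), overriding k-means++.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < _K:
        raise ValueError(f"need at least {_K} pixels, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("pixel values must be finite")
    if np.unique(v).size < _K:
        return _degenerate(v)

    rng = np.random.default_rng(seed)
    centers = np.asarray(init, dtype=float).copy() if init is not None else _kmeanspp_init(v, rng)
    if centers.shape != (_K,):
        raise ValueError("init must provide exactly 4 centres")

    labels = _assign(v, centers)
    history = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for j in range(_K):
            members = v[labels == j]
            if members.size:
                centers[j] = members.mean()
            else:
                # re-seed an emptied cluster at the farthest point
                far = np.argmax((v - centers[labels]) ** 2)
                centers[j] = v[far]
        new_labels = _assign(v, centers)
        inertia = float(np.sum((v - centers[new_labels]) ** 2))
        history.append(inertia)
        if np.array_equal(new_labels, labels):
            break
        if tol > 0 and len(history) > 1 and history[-2] - history[-1] <= tol:
            labels = new_labels
            break
        labels = new_labels

    # exact cluster-mean fixed point for the reported centres
    for j in range(_K):
        members = v[labels == j]
        if members.size:
            centers[j] = members.mean()

    order = np.argsort(centers)[::-1]  # descending centres -> labels 1..4
    rank = np.empty(_K, dtype=np.intp)
    rank[order] = np.arange(_K)
    return ClusterResult(
        labels=(rank[labels] + 1).astype(np.intp),
        centers=centers[order],
        inertia=float(np.sum((v - centers[labels]) ** 2)),
        n_iter=n_iter,
        inertia_history=np.asarray(history),
    )
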