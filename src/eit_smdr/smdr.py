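"""Sensitivity-matrix decomposition regularization (SMDR).

The pipeline refines a Tikhonov reconstruction by treating its k-means
clustering as approximate posterior information about where the objects
are:

1. initial Tikhonov reconstruction of ``dU`` against the full
   sensitivity matrix ``S0``;
2. k-means clustering (k = 4) of the image into Object,
   Artifact-Object Mixture, Artifact, and Background pixels; by
   default the clustering features are location-compensated (each
   pixel scaled by ``r - d_i``) so that the depth bias of EIT
   amplitudes does not push central objects into the Artifact cluster;
3. column-wise decomposition ``S0 = S1 + S2 + S3 + S4`` aligned with
   the cluster labels (``Sc`` keeps the columns of cluster ``c``);
4. differential re-reconstruction: solve once with the working area
   restricted to clusters 1-3 and once with the Artifact area alone,
   and subtract — the common blurred-boundary response cancels while
   the object response survives;
5. post-processing: keep positive values, normalize to unit maximum,
   re-cluster, and zero the Artifact and Background pixels.

The final image is therefore in [0, 1] with support confined to the
Object and Mixture clusters of the second clustering.  A single
regularization parameter (the one resolved for the initial image) is
reused for both decomposed solves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cluster import ARTIFACT, BACKGROUND, MIXTURE, OBJECT, ClusterResult, kmeans4
from .grid import PixelGrid
from .recon import (
    RegularizerConfig,
    TikhonovReconstructor,
    _as_matrix,
    _frame_values,
    tikhonov_dual,
)

__all__ = [
    "DecomposedSensitivity",
    "SMDRResult",
    "SMDRReconstructor",
    "decompose_sensitivity",
    "differential_rereconstruct",
    "filter_normalize",
    "postprocess",
    "smdr",
]

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class DecomposedSensitivity:
    """Column partition of the sensitivity matrix by cluster label."""

    parts: dict
    labels: np.ndarray = field(repr=False)

    def __getitem__(self, label: int) -> np.ndarray:
        return self.parts[label]

    def working(self, labels) -> np.ndarray:
        """Sum of the parts for the given working-area labels."""
        return sum(self.parts[c] for c in labels)


def decompose_sensitivity(S0, clusters: ClusterResult | np.ndarray) -> DecomposedSensitivity:
    """Split ``S0`` column-wise into the four cluster-aligned parts.

    Part ``c`` keeps the columns of pixels labelled ``c`` and zeros the
    rest, so ``S1 + S2 + S3 + S4 == S0`` exactly.
    """
    S0 = _as_matrix(S0)
    labels = clusters.labels if isinstance(clusters, ClusterResult) else np.asarray(clusters)
    if labels.shape != (S0.shape[1],):
        raise ValueError(
            f"label vector length {labels.shape} does not match the "
            f"{S0.shape[1]} sensitivity columns"
        )
    parts = {}
    for c in (OBJECT, MIXTURE, ARTIFACT, BACKGROUND):
        Sc = np.zeros_like(S0)
        cols = labels == c
        Sc[:, cols] = S0[:, cols]
        parts[c] = Sc
    return DecomposedSensitivity(parts=parts, labels=labels)


def differential_rereconstruct(
    dec: DecomposedSensitivity, dU, lam: float
) -> np.ndarray:
    """Difference of the clusters-1-3 and Artifact-only reconstructions.

    Solves the Tikhonov problem twice with the same lambda — once with
    the working area Object + Mixture + Artifact, once with Artifact
    alone — and returns their elementwise difference.  The Artifact-only
    solve contains no object response, so subtracting it suppresses the
    shared blurred-boundary terms.
    """
    d = _frame_values(dU)
    labels = dec.labels
    if not np.any((labels == OBJECT) | (labels == MIXTURE) | (labels == ARTIFACT)):
        raise ValueError(
            "empty working area: no pixel is labelled Object, Mixture, or Artifact"
        )
    S123 = dec.working((OBJECT, MIXTURE, ARTIFACT))
    x123 = tikhonov_dual(S123, d, lam)
    if np.any(labels == ARTIFACT):
        x3 = tikhonov_dual(dec[ARTIFACT], d, lam)
    else:
        x3 = np.zeros_like(x123)
    return x123 - x3


def filter_normalize(values: np.ndarray) -> np.ndarray:
    """Keep positive values and scale them to unit maximum.

    Non-positive pixels become 0.  If no pixel is positive the output
    is all zero (object absent; logged as a warning).
    """
    v = np.asarray(values, dtype=float)
    pos = v > 0
    if not np.any(pos):
        logger.warning("filter_normalize: no positive values — object absent")
        return np.zeros_like(v)
    out = np.zeros_like(v)
    out[pos] = v[pos] / v[pos].max()
    return out


def postprocess(values: np.ndarray, seed: int = 0):
    """Re-cluster a normalized image and zero Artifact/Background pixels.

    Returns ``(cleaned, clusters)``; Object and Mixture pixels pass
    through unchanged.
    """
    v = np.asarray(values, dtype=float)
    clusters = kmeans4(v, seed=seed)
    out = np.where((clusters.labels == OBJECT) | (clusters.labels == MIXTURE), v, 0.0)
    return out, clusters


@dataclass(eq=False)
class SMDRResult:
    """Final image plus every intermediate stage of the pipeline."""

    image: np.ndarray  # final cleaned, normalized interior vector
    initial: np.ndarray  # initial Tikhonov image
    clusters_initial: ClusterResult
    differential: np.ndarray  # x_{1,2,3} - x_3 before filtering
    normalized: np.ndarray  # after filter/normalize
    clusters_post: ClusterResult
    lambda_: float
    object_absent: bool


class SMDRReconstructor(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer running the full SMDR pipeline.

    ``fit`` takes the pixel-basis sensitivity matrix; ``transform`` maps
    frames to cleaned, [0, 1]-normalized interior-pixel images.

    Parameters
    ----------
    lam : float or "auto"
        Regularization parameter for the initial reconstruction, reused
        in both decomposed solves; "auto" = per-frame GCV.
    grid_min, grid_max, n_grid : float, float, int
        The GCV search grid.
    random_state : int
        Seed for both k-means++ initializations.
    max_iter : int
        Lloyd iteration cap.
    compensate_clustering : bool
        Cluster on the location-compensated initial image (default).
        EIT amplitudes are depth-biased — boundary objects dominate raw
        images — so compensating the *clustering features* keeps central
        objects out of the Artifact cluster that the differential step
        subtracts.  The reconstruction solves and the returned image are
        unaffected.  Needs a pixel grid (taken from a
        ``SensitivityMatrix`` input or the ``grid`` parameter); without
        one the raw image is clustered.
    grid : PixelGrid, optional
        Pixel grid for the compensation weights when ``fit`` receives a
        plain array.
    """

    def __init__(
        self,
        lam: float | str = "auto",
        grid_min: float = 1e-3,
        grid_max: float = 1.0,
        n_grid: int = 20,
        random_state: int = 0,
        max_iter: int = 300,
        compensate_clustering: bool = True,
        grid: PixelGrid | None = None,
    ):
        self.lam = lam
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.n_grid = n_grid
        self.random_state = random_state
        self.max_iter = max_iter
        self.compensate_clustering = compensate_clustering
        self.grid = grid

    def fit(self, X, y=None):
        """Store the sensitivity matrix (and its SVD for the initial solve)."""
        self.tik_ = TikhonovReconstructor(
            lam=self.lam, grid_min=self.grid_min, grid_max=self.grid_max, n_grid=self.n_grid
        ).fit(X)
        self.S_ = self.tik_.S_
        self.n_measurements_, self.n_pixels_ = self.S_.shape
        grid = getattr(X, "grid", None) or self.grid
        self.cluster_weights_ = None
        if self.compensate_clustering and grid is not None and grid.M == self.n_pixels_:
            self.cluster_weights_ = grid.radius - grid.distances
        return self

    def _cluster_features(self, image: np.ndarray) -> np.ndarray:
        if self.cluster_weights_ is None:
            return image
        return image * self.cluster_weights_

    def reconstruct(self, dU) -> SMDRResult:
        """Run the five pipeline stages on one frame, keeping intermediates."""
        check_is_fitted(self, "S_")
        d = _frame_values(dU)
        seed = self.random_state

        initial = self.tik_.transform(d)
        lam = self.tik_.lambda_
        logger.debug("smdr: initial reconstruction done (lambda=%.3g)", lam)

        if not np.any(initial != 0.0):
            # degenerate frame: nothing to cluster on, object absent
            logger.warning("smdr: all-zero initial image — reporting absent object")
            clusters = kmeans4(initial, seed=seed)
            zeros = np.zeros_like(initial)
            return SMDRResult(
                image=zeros,
                initial=initial,
                clusters_initial=clusters,
                differential=zeros,
                normalized=zeros,
                clusters_post=clusters,
                lambda_=lam,
                object_absent=True,
            )

        clusters = kmeans4(self._cluster_features(initial), seed=seed,
                           max_iter=self.max_iter)
        logger.debug("smdr: clustering done (%d iterations)", clusters.n_iter)
        dec = decompose_sensitivity(self.S_, clusters)
        diff = differential_rereconstruct(dec, d, lam)
        logger.debug("smdr: differential re-reconstruction done")
        normalized = filter_normalize(diff)
        absent = not np.any(normalized > 0)
        cleaned, clusters_post = postprocess(normalized, seed=seed)
        logger.debug("smdr: post-processing done")
        return SMDRResult(
            image=cleaned,
            initial=initial,
            clusters_initial=clusters,
            differential=diff,
            normalized=normalized,
            clusters_post=clusters_post,
            lambda_=lam,
            object_absent=absent,
        )

    def transform(self, X) -> np.ndarray:
        """Reconstruct one frame (N,) or a stack (n, N) of frames."""
        check_is_fitted(self, "S_")
        d = _frame_values(X)
        single = d.ndim == 1
        d = np.atleast_2d(d)
        out = np.empty((d.shape[0], self.n_pixels_))
        for i, row in enumerate(d):
            out[i] = self.reconstruct(row).image
        return out[0] if single else out


def smdr(
    S0,
    dU,
    cfg: RegularizerConfig | None = None,
    seed: int = 0,
    grid: PixelGrid | None = None,
    return_details: bool = False,
):
    """One-shot SMDR reconstruction.

    Returns the interior-pixel vector (or the embedded image when a
    grid is given); with ``return_details=True`` returns the full
    :class:`SMDRResult`.
    """
    cfg = cfg or RegularizerConfig()
    est = SMDRReconstructor(
        lam=cfg.lam,
        grid_min=cfg.grid_min,
        grid_max=cfg.grid_max,
        n_grid=cfg.n_grid,
        random_state=seed,
        grid=grid,
    ).fit(S0)
    result = est.reconstruct(dU)
    if return_details:
        return result
    return grid.embed(result.image) if grid is not None else result.image
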