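"""64x64 pixel grid over the sensor disk and mesh-to-pixel rasterization.

Reconstruction operates on a square pixel grid covering ``[-r, r]^2``
with the circular mask of pixels whose centres lie strictly inside the
disk.  Pixel (0, 0) is the top-left corner, storage is row-major, and
the centre of pixel ``(i, j)`` is at

    x = -r + (j + 0.5) * 2r / side,   y = r - (i + 0.5) * 2r / side.

Mesh quantities are pushed onto the grid by sampling each triangle at a
regular barycentric sub-grid (equal-weight quadrature) and binning the
samples into pixels:

* conductivity-like fields use the area-weighted average per pixel;
* sensitivity columns distribute each element's Jacobian entry over the
  pixels it overlaps in proportion to the overlap area, so that
  ``dU ~= S @ dsigma`` carries over to the pixel basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .mesh import Mesh

__all__ = ["PixelGrid", "SensitivityMatrix", "rasterize_field", "rasterize_sensitivity"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class PixelGrid:
    """Square pixel grid with a circular interior mask."""

    side: int = 64
    radius: float = 1.0

    @property
    def pixel_size(self) -> float:
        return 2.0 * self.radius / self.side

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2

    @cached_property
    def centers(self) -> np.ndarray:
        """(side, side, 2) array of pixel-centre coordinates."""
        step = self.pixel_size
        x = -self.radius + (np.arange(self.side) + 0.5) * step
        y = self.radius - (np.arange(self.side) + 0.5) * step
        cx, cy = np.meshgrid(x, y)  # row i -> y[i], col j -> x[j]
        return np.stack([cx, cy], axis=-1)

    @cached_property
    def mask(self) -> np.ndarray:
        """(side, side) boolean mask of pixels with centre inside the disk."""
        c = self.centers
        return c[..., 0] ** 2 + c[..., 1] ** 2 < self.radius**2

    @property
    def M(self) -> int:
        """Number of interior pixels."""
        return int(self.mask.sum())

    @cached_property
    def interior_centers(self) -> np.ndarray:
        """(M, 2) centres of interior pixels in row-major order."""
        return self.centers[self.mask]

    @cached_property
    def distances(self) -> np.ndarray:
        """(M,) distance of each interior pixel centre from the domain centre."""
        c = self.interior_centers
        return np.hypot(c[:, 0], c[:, 1])

    @cached_property
    def _interior_index(self) -> np.ndarray:
        """(side, side) map from pixel to interior index, -1 outside."""
        idx = np.full((self.side, self.side), -1, dtype=np.intp)
        idx[self.mask] = np.arange(self.M)
        return idx

    def embed(self, values: np.ndarray) -> np.ndarray:
        """Scatter an (M,) interior vector into a (side, side) image."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.M,):
            raise ValueError(f"expected shape ({self.M},), got {values.shape}")
        img = np.zeros((self.side, self.side))
        img[self.mask] = values
        return img

    def extract(self, image: np.ndarray) -> np.ndarray:
        """Gather the (M,) interior vector from a (side, side) image."""
        image = np.asarray(image, dtype=float)
        if image.shape != (self.side, self.side):
            raise ValueError(f"expected shape {(self.side, self.side)}, got {image.shape}")
        return image[self.mask]

    def pixel_of(self, points: np.ndarray) -> np.ndarray:
        """Interior-pixel index of each point; -1 for masked-out pixels."""
        points = np.atleast_2d(points)
        step = self.pixel_size
        col = np.clip(((points[:, 0] + self.radius) / step).astype(np.intp), 0, self.side - 1)
        row = np.clip(((self.radius - points[:, 1]) / step).astype(np.intp), 0, self.side - 1)
        return self._interior_index[row, col]


@dataclass(eq=False)
class SensitivityMatrix:
    """Pixel-basis sensitivity: N measurements x M interior pixels."""

    values: np.ndarray
    grid: PixelGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.M:
            raise ValueError(
                f"sensitivity shape {self.values.shape} does not match the "
                f"grid's {self.grid.M} interior pixels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensitivity entries must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _triangle_samples(mesh: Mesh, n_sub: int):
    """Equal-weight sample points on a regular barycentric refinement.

    Each triangle is split into ``n_sub**2`` congruent sub-triangles and
    sampled at their centroids, giving points with weight
    ``area / n_sub**2``.  Returns ``(points, element_index, weights)``.
    """
    bary = []
    for i in range(n_sub):
        for j in range(n_sub - i):
            # upright sub-triangle centroid
            bary.append(((i + 1 / 3), (j + 1 / 3)))
            if i + j < n_sub - 1:
                # inverted sub-triangle centroid
                bary.append(((i + 2 / 3), (j + 2 / 3)))
    bary = np.asarray(bary) / n_sub  # (k, 2) barycentric (l1, l2)
    l1, l2 = bary[:, 0], bary[:, 1]
    l0 = 1.0 - l1 - l2
    p = mesh.nodes[mesh.elements]  # (ne, 3, 2)
    pts = (
        l0[None, :, None] * p[:, 0, None, :]
        + l1[None, :, None] * p[:, 1, None, :]
        + l2[None, :, None] * p[:, 2, None, :]
    )  # (ne, k, 2)
    k = bary.shape[0]
    elem = np.repeat(np.arange(mesh.n_elements), k)
    weights = np.repeat(mesh.areas / k, k)
    return pts.reshape(-1, 2), elem, weights


def _overlap_matrix(mesh: Mesh, grid: PixelGrid, n_sub: int) -> sp.csr_matrix:
    """Sparse (n_elements, M) matrix of approximate overlap areas."""
    pts, elem, w = _triangle_samples(mesh, n_sub)
    pix = grid.pixel_of(pts)
    keep = pix >= 0
    T = sp.coo_matrix(
        (w[keep], (elem[keep], pix[keep])),
        shape=(mesh.n_elements, grid.M),
    )
    return T.tocsr()


def rasterize_field(
    values: np.ndarray, mesh: Mesh, grid: PixelGrid, n_sub: int = 4
) -> np.ndarray:
    """Area-weighted average of a per-element field on the pixel grid.

    Returns a (side, side) image with masked-out pixels set to 0.
    Interior pixels not overlapped by any sample are filled with the
    value of the nearest element centroid (logged).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (mesh.n_elements,):
        raise ValueError("field length does not match the element count")
    if not np.all(np.isfinite(values)):
        raise ValueError("field values must be finite")
    T = _overlap_matrix(mesh, grid, n_sub)
    num = T.T @ values
    den = np.asarray(T.sum(axis=0)).ravel()
    out = np.zeros(grid.M)
    covered = den > 0
    out[covered] = num[covered] / den[covered]
    n_empty = int((~covered).sum())
    if n_empty:
        logger.info("rasterize: filling %d empty interior pixels from nearest elements", n_empty)
        tree = cKDTree(mesh.centroids)
        _, nearest = tree.query(grid.interior_centers[~covered])
        out[~covered] = values[nearest]
    return grid.embed(out)


def rasterize_sensitivity(
    S_elements: np.ndarray, mesh: Mesh, grid: PixelGrid, n_sub: int = 4
) -> SensitivityMatrix:
    """Project a per-element sensitivity table onto the pixel basis.

    Each element's Jacobian entries are split over the pixels it
    overlaps in proportion to the overlap area, so a pixel column is
    the derivative with respect to a uniform perturbation of that pixel.
    """
    S_elements = np.asarray(S_elements, dtype=float)
    if S_elements.ndim != 2 or S_elements.shape[1] != mesh.n_elements:
        raise ValueError("sensitivity table must be (n_measurements, n_elements)")
    T = _overlap_matrix(mesh, grid, n_sub)
    frac = sp.diags(1.0 / mesh.areas) @ T  # row e: fraction of element e per pixel
    values = S_elements @ frac
    return SensitivityMatrix(values=np.asarray(values), grid=grid)
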