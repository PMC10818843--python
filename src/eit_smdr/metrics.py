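"""Image-quality metrics for difference EIT reconstructions.

Two standard scores against the known conductivity change:

* correlation coefficient (CC) — Pearson correlation of reconstruction
  and truth over the interior pixels, scale- and offset-free;
* relative image error (RE) — ``||recon - truth|| / ||truth||`` in the
  Euclidean norm, scale-sensitive.

Because the SMDR pipeline outputs images normalized to [0, 1] while the
truth is in S/m, ``normalize_truth_for_metrics`` rescales the truth to
unit maximum before RE is computed for normalized reconstructions; CC
is unaffected by that rescaling.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grid import PixelGrid

__all__ = ["cc", "relative_error", "normalize_truth_for_metrics"]


def _interior(values, grid: PixelGrid | None) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        if grid is None:
            raise ValueError("a PixelGrid is required to mask full images")
        return grid.extract(arr)
    return arr.ravel()


def cc(recon, truth, grid: PixelGrid | None = None) -> float:
    """Pearson correlation coefficient over interior pixels.

    Returns NaN (with a warning) when either image is constant, where
    the correlation is undefined.
    """
    x = _interior(recon, grid)
    y = _interior(truth, grid)
    if x.shape != y.shape:
        raise ValueError("reconstruction and truth have different sizes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined for a constant image", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def relative_error(recon, truth, grid: PixelGrid | None = None) -> float:
    """Relative Euclidean image error ``||recon - truth|| / ||truth||``."""
    x = _interior(recon, grid)
    y = _interior(truth, grid)
    if x.shape != y.shape:
        raise ValueError("reconstruction and truth have different sizes")
    denom = float(np.linalg.norm(y))
    if denom == 0.0:
        raise ValueError("zero-norm truth: relative error undefined")
    return float(np.linalg.norm(x - y) / denom)


def normalize_truth_for_metrics(truth, recon, recon_normalized: bool | None = None):
    """Bring truth and reconstruction onto a common scale for RE.

    When the reconstruction is a [0, 1]-normalized image (detected from
    its range unless stated explicitly), the truth is scaled to unit
    maximum; otherwise both pass through unchanged.  CC is invariant
    under this scaling.
    """
    t = np.asarray(truth, dtype=float)
    r = np.asarray(recon, dtype=float)
    if recon_normalized is None:
        recon_normalized = bool(r.size) and float(r.min()) >= 0.0 and float(r.max()) <= 1.0 + 1e-12
    if recon_normalized and t.max() > 0:
        t = t / t.max()
    return t, r
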