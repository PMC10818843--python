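"""Baseline regularized inversion for difference EIT.

The linearized inverse problem ``dU ~= S dsigma`` is solved by Tikhonov
regularization,

    dsigma = argmin ||S dsigma - dU||^2 + lambda ||L dsigma||^2
           = (S^T S + lambda L^T L)^{-1} S^T dU,

with the identity as the default regularization matrix.  For L = I the
solution is evaluated from the SVD of S (equivalently the dual form
``S^T (S S^T + lambda I)^{-1} dU``), which is cheap because the number
of measurements is small; explicit inversion is never formed.

When ``lam="auto"`` the regularization parameter is picked from a
log-spaced grid by minimizing the generalized cross-validation (GCV)
score, an unsupervised criterion that needs no noise estimate:

    GCV(lambda) = N ||(I - A(lambda)) dU||^2 / tr(I - A(lambda))^2,

with ``A`` the influence matrix of the Tikhonov smoother.  The grid is
specified in units of ``||S||_2^2`` (the squared largest singular
value), so the search window tracks the scale of the Jacobian; a fixed
``lam`` is always absolute.

``TikhonovReconstructor`` is a scikit-learn style transformer: ``fit``
takes the sensitivity matrix, ``transform`` maps measurement frames to
interior-pixel images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .grid import PixelGrid

__all__ = [
    "RegularizerConfig",
    "TikhonovReconstructor",
    "tikhonov",
    "tikhonov_dual",
    "select_lambda",
    "location_compensate",
]


@dataclass(frozen=True)
class RegularizerConfig:
    """Tikhonov configuration: fixed lambda or an auto-selection grid.

    ``grid_min``/``grid_max`` bound the GCV search grid in units of the
    squared spectral norm of the sensitivity matrix (resolved to
    absolute values once the matrix is known); ``lam`` given as a
    number is absolute.
    """

    lam: float | str = "auto"
    grid_min: float = 1e-3
    grid_max: float = 1.0
    n_grid: int = 20
    L: np.ndarray | None = None  # identity when None

    def __post_init__(self) -> None:
        if isinstance(self.lam, str):
            if self.lam != "auto":
                raise ValueError("lam must be a nonnegative number or 'auto'")
        elif self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not (0 < self.grid_min < self.grid_max):
            raise ValueError("lambda grid bounds must be positive and increasing")
        if self.n_grid < 2:
            raise ValueError("lambda grid needs at least 2 points")

    @property
    def lambda_grid(self) -> np.ndarray:
        """Relative grid (multiply by ``||S||_2^2`` for absolute values)."""
        return np.logspace(np.log10(self.grid_min), np.log10(self.grid_max), self.n_grid)


def _as_matrix(S) -> np.ndarray:
    """Accept a plain array or a SensitivityMatrix-like object."""
    return np.asarray(getattr(S, "values", S), dtype=float)


def _frame_values(dU) -> np.ndarray:
    return np.asarray(getattr(dU, "values", dU), dtype=float)


class TikhonovReconstructor(TransformerMixin, BaseEstimator):
    """Tikhonov inversion of measurement frames against a fixed Jacobian.

    Parameters
    ----------
    lam : float or "auto"
        Regularization parameter; "auto" selects it per frame by GCV.
    grid_min, grid_max, n_grid : float, float, int
        Log-spaced lambda grid searched when ``lam="auto"``.
    L : array or None
        Regularization matrix; ``None`` means the identity.

    Attributes
    ----------
    S_ : (N, M) array
        Sensitivity matrix seen in ``fit``.
    U_, s_, Vt_ : arrays
        Thin SVD of ``S_`` (computed when ``L`` is None).
    lambda_ : float
        Regularization parameter used for the most recent frame.
    """

    def __init__(
        self,
        lam: float | str = "auto",
        grid_min: float = 1e-3,
        grid_max: float = 1.0,
        n_grid: int = 20,
        L: np.ndarray | None = None,
    ):
        self.lam = lam
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.n_grid = n_grid
        self.L = L

    def _config(self) -> RegularizerConfig:
        return RegularizerConfig(
            lam=self.lam,
            grid_min=self.grid_min,
            grid_max=self.grid_max,
            n_grid=self.n_grid,
            L=self.L,
        )

    def fit(self, X, y=None):
        """Store the sensitivity matrix and precompute its thin SVD."""
        self._config()  # validate parameters
        X = check_array(_as_matrix(X), ensure_all_finite=True)
        self.S_ = X
        self.n_measurements_, self.n_pixels_ = X.shape
        if self.L is None:
            self.U_, self.s_, self.Vt_ = sla.svd(X, full_matrices=False)
            norm2 = float(self.s_[0] ** 2)
        else:
            norm2 = float(np.linalg.norm(X, 2) ** 2)
        # absolute GCV grid: relative bounds scaled by ||S||_2^2
        self.lambda_grid_ = self._config().lambda_grid * (norm2 if norm2 > 0 else 1.0)
        return self

    # -- lambda selection ------------------------------------------------

    def gcv_scores(self, dU) -> np.ndarray:
        """GCV score for every grid lambda (requires L = identity)."""
        check_is_fitted(self, "S_")
        if self.L is not None:
            raise ValueError("GCV selection is implemented for L = identity only")
        d = _frame_values(dU)
        beta = self.U_.T @ d
        out_of_range = float(d @ d - beta @ beta)
        s2 = self.s_**2
        N = self.n_measurements_
        scores = np.empty(self.n_grid)
        for i, lam in enumerate(self.lambda_grid_):
            shrink = lam / (s2 + lam)  # 1 - f_i
            resid2 = float(np.sum((shrink * beta) ** 2)) + out_of_range
            denom = N - float(np.sum(s2 / (s2 + lam)))
            scores[i] = N * resid2 / denom**2
        return scores

    def select_lambda(self, dU) -> float:
        """The (absolute) grid lambda minimizing the GCV score; deterministic."""
        scores = self.gcv_scores(dU)
        return float(self.lambda_grid_[int(np.argmin(scores))])

    def _resolve_lambda(self, dU) -> float:
        return self.select_lambda(dU) if self.lam == "auto" else float(self.lam)

    # -- solving ---------------------------------------------------------

    def _solve(self, d: np.ndarray, lam: float) -> np.ndarray:
        if self.L is None:
            s = self.s_
            if lam == 0.0:
                tol = s.max() * max(self.S_.shape) * np.finfo(float).eps
                if s.min() <= tol or self.n_measurements_ < self.n_pixels_:
                    raise np.linalg.LinAlgError(
                        "lambda = 0 with a rank-deficient system: the normal "
                        "equations are singular"
                    )
            filt = s / (s**2 + lam)
            return self.Vt_.T @ (filt * (self.U_.T @ d))
        L = np.asarray(self.L, dtype=float)
        A = self.S_.T @ self.S_ + lam * (L.T @ L)
        try:
            c = sla.cho_factor(A)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular normal equations: {exc}") from exc
        return sla.cho_solve(c, self.S_.T @ d)

    def transform(self, X) -> np.ndarray:
        """Reconstruct one frame (N,) or a stack of frames (n, N)."""
        check_is_fitted(self, "S_")
        d = _frame_values(X)
        single = d.ndim == 1
        d = np.atleast_2d(d)
        if d.shape[1] != self.n_measurements_:
            raise ValueError(
                f"frame length {d.shape[1]} does not match the "
                f"{self.n_measurements_} measurements of the fitted system"
            )
        out = np.empty((d.shape[0], self.n_pixels_))
        lambdas = np.empty(d.shape[0])
        for i, row in enumerate(d):
            lambdas[i] = self._resolve_lambda(row)
            out[i] = self._solve(row, lambdas[i])
        self.lambdas_ = lambdas
        self.lambda_ = float(lambdas[-1])
        return out[0] if single else out


# -- functional wrappers -------------------------------------------------


def tikhonov(S, dU, cfg: RegularizerConfig | None = None, grid: PixelGrid | None = None):
    """One-shot Tikhonov reconstruction.

    Returns the interior-pixel vector, or the (side, side) image when a
    grid is given.
    """
    cfg = cfg or RegularizerConfig()
    est = TikhonovReconstructor(
        lam=cfg.lam, grid_min=cfg.grid_min, grid_max=cfg.grid_max, n_grid=cfg.n_grid, L=cfg.L
    ).fit(S)
    x = est.transform(_frame_values(dU))
    return grid.embed(x) if grid is not None else x


def tikhonov_dual(S, dU, lam: float) -> np.ndarray:
    """Tikhonov solution via the dual (underdetermined) form, L = identity.

    ``x = S^T (S S^T + lam I)^{-1} dU`` — algebraically identical to the
    primal normal equations but sized by the measurement count, which
    makes repeated solves with modified (decomposed) sensitivity
    matrices cheap.  Requires ``lam > 0``.
    """
    if not lam > 0:
        raise ValueError("the dual form requires lam > 0")
    S = _as_matrix(S)
    d = _frame_values(dU)
    G = S @ S.T
    G[np.diag_indices_from(G)] += lam
    c = sla.cho_factor(G)
    return S.T @ sla.cho_solve(c, d)


def select_lambda(S, dU, cfg: RegularizerConfig | None = None) -> float:
    """GCV-optimal lambda on the config's grid."""
    cfg = cfg or RegularizerConfig()
    est = TikhonovReconstructor(
        lam="auto", grid_min=cfg.grid_min, grid_max=cfg.grid_max, n_grid=cfg.n_grid
    ).fit(S)
    return est.select_lambda(dU)


def location_compensate(image, grid: PixelGrid):
    """Scale each interior pixel by ``(r - d_i)``.

    ``d_i`` is the distance of the pixel centre from the domain centre;
    the boundary (low-information) region is attenuated to zero while
    the low-sensitivity centre is emphasised.  Accepts an interior
    vector or a full image and returns the same shape.
    """
    weights = grid.radius - grid.distances
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 1:
        if arr.shape != (grid.M,):
            raise ValueError(f"expected {grid.M} interior pixels, got {arr.shape}")
        return arr * weights
    return grid.embed(grid.extract(arr) * weights)
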