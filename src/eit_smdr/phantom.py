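"""Phantom generation, forward simulation, and the measurement noise model.

Phantoms are conductive inclusions (circles, optionally squares) on a
homogeneous disk: by default 2 S/m objects on a 1 S/m background, the
standard two-phase setup for a 16-electrode circular sensor.  A small
library of six deterministic cases covers the usual benchmark layouts
(well-separated objects, near-centre objects, a centre-plus-ring
arrangement, many small objects, a square), and a ``"random"`` spec
draws non-overlapping circular inclusions from configured ranges.

Measurement noise is zero-mean additive white Gaussian noise with one
global standard deviation per frame (signal-independent), fixed by the
requested SNR in dB relative to the frame RMS:

    std = rms(dU) * 10**(-snr_db / 20)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import homogeneous_field, solve_forward
from .grid import PixelGrid
from .mesh import Mesh
from .protocol import Protocol, VoltageFrame

__all__ = [
    "Inclusion",
    "Phantom",
    "NoiseSpec",
    "make_case",
    "phantom_to_field",
    "truth_image",
    "simulate_frame",
    "add_noise",
    "noise_std",
    "negate_frame",
    "CASE_IDS",
]

CASE_IDS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class Inclusion:
    """One inclusion: a circle, or an axis-aligned square of half-side ``radius``."""

    center: tuple
    radius: float
    conductivity: float = 2.0
    shape: str = "circle"

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        dx = points[:, 0] - self.center[0]
        dy = points[:, 1] - self.center[1]
        if self.shape == "circle":
            return dx**2 + dy**2 <= self.radius**2
        if self.shape == "square":
            return np.maximum(np.abs(dx), np.abs(dy)) <= self.radius
        raise ValueError(f"unknown inclusion shape {self.shape!r}")

    @property
    def outer_radius(self) -> float:
        """Radius of the circumscribing circle."""
        return self.radius if self.shape == "circle" else self.radius * np.sqrt(2.0)


@dataclass(frozen=True)
class Phantom:
    """Inclusions on a homogeneous background disk."""

    background_conductivity: float = 1.0
    inclusions: tuple = ()
    domain_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.background_conductivity <= 0:
            raise ValueError("background conductivity must be positive")
        for inc in self.inclusions:
            if inc.conductivity <= 0:
                raise ValueError("inclusion conductivity must be positive")
            c = np.hypot(*inc.center)
            if c + inc.outer_radius > self.domain_radius * (1 + 1e-12):
                raise ValueError(
                    f"inclusion at {inc.center} (outer radius {inc.outer_radius:.3f}) "
                    f"extends outside the domain disk"
                )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a given SNR (dB); ``None`` = noiseless."""

    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db is not None and not self.snr_db > 0:
            raise ValueError("snr_db must be positive (or None for noiseless)")


def _ring(n: int, dist: float, r: float, sigma: float, phase: float = 0.0) -> list:
    return [
        Inclusion(
            center=(dist * np.cos(phase + 2 * np.pi * k / n), dist * np.sin(phase + 2 * np.pi * k / n)),
            radius=r,
            conductivity=sigma,
        )
        for k in range(n)
    ]


def _case_library(sigma_obj: float) -> dict:
    """Deterministic benchmark layouts (domain radius 1)."""
    lib = {
        # three well-separated circles
        1: _ring(3, 0.55, 0.20, sigma_obj, phase=np.pi / 2),
        # two circles near the centre plus one peripheral
        2: [
            Inclusion((-0.24, 0.05), 0.18, sigma_obj),
            Inclusion((0.24, 0.05), 0.18, sigma_obj),
            Inclusion((0.0, -0.65), 0.18, sigma_obj),
        ],
        # a central object surrounded by a ring of objects
        3: [Inclusion((0.0, 0.0), 0.18, sigma_obj)] + _ring(5, 0.60, 0.14, sigma_obj),
        # four circles
        4: _ring(4, 0.52, 0.17, sigma_obj, phase=np.pi / 4),
        # ten small circles
        5: _ring(7, 0.68, 0.11, sigma_obj) + _ring(3, 0.30, 0.11, sigma_obj, phase=np.pi / 3),
        # one square plus one circle
        6: [
            Inclusion((0.40, 0.30), 0.18, sigma_obj, shape="square"),
            Inclusion((-0.40, -0.30), 0.20, sigma_obj),
        ],
    }
    return lib


def make_case(
    case_id,
    seed: int = 0,
    background: float = 1.0,
    object_conductivity: float = 2.0,
    domain_radius: float = 1.0,
    n_inclusions: tuple = (1, 3),
    radius_range: tuple = (0.10, 0.25),
    margin: float = 0.05,
    max_tries: int = 500,
) -> Phantom:
    """Build a phantom from the case library or draw a random one.

    ``case_id`` is 1..6 for the deterministic library, or ``"random"``
    for non-overlapping random circles: the inclusion count is uniform
    over ``n_inclusions`` (inclusive), radii uniform over
    ``radius_range``, centres uniform in the disk with ``margin`` m of
    clearance from the boundary and between inclusions.  Library cases
    ignore the seed; random phantoms are a pure function of the seed.
    """
    if case_id in CASE_IDS:
        incs = _case_library(object_conductivity)[case_id]
        return Phantom(
            background_conductivity=background,
            inclusions=tuple(incs),
            domain_radius=domain_radius,
        )
    if case_id != "random":
        raise ValueError(f"case_id must be 1..6 or 'random', got {case_id!r}")

    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_inclusions[0], n_inclusions[1] + 1))
    placed: list[Inclusion] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} non-overlapping inclusions in {max_tries} tries"
            )
        tries += 1
        r = float(rng.uniform(*radius_range))
        max_c = domain_radius - margin - r
        if max_c <= 0:
            continue
        # uniform over the admissible centre disk
        rho = max_c * np.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * np.pi)
        c = (rho * np.cos(th), rho * np.sin(th))
        ok = all(
            np.hypot(c[0] - p.center[0], c[1] - p.center[1]) >= r + p.radius + margin
            for p in placed
        )
        if ok:
            placed.append(Inclusion(center=c, radius=r, conductivity=object_conductivity))
    return Phantom(
        background_conductivity=background,
        inclusions=tuple(placed),
        domain_radius=domain_radius,
    )


def phantom_to_field(phantom: Phantom, mesh: Mesh) -> np.ndarray:
    """Per-element conductivity: inclusion value where the centroid falls inside."""
    sigma = homogeneous_field(mesh, phantom.background_conductivity)
    cent = mesh.centroids
    for inc in phantom.inclusions:
        sigma[inc.contains(cent)] = inc.conductivity
    return sigma


def truth_image(phantom: Phantom, grid: PixelGrid) -> np.ndarray:
    """Ground-truth conductivity change on the pixel grid (side x side)."""
    delta = np.zeros(grid.M)
    pts = grid.interior_centers
    for inc in phantom.inclusions:
        inside = inc.contains(pts)
        delta[inside] = inc.conductivity - phantom.background_conductivity
    return grid.embed(delta)


def simulate_frame(
    phantom: Phantom,
    mesh: Mesh,
    protocol: Protocol,
    grid: PixelGrid | None = None,
    u0: VoltageFrame | None = None,
):
    """Simulate the differential frame and rasterized truth for a phantom.

    Returns ``(dU, truth)`` where ``dU = U(phantom) - U0`` and ``truth``
    is the pixel image of ``sigma - sigma0`` (``None`` when no grid is
    given).  ``u0`` may carry a precomputed homogeneous reference frame.
    """
    if u0 is None:
        sigma0 = homogeneous_field(mesh, phantom.background_conductivity)
        u0 = solve_forward(mesh, sigma0, protocol)
    u = solve_forward(mesh, phantom_to_field(phantom, mesh), protocol)
    dU = VoltageFrame(values=u.values - u0.values, protocol=protocol)
    truth = truth_image(phantom, grid) if grid is not None else None
    return dU, truth


def noise_std(frame: VoltageFrame | np.ndarray, snr_db: float) -> float:
    """Noise standard deviation for a frame at the given SNR (dB)."""
    values = getattr(frame, "values", frame)
    rms = float(np.sqrt(np.mean(np.square(values))))
    if rms == 0.0:
        raise ValueError("all-zero frame: the noise scale is undefined")
    return rms * 10.0 ** (-snr_db / 20.0)


def add_noise(frame: VoltageFrame, spec: NoiseSpec) -> VoltageFrame:
    """Add signal-independent AWGN at the spec's SNR; pass through if noiseless."""
    if len(frame) == 0:
        raise ValueError("empty frame")
    if spec.snr_db is None:
        return VoltageFrame(values=frame.values.copy(), protocol=frame.protocol)
    std = noise_std(frame, spec.snr_db)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, std, size=len(frame))
    return VoltageFrame(values=frame.values + eps, protocol=frame.protocol)


def negate_frame(frame: VoltageFrame) -> VoltageFrame:
    """Flip the polarity of a frame.

    Use for drop-type data (non-conductive objects in a conductive
    background, as in saline-tank measurements) so that objects are
    always positive conductivity changes in reconstruction space.
    """
    return VoltageFrame(values=-frame.values, protocol=frame.protocol)
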