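"""Bundled forward model: mesh, protocol, pixel grid, and Jacobian.

``build_model`` assembles everything a reconstruction needs for the
standard desk-scale setup — a 1 m disk with sixteen 5 cm electrodes,
adjacent protocol, homogeneous 1 S/m reference, and the 64x64 pixel
grid — and precomputes the reference frame and the pixel-basis
sensitivity matrix.  ``simulate`` then produces (optionally noisy)
difference frames for phantoms against the cached reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import compute_sensitivity, homogeneous_field, solve_forward
from .grid import PixelGrid, SensitivityMatrix, rasterize_sensitivity
from .mesh import Mesh, build_mesh
from .phantom import NoiseSpec, Phantom, add_noise, simulate_frame
from .protocol import Protocol, VoltageFrame, build_protocol

__all__ = ["ForwardModel", "build_model"]


@dataclass(eq=False)
class ForwardModel:
    """Everything needed to simulate and reconstruct on one geometry."""

    mesh: Mesh
    protocol: Protocol
    grid: PixelGrid
    sensitivity: SensitivityMatrix  # pixel basis, reference state
    u0: VoltageFrame  # reference frame at the background conductivity
    background: float = 1.0

    def simulate(self, phantom: Phantom, snr_db: float | None = None, seed: int = 0):
        """Simulate ``(dU, truth)`` for a phantom, adding AWGN when asked.

        The phantom's background must match the model's reference state
        (the cached reference frame and Jacobian are computed there).
        """
        if phantom.background_conductivity != self.background:
            raise ValueError(
                "phantom background differs from the model's reference conductivity"
            )
        dU, truth = simulate_frame(
            phantom, self.mesh, self.protocol, grid=self.grid, u0=self.u0
        )
        if snr_db is not None:
            dU = add_noise(dU, NoiseSpec(snr_db=snr_db, seed=seed))
        return dU, truth


def build_model(
    radius: float = 1.0,
    n_electrodes: int = 16,
    electrode_width: float = 0.05,
    n_elements: int = 2000,
    grid_side: int = 64,
    background: float = 1.0,
    current: float = 1.0,
    n_sub: int = 4,
) -> ForwardModel:
    """Build the mesh, protocol, grid, reference frame, and Jacobian."""
    mesh = build_mesh(
        radius=radius,
        n_electrodes=n_electrodes,
        electrode_width=electrode_width,
        target_element_count=n_elements,
    )
    protocol = build_protocol(n_electrodes=n_electrodes, current=current)
    grid = PixelGrid(side=grid_side, radius=radius)
    sigma0 = homogeneous_field(mesh, background)
    u0 = solve_forward(mesh, sigma0, protocol)
    S_el = compute_sensitivity(mesh, sigma0, protocol)
    S = rasterize_sensitivity(S_el, mesh, grid, n_sub=n_sub)
    return ForwardModel(
        mesh=mesh,
        protocol=protocol,
        grid=grid,
        sensitivity=S,
        u0=u0,
        background=background,
    )
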