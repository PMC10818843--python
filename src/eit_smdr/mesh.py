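"""Triangulated disk meshes for a circular multi-electrode sensor.

The sensing domain is a disk of radius ``r`` carrying ``n_electrodes``
electrodes of equal arc width, evenly spread around the boundary.
Electrode 1 is centred at angle 0 and numbering proceeds
counterclockwise.  Boundary nodes are laid out so that every electrode
spans a whole number of boundary edges with its endpoints exactly at the
electrode edges; this lets the gap electrode model impose its current
flux on the electrode arcs without quadrature error in the geometry.

Interior nodes sit on concentric rings whose spacing matches the
boundary density, and the triangulation is the Delaunay triangulation of
the combined point cloud.  All triangles are stored with counterclockwise
orientation (positive signed area).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["Mesh", "build_mesh"]


@dataclass(frozen=True, eq=False)
class Mesh:
    """A P1 triangle mesh of the sensor disk.

    Parameters
    ----------
    nodes : (n_nodes, 2) float array
        Node coordinates in metres.
    elements : (n_elements, 3) int array
        Node indices of each triangle, counterclockwise.
    electrode_arcs : tuple of int arrays
        For each electrode, the boundary node indices along its arc,
        ordered by angle.  Consecutive entries define the boundary edges
        the electrode covers.
    radius : float
        Domain radius in metres.
    """

    nodes: np.ndarray
    elements: np.ndarray
    electrode_arcs: tuple
    radius: float

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_arcs)

    @cached_property
    def areas(self) -> np.ndarray:
        """Signed triangle areas (all positive by construction)."""
        p = self.nodes[self.elements]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    @cached_property
    def boundary_nodes(self) -> np.ndarray:
        """Indices of nodes lying on the outer circle."""
        r = np.hypot(self.nodes[:, 0], self.nodes[:, 1])
        return np.flatnonzero(r >= self.radius * (1.0 - 1e-9))

    def electrode_arc_length(self, k: int) -> float:
        """Polyline length of electrode ``k``'s arc (approximates its width)."""
        idx = self.electrode_arcs[k]
        seg = np.diff(self.nodes[idx], axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _boundary_angles(n_electrodes: int, half_angle: float, h_angle: float) -> np.ndarray:
    """Boundary node angles: electrode edges exactly at centre +/- half_angle."""
    angles = []
    pitch = 2.0 * np.pi / n_electrodes
    gap = pitch - 2.0 * half_angle
    n_on = max(1, int(np.ceil(2.0 * half_angle / h_angle)))  # edges per electrode
    n_gap = max(1, int(round(gap / h_angle)))  # edges per inter-electrode gap
    for k in range(n_electrodes):
        c = k * pitch
        angles.extend(np.linspace(c - half_angle, c + half_angle, n_on + 1))
        # open interval between this electrode and the next
        angles.extend(c + half_angle + gap * np.arange(1, n_gap) / n_gap)
    return np.mod(np.asarray(angles), 2.0 * np.pi)


def build_mesh(
    radius: float = 1.0,
    n_electrodes: int = 16,
    electrode_width: float = 0.05,
    target_element_count: int = 2000,
) -> Mesh:
    """Build a triangulated disk with boundary-conforming electrode arcs.

    Parameters
    ----------
    radius : float
        Disk radius in metres (default 1 m).
    n_electrodes : int
        Number of boundary electrodes (default 16).
    electrode_width : float
        Arc width of each electrode in metres (default 5 cm).
    target_element_count : int
        Requested number of triangles; the realised count is close but
        not exact.  Must be at least 64.

    Raises
    ------
    ValueError
        If the electrodes would overlap or the parameters are infeasible.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_electrodes < 1:
        raise ValueError("need at least one electrode")
    if electrode_width <= 0:
        raise ValueError("electrode_width must be positive")
    circumference = 2.0 * np.pi * radius
    if electrode_width * n_electrodes >= circumference:
        raise ValueError(
            f"electrodes overlap: {n_electrodes} electrodes of width "
            f"{electrode_width} m exceed the circumference {circumference:.3f} m"
        )
    if target_element_count < 64:
        raise ValueError("target_element_count must be >= 64")

    half_angle = electrode_width / (2.0 * radius)
    # A disk triangulated from n_rings concentric rings with isotropic
    # spacing h = radius/n_rings yields roughly 2*pi*n_rings^2 triangles.
    n_rings = max(4, int(round(np.sqrt(target_element_count / (2.0 * np.pi)))))
    h = radius / n_rings

    theta_b = _boundary_angles(n_electrodes, half_angle, h / radius)
    order = np.argsort(theta_b)
    theta_b = theta_b[order]
    boundary = radius * np.column_stack([np.cos(theta_b), np.sin(theta_b)])

    pts = [np.zeros((1, 2))]
    for i in range(1, n_rings):
        ri = radius * i / n_rings
        ni = max(6, int(round(2.0 * np.pi * ri / h)))
        th = 2.0 * np.pi * np.arange(ni) / ni + (i % 2) * np.pi / ni
        pts.append(ri * np.column_stack([np.cos(th), np.sin(th)]))
    interior = np.vstack(pts)
    nodes = np.vstack([interior, boundary])
    boundary_offset = interior.shape[0]

    tri = Delaunay(nodes)
    elements = tri.simplices.copy()
    # enforce counterclockwise orientation
    p = nodes[elements]
    sgn = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = sgn < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    # drop degenerate slivers (collinear points can appear on the boundary)
    p = nodes[elements]
    area2 = np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0])
    )
    elements = elements[area2 > 1e-14 * radius**2]

    arcs = []
    pitch = 2.0 * np.pi / n_electrodes
    for k in range(n_electrodes):
        centre = k * pitch
        rel = np.mod(theta_b - centre + np.pi, 2.0 * np.pi) - np.pi
        on = np.flatnonzero(np.abs(rel) <= half_angle + 1e-9)
        on = on[np.argsort(rel[on])]
        arcs.append(boundary_offset + on)

    flat = np.concatenate(arcs)
    if len(np.unique(flat)) != len(flat):
        raise ValueError("electrode arcs are not disjoint; widen the gaps")

    return Mesh(
        nodes=nodes,
        elements=elements,
        electrode_arcs=tuple(arcs),
        radius=float(radius),
    )
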