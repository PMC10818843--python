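"""P1 finite-element forward solver and sensitivity (Jacobian) matrix.

The forward problem is the elliptic equation ``div(sigma grad u) = 0``
on the sensor disk.  Electrodes follow the *gap model*: the injected
current enters as a uniform flux density over the drive electrode arcs
and the electrode potential is the arc average of the boundary
potential.  The Neumann nullspace is removed by constraining the
boundary potential to zero mean (a Lagrange multiplier on the assembled
system).

A conductivity field is a per-element array of strictly positive values
in S/m.

Under the gap model the measurement of pattern ``(d, m)`` is the bilinear
form ``a_sigma(u_d, u_m)`` of the two unit-current fields, which makes
reciprocity exact up to solver round-off and gives the standard EIT
sensitivity theorem

    dV_(d,m) / dsigma_e = -integral_e grad(u_d) . grad(u_m) dA

for unit drive currents, evaluated here exactly for P1 elements
(gradients are constant per triangle).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh
from .protocol import Protocol, VoltageFrame

__all__ = [
    "homogeneous_field",
    "solve_forward",
    "compute_sensitivity",
    "electrode_pair_voltages",
]


def homogeneous_field(mesh: Mesh, value: float = 1.0) -> np.ndarray:
    """Uniform per-element conductivity field (S/m)."""
    if value <= 0:
        raise ValueError("conductivity must be strictly positive")
    return np.full(mesh.n_elements, float(value))


def _check_sigma(mesh: Mesh, sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (mesh.n_elements,):
        raise ValueError(
            f"conductivity field has shape {sigma.shape}, expected "
            f"({mesh.n_elements},)"
        )
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError("conductivity values must be finite and strictly positive")
    return sigma


def _p1_gradients(mesh: Mesh) -> np.ndarray:
    """Gradients of the three nodal basis functions per element.

    Returns ``g`` of shape (n_elements, 3, 2) with
    ``grad u|_e = sum_v u[elements[e, v]] * g[e, v]``.
    """
    p = mesh.nodes[mesh.elements]  # (ne, 3, 2)
    a2 = 2.0 * mesh.areas[:, None]
    g = np.empty((mesh.n_elements, 3, 2))
    # grad phi_i = perp(p_k - p_j) / (2A) for (i, j, k) cyclic, CCW triangles
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        d = p[:, k] - p[:, j]
        g[:, i, 0] = -d[:, 1] / a2[:, 0]
        g[:, i, 1] = d[:, 0] / a2[:, 0]
    return g


def _assemble_stiffness(mesh: Mesh, sigma: np.ndarray, grads: np.ndarray) -> sp.csr_matrix:
    ne = mesh.n_elements
    coeff = (sigma * mesh.areas)[:, None, None]
    local = coeff * np.einsum("eid,ejd->eij", grads, grads)
    rows = np.repeat(mesh.elements, 3, axis=1).reshape(ne, 3, 3)
    cols = np.tile(mesh.elements[:, None, :], (1, 3, 1))
    K = sp.coo_matrix(
        (local.ravel(), (rows.ravel(), cols.ravel())),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    return K.tocsr()


def _arc_flux_vector(mesh: Mesh, k: int) -> np.ndarray:
    """Load vector of a unit current spread uniformly over electrode k's arc.

    The same vector (for unit current) is the arc-average functional of
    the boundary potential, so it serves both as drive load and as
    measurement functional.
    """
    idx = mesh.electrode_arcs[k]
    if len(idx) < 2:
        raise ValueError(f"electrode {k} has fewer than 2 boundary nodes")
    seg = np.diff(mesh.nodes[idx], axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    total = lengths.sum()
    b = np.zeros(mesh.n_nodes)
    np.add.at(b, idx[:-1], 0.5 * lengths / total)
    np.add.at(b, idx[1:], 0.5 * lengths / total)
    return b


def _pair_load_matrix(mesh: Mesh) -> np.ndarray:
    """Columns: unit-current load of the adjacent pair (k, k+1), all k."""
    nE = mesh.n_electrodes
    single = np.column_stack([_arc_flux_vector(mesh, k) for k in range(nE)])
    return single - np.roll(single, -1, axis=1)


def _solve_grounded(mesh: Mesh, K: sp.csr_matrix, rhs: np.ndarray) -> np.ndarray:
    """Solve K u = rhs subject to zero-mean potential on boundary nodes."""
    n = mesh.n_nodes
    g = np.zeros(n)
    g[mesh.boundary_nodes] = 1.0
    A = sp.bmat([[K, g[:, None]], [g[None, :], None]], format="csc")
    rhs_aug = np.vstack([rhs, np.zeros((1, rhs.shape[1]))])
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:  # pragma: no cover - qhull/superlu detail
        raise np.linalg.LinAlgError(f"singular forward system: {exc}") from exc
    sol = lu.solve(rhs_aug)
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError("forward solve produced non-finite values")
    return sol[:-1]


def _pair_fields(mesh: Mesh, sigma: np.ndarray, current: float = 1.0):
    """Potential fields for unit current through every adjacent pair.

    Returns ``(u, B)`` where ``u[:, k]`` is the nodal potential for unit
    current through pair ``(k, k+1)`` and ``B`` the unit-current load
    matrix (also the arc-average measurement functionals).
    """
    grads = _p1_gradients(mesh)
    K = _assemble_stiffness(mesh, sigma, grads)
    B = _pair_load_matrix(mesh)
    u = _solve_grounded(mesh, K, B * current) / current
    return u, B, grads


def electrode_pair_voltages(mesh: Mesh, sigma: np.ndarray, protocol: Protocol) -> np.ndarray:
    """Matrix ``V[m, d]`` of pair-(m) voltages under unit-current drive d."""
    sigma = _check_sigma(mesh, sigma)
    if mesh.n_electrodes != protocol.n_electrodes:
        raise ValueError("protocol and mesh disagree on the electrode count")
    u, B, _ = _pair_fields(mesh, sigma)
    return B.T @ u


def solve_forward(mesh: Mesh, sigma: np.ndarray, protocol: Protocol) -> VoltageFrame:
    """Differential boundary voltages for every protocol pattern.

    The returned values are in volts for the protocol's drive current.
    """
    V = electrode_pair_voltages(mesh, sigma, protocol) * protocol.current
    values = V[protocol.measure_index, protocol.drive_index]
    return VoltageFrame(values=values, protocol=protocol)


def compute_sensitivity(mesh: Mesh, sigma0: np.ndarray, protocol: Protocol) -> np.ndarray:
    """Per-element sensitivity table ``S[i, e] = dU_i / dsigma_e`` at sigma0.

    ``sigma0`` is normally the homogeneous reference field.  Entries are
    ``-area_e * grad(u_d) . grad(u_m)`` for the unit-current drive and
    measurement fields of pattern ``i``, which is the exact derivative of
    the P1 gap-model voltage with respect to the element conductivity.
    The result is independent of the protocol's drive current.
    """
    sigma0 = _check_sigma(mesh, sigma0)
    if mesh.n_electrodes != protocol.n_electrodes:
        raise ValueError("protocol and mesh disagree on the electrode count")
    u, _, grads = _pair_fields(mesh, sigma0)
    ue = u[mesh.elements]  # (ne, 3, nE) nodal values per element per pair
    grad_fields = np.einsum("evk,evd->ekd", ue, grads)  # (ne, nE, 2)
    dots = np.einsum("ekd,eld->ekl", grad_fields, grad_fields)  # (ne, nE, nE)
    S = -(mesh.areas[:, None] * dots[:, protocol.drive_index, protocol.measure_index])
    return np.ascontiguousarray(S.T)  # (N, n_elements)
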