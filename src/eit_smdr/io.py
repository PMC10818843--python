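"""File I/O: CSV images and frames, HDF5 containers for model bundles.

Images are plain 64x64 CSV matrices.  Frames are one-column CSVs or
HDF5 datasets with protocol metadata.  A *model bundle* is one HDF5
file holding the mesh, protocol, pixel-basis sensitivity matrix, and
reference frame, so a reconstruction run never has to re-solve the
forward problem.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .grid import PixelGrid, SensitivityMatrix
from .mesh import Mesh
from .model import ForwardModel
from .protocol import Protocol, VoltageFrame

__all__ = [
    "save_image_csv",
    "load_image_csv",
    "save_frame_csv",
    "load_frame_csv",
    "save_frame_h5",
    "load_frame_h5",
    "save_mesh_csv",
    "save_model_h5",
    "load_model_h5",
]


def save_image_csv(path, image: np.ndarray) -> None:
    np.savetxt(path, np.asarray(image, dtype=float), delimiter=",")


def load_image_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def save_frame_csv(path, frame: VoltageFrame) -> None:
    np.savetxt(path, frame.values, delimiter=",")


def load_frame_csv(path, protocol: Protocol) -> VoltageFrame:
    return VoltageFrame(values=np.loadtxt(path, delimiter=","), protocol=protocol)


def _write_protocol(g: h5py.Group, protocol: Protocol) -> None:
    g.create_dataset("patterns", data=protocol.patterns)
    g.attrs["n_electrodes"] = protocol.n_electrodes
    g.attrs["current"] = protocol.current


def _read_protocol(g: h5py.Group) -> Protocol:
    return Protocol(
        n_electrodes=int(g.attrs["n_electrodes"]),
        patterns=np.asarray(g["patterns"]),
        current=float(g.attrs["current"]),
    )


def save_frame_h5(path, frame: VoltageFrame) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=frame.values)
        _write_protocol(f.create_group("protocol"), frame.protocol)


def load_frame_h5(path) -> VoltageFrame:
    with h5py.File(path, "r") as f:
        protocol = _read_protocol(f["protocol"])
        return VoltageFrame(values=np.asarray(f["values"]), protocol=protocol)


def save_mesh_csv(prefix, mesh: Mesh) -> None:
    """Write ``<prefix>_nodes.csv`` and ``<prefix>_elements.csv``."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_name(prefix.name + "_nodes.csv"), mesh.nodes, delimiter=",")
    np.savetxt(
        prefix.with_name(prefix.name + "_elements.csv"),
        mesh.elements,
        delimiter=",",
        fmt="%d",
    )


def _write_mesh(g: h5py.Group, mesh: Mesh) -> None:
    g.create_dataset("nodes", data=mesh.nodes)
    g.create_dataset("elements", data=mesh.elements)
    arcs = mesh.electrode_arcs
    g.create_dataset("arc_nodes", data=np.concatenate(arcs))
    g.create_dataset("arc_offsets", data=np.cumsum([0] + [len(a) for a in arcs]))
    g.attrs["radius"] = mesh.radius


def _read_mesh(g: h5py.Group) -> Mesh:
    arc_nodes = np.asarray(g["arc_nodes"])
    offsets = np.asarray(g["arc_offsets"])
    arcs = tuple(arc_nodes[offsets[i] : offsets[i + 1]] for i in range(len(offsets) - 1))
    return Mesh(
        nodes=np.asarray(g["nodes"]),
        elements=np.asarray(g["elements"]),
        electrode_arcs=arcs,
        radius=float(g.attrs["radius"]),
    )


def save_model_h5(path, model: ForwardModel) -> None:
    with h5py.File(path, "w") as f:
        _write_mesh(f.create_group("mesh"), model.mesh)
        _write_protocol(f.create_group("protocol"), model.protocol)
        f.create_dataset("sensitivity", data=model.sensitivity.values)
        f.create_dataset("u0", data=model.u0.values)
        f.attrs["grid_side"] = model.grid.side
        f.attrs["radius"] = model.grid.radius
        f.attrs["background"] = model.background


def load_model_h5(path) -> ForwardModel:
    with h5py.File(path, "r") as f:
        mesh = _read_mesh(f["mesh"])
        protocol = _read_protocol(f["protocol"])
        grid = PixelGrid(side=int(f.attrs["grid_side"]), radius=float(f.attrs["radius"]))
        S = SensitivityMatrix(values=np.asarray(f["sensitivity"]), grid=grid)
        u0 = VoltageFrame(values=np.asarray(f["u0"]), protocol=protocol)
        return ForwardModel(
            mesh=mesh,
            protocol=protocol,
            grid=grid,
            sensitivity=S,
            u0=u0,
            background=float(f.attrs["background"]),
        )
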