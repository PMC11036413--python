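"""Minimal ASCII VTU (VTK XML unstructured grid) writer/reader.

Covers exactly what this package emits: linear line/triangle/tetra cells,
point-data and cell-data float/int arrays.  Files are plain text and
readable by ParaView/VTK.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .errors import ValidationError
from .geometry import Mesh

__all__ = ["write_vtu", "read_vtu"]

_VTK_TYPE = {"line": 3, "triangle": 5, "tetra": 10}
_TYPE_VTK = {v: k for k, v in _VTK_TYPE.items()}


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if a.dtype.kind in "iu":
        return " ".join(str(int(x)) for x in a.ravel())
    return " ".join(f"{float(x):.9g}" for x in a.ravel())


def write_vtu(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh and named per-node / per-element arrays."""
    n, m = mesh.n_nodes, mesh.n_elements
    k = mesh.elements.shape[1]
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.nodes), "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(mesh.elements), "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(np.arange(1, m + 1) * k), "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt(np.full(m, _VTK_TYPE[mesh.element_type], np.uint8)),
        "</DataArray>", "</Cells>",
    ]

    def emit(data: dict | None, holder: str, count: int):
        lines.append(f"<{holder}>")
        for name, arr in (data or {}).items():
            a = np.asarray(arr)
            if a.shape[0] != count:
                raise ValidationError(f"array {name!r} has wrong length")
            ncomp = 1 if a.ndim == 1 else a.shape[1]
            typ = "Int64" if a.dtype.kind in "iu" else "Float64"
            lines.append(f'<DataArray type="{typ}" Name="{name}" '
                         f'NumberOfComponents="{ncomp}" format="ascii">')
            lines.append(_fmt(a))
            lines.append("</DataArray>")
        lines.append(f"</{holder}>")

    emit(point_data, "PointData", n)
    emit(cell_data, "CellData", m)
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def read_vtu(path) -> tuple[Mesh, dict, dict]:
    """Read a VTU written by :func:`write_vtu`.

    Returns (mesh, point_data, cell_data); mesh labels/coordinates present
    in point_data are not re-attached automatically.
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def parse(da):
        typ = da.get("type")
        ncomp = int(da.get("NumberOfComponents", "1"))
        dtype = np.int64 if typ.startswith(("Int", "UInt")) else float
        a = np.array(da.text.split(), dtype=float).astype(dtype)
        return a.reshape(-1, ncomp) if ncomp > 1 else a

    pts = parse(piece.find("./Points/DataArray"))
    cells = piece.find("./Cells")
    arrays = {da.get("Name"): parse(da) for da in cells.findall("DataArray")}
    conn, offs, types = arrays["connectivity"], arrays["offsets"], arrays["types"]
    t0 = int(types[0])
    if not np.all(types == t0):
        raise ValidationError("mixed cell types are not supported")
    k = int(offs[0])
    elements = conn.reshape(-1, k)
    mesh = Mesh(pts, elements, _TYPE_VTK[t0])

    def collect(holder):
        h = piece.find(holder)
        if h is None:
            return {}
        return {da.get("Name"): parse(da) for da in h.findall("DataArray")}

    return mesh, collect("PointData"), collect("CellData")
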