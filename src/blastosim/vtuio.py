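"""Minimal ASCII VTU (XML unstructured grid) writer and reader.

Only what the simulator needs: hexahedral cells, float point/cell data
arrays, ASCII encoding.  Coordinates and fields round-trip to full double
precision (written with 17 significant digits).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

VTK_HEXAHEDRON = 12
VTK_QUAD = 9


def _fmt(arr):
    return " ".join(f"{v:.17g}" for v in np.asarray(arr, dtype=float).ravel())


def write_vtu(path, points, cells, point_data=None, cell_data=None,
              cell_type=VTK_HEXAHEDRON):
    """Write an unstructured grid of one homogeneous cell type.

    ``point_data`` values may be (n,) scalars or (n, 3) vectors; ``cell_data``
    values are per-cell scalars.
    """
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    n_pts, n_cells = points.shape[0], cells.shape[0]
    nodes_per_cell = cells.shape[1]

    lines = []
    lines.append('<?xml version="1.0"?>')
    lines.append(
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">'
    )
    lines.append("  <UnstructuredGrid>")
    lines.append(
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">'
    )
    lines.append("      <Points>")
    lines.append(
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">'
    )
    lines.append("          " + _fmt(points))
    lines.append("        </DataArray>")
    lines.append("      </Points>")
    lines.append("      <Cells>")
    lines.append('        <DataArray type="Int64" Name="connectivity" format="ascii">')
    lines.append("          " + " ".join(str(v) for v in cells.ravel()))
    lines.append("        </DataArray>")
    lines.append('        <DataArray type="Int64" Name="offsets" format="ascii">')
    offs = nodes_per_cell * np.arange(1, n_cells + 1)
    lines.append("          " + " ".join(str(v) for v in offs))
    lines.append("        </DataArray>")
    lines.append('        <DataArray type="UInt8" Name="types" format="ascii">')
    lines.append("          " + " ".join(str(cell_type) for _ in range(n_cells)))
    lines.append("        </DataArray>")
    lines.append("      </Cells>")

    for tag, data in (("PointData", point_data), ("CellData", cell_data)):
        lines.append(f"      <{tag}>")
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            lines.append(
                f'        <DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            lines.append("          " + _fmt(arr))
            lines.append("        </DataArray>")
        lines.append(f"      </{tag}>")

    lines.append("    </Piece>")
    lines.append("  </UnstructuredGrid>")
    lines.append("</VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtu(path):
    """Read a file written by :func:`write_vtu`.

    Returns ``(points, cells, point_data, cell_data)``.
    """
    tree = ET.parse(path)
    piece = tree.getroot().find("UnstructuredGrid").find("Piece")
    n_pts = int(piece.get("NumberOfPoints"))
    n_cells = int(piece.get("NumberOfCells"))

    def _parse(da, dtype=float):
        return np.fromstring(da.text.strip(), sep=" ", dtype=dtype)

    pts_da = piece.find("Points").find("DataArray")
    points = _parse(pts_da).reshape(n_pts, 3)
    cells_el = piece.find("Cells")
    conn = offsets = None
    for da in cells_el.findall("DataArray"):
        if da.get("Name") == "connectivity":
            conn = _parse(da).astype(np.int64)
        elif da.get("Name") == "offsets":
            offsets = _parse(da).astype(np.int64)
    nodes_per_cell = offsets[0]
    cells = conn.reshape(n_cells, nodes_per_cell)

    def _fields(tag, n):
        out = {}
        sec = piece.find(tag)
        if sec is None:
            return out
        for da in sec.findall("DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = _parse(da)
            out[da.get("Name")] = arr if ncomp == 1 else arr.reshape(n, ncomp)
        return out

    return points, cells, _fields("PointData", n_pts), _fields("CellData", n_cells)
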