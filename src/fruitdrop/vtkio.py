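"""Minimal ASCII VTK export/import for the fruit meshes and fields.

Writes legacy ASCII .vtk and XML .vtu unstructured grids holding the
tetrahedra (cell type 10) and skin triangles (cell type 5) with region
labels, node sets and any per-cell fields; reads back the same two
formats.  Only the ASCII subset this package writes is supported.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET


import numpy as np

from .synthetic_fruit import FruitMesh

__all__ = ["write_vtk", "write_vtu", "read_vtu", "mesh_to_cells", "mesh_from_arrays"]


def mesh_to_cells(mesh: FruitMesh):
    """(points, connectivity list, cell types, cell data) for export:
    tets first, then skin triangles."""
    cells = [mesh.tets[i] for i in range(mesh.n_tets)] + [
        mesh.skin_tris[i] for i in range(mesh.skin_tris.shape[0])
    ]
    types = np.concatenate(
        [np.full(mesh.n_tets, 10, dtype=int), np.full(mesh.skin_tris.shape[0], 5, dtype=int)]
    )
    region = np.concatenate(
        [mesh.region.astype(int), np.full(mesh.skin_tris.shape[0], 2, dtype=int)]
    )
    return mesh.points, cells, types, {"region": region}


def write_vtk(path, mesh: FruitMesh, cell_data: dict | None = None) -> None:
    """Legacy ASCII .vtk unstructured grid."""
    points, cells, types, base = mesh_to_cells(mesh)
    data = dict(base)
    if cell_data:
        data.update(cell_data)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfruitdrop mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        total = sum(len(c) + 1 for c in cells)
        fh.write(f"CELLS {len(cells)} {total}\n")
        for c in cells:
            fh.write(str(len(c)) + " " + " ".join(str(int(i)) for i in c) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        for t in types:
            fh.write(f"{t}\n")
        if data:
            fh.write(f"CELL_DATA {len(cells)}\n")
            for name, values in data.items():
                values = np.asarray(values)
                kind = "int" if np.issubdtype(values.dtype, np.integer) else "double"
                fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                for v in values:
                    fh.write(f"{v:.9g}\n" if kind == "double" else f"{int(v)}\n")


def write_vtu(path, mesh: FruitMesh, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """XML ASCII .vtu unstructured grid."""
    points, cells, types, base = mesh_to_cells(mesh)
    data = dict(base)
    if cell_data:
        data.update(cell_data)
    offsets = np.cumsum([len(c) for c in cells])
    conn = np.concatenate([np.asarray(c) for c in cells])

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(len(points)),
                          NumberOfCells=str(len(cells)))
    pts_el = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts_el, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = "\n".join(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in points)
    cells_el = ET.SubElement(piece, "Cells")
    for name, arr, typ in (
        ("connectivity", conn, "Int64"),
        ("offsets", offsets, "Int64"),
        ("types", types, "UInt8"),
    ):
        d = ET.SubElement(cells_el, "DataArray", type=typ, Name=name, format="ascii")
        d.text = " ".join(str(int(v)) for v in arr)
    cd = ET.SubElement(piece, "CellData")
    for name, values in data.items():
        values = np.asarray(values)
        typ = "Int32" if np.issubdtype(values.dtype, np.integer) else "Float64"
        d = ET.SubElement(cd, "DataArray", type=typ, Name=name, format="ascii")
        d.text = " ".join(
            f"{v:.9g}" if typ == "Float64" else str(int(v)) for v in values
        )
    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, values in point_data.items():
            values = np.asarray(values)
            d = ET.SubElement(pd, "DataArray", type="Float64", Name=name, format="ascii")
            if values.ndim == 2:
                d.set("NumberOfComponents", str(values.shape[1]))
                d.text = "\n".join(" ".join(f"{x:.9g}" for x in row) for row in values)
            else:
                d.text = " ".join(f"{v:.9g}" for v in values)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_vtu(path):
    """Read a .vtu written by this module.

    Returns (points, tets, tris, cell_data) where cell_data arrays are
    aligned with tets followed by tris.
    """
    tree = ET.parse(path)
    piece = tree.getroot().find(".//Piece")
    arrays = {}
    for da in piece.iter("DataArray"):
        name = da.get("Name") or "points"
        text = (da.text or "").split()
        typ = da.get("type", "Float64")
        vals = np.array(text, dtype=float if typ.startswith("Float") else np.int64)
        ncomp = int(da.get("NumberOfComponents", "1"))
        if ncomp > 1:
            vals = vals.reshape(-1, ncomp)
        arrays[name] = vals
    points = arrays.pop("points")
    conn = arrays.pop("connectivity").astype(np.int64)
    offsets = arrays.pop("offsets").astype(np.int64)
    types = arrays.pop("types").astype(int)
    cells = np.split(conn, offsets[:-1])
    tets = np.array([c for c, t in zip(cells, types) if t == 10], dtype=np.int64)
    tris = np.array([c for c, t in zip(cells, types) if t == 5], dtype=np.int64)
    tets = tets.reshape(-1, 4) if tets.size else np.empty((0, 4), dtype=np.int64)
    tris = tris.reshape(-1, 3) if tris.size else np.empty((0, 3), dtype=np.int64)
    return points, tets, tris, arrays


def mesh_from_arrays(points, tets, tris, region, element_size=2.0,
                     skin_thickness=0.3) -> FruitMesh:
    """Rebuild a FruitMesh from imported arrays."""
    return FruitMesh(
        points=points,
        tets=tets,
        region=np.asarray(region, dtype=np.int8),
        skin_tris=tris,
        skin_thickness=skin_thickness,
        element_size=element_size,
    )
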