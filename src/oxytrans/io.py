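"""Lightweight standard-format I/O: VTU point fields, Gmsh MSH meshes,
CSV diagnostics and JSON summaries.

The writers emit plain ASCII XML VTU (readable by ParaView/VTK) and Gmsh
MSH 2.2; the matching readers parse only what this package writes plus the
common subset produced by other tools (triangles, line elements with
physical tags, point-data arrays).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import GeometryError, Mesh, PerforatedDomain

__all__ = [
    "write_vtu", "read_vtu_point_data", "write_msh", "read_msh",
    "write_diagnostics_csv", "write_summary_json",
]


def write_vtu(path, mesh: Mesh, point_data: dict | None = None) -> None:
    """Write the mesh and nodal fields as ASCII XML VTU.

    Scalar fields are (N,) arrays; vector fields (N, 2) are padded to 3D as
    VTK expects.
    """
    n = mesh.n_vertices
    m = len(mesh.triangles)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        '  <UnstructuredGrid>',
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        '      <Points>',
        '        <DataArray type="Float64" NumberOfComponents="3" '
        'format="ascii">',
    ]
    pts = np.column_stack([mesh.vertices, np.zeros(n)])
    lines.append("          " + " ".join(f"{v:.17g}" for v in pts.ravel()))
    lines += [
        '        </DataArray>',
        '      </Points>',
        '      <Cells>',
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + " ".join(map(str, mesh.triangles.ravel())),
        '        </DataArray>',
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + " ".join(str(3 * (i + 1)) for i in range(m)),
        '        </DataArray>',
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + " ".join(["5"] * m),
        '        </DataArray>',
        '      </Cells>',
    ]
    if point_data:
        lines.append('      <PointData>')
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                comp = 1
                flat = arr
            else:
                comp = 3
                flat = np.column_stack(
                    [arr, np.zeros((arr.shape[0], 3 - arr.shape[1]))]).ravel()
            lines += [
                f'        <DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{comp}" format="ascii">',
                "          " + " ".join(f"{v:.17g}" for v in np.ravel(flat)),
                '        </DataArray>',
            ]
        lines.append('      </PointData>')
    lines += ['    </Piece>', '  </UnstructuredGrid>', '</VTKFile>', '']
    Path(path).write_text("\n".join(lines))


def read_vtu_point_data(path) -> dict:
    """Read points and point-data arrays from an ASCII VTU file."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    out = {}
    pts = piece.find("./Points/DataArray")
    coords = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    out["points"] = coords[:, :2]
    pd = piece.find("./PointData")
    if pd is not None:
        for da in pd.findall("DataArray"):
            comp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            if comp > 1:
                arr = arr.reshape(-1, comp)[:, :2]
            out[da.get("Name")] = arr
    return out


def write_msh(path, mesh: Mesh) -> None:
    """Write Gmsh MSH 2.2 ASCII with tagged boundary lines and triangles.

    Physical tags: boundary lines carry the package's boundary tags
    (1 edge, 2 inlet, 3 outlet); triangles carry physical tag 10.
    """
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
           str(mesh.n_vertices)]
    for i, (x, y) in enumerate(mesh.vertices, start=1):
        out.append(f"{i} {x:.17g} {y:.17g} 0")
    out += ["$EndNodes", "$Elements",
            str(len(mesh.boundary_edges) + len(mesh.triangles))]
    eid = 1
    for (v0, v1), tag in zip(mesh.boundary_edges, mesh.boundary_tags):
        out.append(f"{eid} 1 2 {tag} {tag} {v0 + 1} {v1 + 1}")
        eid += 1
    for v0, v1, v2 in mesh.triangles:
        out.append(f"{eid} 2 2 10 10 {v0 + 1} {v1 + 1} {v2 + 1}")
        eid += 1
    out += ["$EndElements", ""]
    Path(path).write_text("\n".join(out))


def read_msh(path, domain: PerforatedDomain | None = None) -> Mesh:
    """Read a Gmsh MSH 2.2 ASCII mesh with tagged line elements."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes = {}
    tris = []
    edges = []
    tags = []
    for line in it:
        if line.strip() == "$Nodes":
            count = int(next(it))
            for _ in range(count):
                parts = next(it).split()
                nodes[int(parts[0])] = (float(parts[1]), float(parts[2]))
        elif line.strip() == "$Elements":
            count = int(next(it))
            for _ in range(count):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                phys = int(parts[3]) if ntags else 0
                conn = [int(v) for v in parts[3 + ntags:]]
                if etype == 1:
                    edges.append(conn)
                    tags.append(phys)
                elif etype == 2:
                    tris.append(conn)
    if not nodes or not tris:
        raise GeometryError(f"{path}: no nodes/triangles found")
    ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(ids)}
    vertices = np.array([nodes[nid] for nid in ids])
    triangles = np.array([[remap[v] for v in t] for t in tris],
                         dtype=np.int64)
    bedges = np.array([[remap[v] for v in e] for e in edges],
                      dtype=np.int64).reshape(-1, 2)
    # enforce positive orientation
    p = vertices[triangles]
    areas2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
              - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = areas2 < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    return Mesh(vertices=vertices, triangles=triangles,
                boundary_edges=bedges,
                boundary_tags=np.array(tags, dtype=np.int64),
                domain=domain)


def write_diagnostics_csv(path, result) -> None:
    """RFC-4180 CSV with one row per stored time step."""
    result.records_frame().to_csv(path, index=False, lineterminator="\r\n")


def write_summary_json(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=_json_default)
                          + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
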