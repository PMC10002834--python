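"""Mesh and field interchange: ASCII VTU and Gmsh .msh (v4.1).

Writers emit plain-text files readable by ParaView (VTU) and Gmsh (.msh);
readers parse the same subset back, preserving boundary face-group labels
(as physical surface names in .msh, as an integer cell array plus legend in
VTU).  Field exports write one VTU per snapshot plus a .pvd collection
index.
"""
from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import SimplicialMesh

__all__ = ["write_vtu", "read_vtu", "write_msh", "read_msh",
           "write_field_series"]

_VTK_TYPE = {(2, 3): 5, (3, 4): 10, (2, 2): 3, (3, 3): 5}


def _pad3(pts: np.ndarray) -> np.ndarray:
    if pts.shape[1] == 3:
        return pts
    out = np.zeros((pts.shape[0], 3))
    out[:, : pts.shape[1]] = pts
    return out


def _fmt(arr) -> str:
    a = np.asarray(arr)
    if np.issubdtype(a.dtype, np.integer):
        return " ".join(map(str, a.ravel()))
    return " ".join(f"{x:.17g}" for x in a.ravel())


def write_vtu(path, mesh: SimplicialMesh, point_data: dict | None = None,
              include_boundary_labels: bool = True) -> None:
    """Write the volume mesh (and optional nodal fields) as ASCII VTU.

    Boundary labels are stored by appending the boundary faces as extra
    cells carrying a ``face_group`` integer cell array; the id-to-name
    legend travels in a ``face_group_legend`` FieldData string encoded as
    JSON.  Volume cells carry face_group = -1.
    """
    path = Path(path)
    dim = mesh.dim
    cells = [mesh.cells]
    types = [np.full(mesh.n_cells, _VTK_TYPE[(dim, dim + 1)], np.uint8)]
    groups = mesh.group_names()
    gid = {g: i for i, g in enumerate(groups)}
    labels = [np.full(mesh.n_cells, -1, np.int64)]
    if include_boundary_labels:
        cells.append(mesh.boundary_faces)
        types.append(np.full(mesh.boundary_faces.shape[0],
                             _VTK_TYPE[(dim, dim)], np.uint8))
        labels.append(np.array([gid[l] for l in mesh.face_labels], np.int64))
    conn = np.concatenate([c.ravel() for c in cells])
    sizes = np.concatenate([np.full(c.shape[0], c.shape[1]) for c in cells])
    offsets = np.cumsum(sizes)
    types = np.concatenate(types)
    labels = np.concatenate(labels)
    n_cells_total = types.size

    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             ' <UnstructuredGrid>',
             f'  <Piece NumberOfPoints="{mesh.n_nodes}" '
             f'NumberOfCells="{n_cells_total}">',
             '   <Points>',
             '    <DataArray type="Float64" NumberOfComponents="3" '
             f'format="ascii">{_fmt(_pad3(mesh.nodes))}</DataArray>',
             '   </Points>',
             '   <Cells>',
             f'    <DataArray type="Int64" Name="connectivity" '
             f'format="ascii">{_fmt(conn)}</DataArray>',
             f'    <DataArray type="Int64" Name="offsets" '
             f'format="ascii">{_fmt(offsets)}</DataArray>',
             f'    <DataArray type="UInt8" Name="types" '
             f'format="ascii">{_fmt(types)}</DataArray>',
             '   </Cells>']
    if point_data:
        lines.append('   <PointData>')
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if arr.ndim == 2 and arr.shape[1] == dim and dim == 2:
                arr = _pad3(arr)
                ncomp = 3
            lines.append(f'    <DataArray type="Float64" Name="{name}" '
                         f'NumberOfComponents="{ncomp}" format="ascii">'
                         f'{_fmt(arr)}</DataArray>')
        lines.append('   </PointData>')
    lines.append('   <CellData>')
    lines.append(f'    <DataArray type="Int64" Name="face_group" '
                 f'format="ascii">{_fmt(labels)}</DataArray>')
    lines.append('   </CellData>')
    lines.append('  </Piece>')
    legend = json.dumps(gid)
    lines.append(f'  <FieldData><DataArray type="Int8" '
                 f'Name="face_group_legend_json" format="ascii" '
                 f'legend=\'{legend}\'></DataArray></FieldData>')
    lines.append(' </UnstructuredGrid>')
    lines.append('</VTKFile>')
    path.write_text("\n".join(lines))


def read_vtu(path) -> tuple[SimplicialMesh, dict]:
    """Read a VTU written by :func:`write_vtu`; returns (mesh, point_data)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    pts = np.fromstring(piece.find("Points/DataArray").text, sep=" ")
    pts = pts.reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.find("Cells")}
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=np.int64)
    offsets = np.fromstring(arrays["offsets"].text, sep=" ", dtype=np.int64)
    types = np.fromstring(arrays["types"].text, sep=" ", dtype=np.int64)
    cd = piece.find("CellData")
    labels = np.fromstring(cd.find("DataArray").text, sep=" ", dtype=np.int64)
    fd = root.find(".//FieldData/DataArray")
    legend = json.loads(fd.get("legend")) if fd is not None else {}
    inv = {v: k for k, v in legend.items()}

    starts = np.concatenate([[0], offsets[:-1]])
    vol_mask = np.isin(types, (10,)) if 10 in types else (types == 5)
    dim = 3 if 10 in types else 2
    nvert = dim + 1
    cells = np.stack([conn[s:s + nvert]
                      for s, m in zip(starts, vol_mask) if m])
    bmask = ~vol_mask
    bfaces = (np.stack([conn[s:s + dim]
                        for s, m in zip(starts, bmask) if m])
              if np.any(bmask) else np.empty((0, dim), np.int64))
    blabels = np.array([inv.get(l, str(l)) for l in labels[bmask]],
                       dtype=object)
    nodes = pts[:, :dim]
    mesh = SimplicialMesh(nodes, cells, bfaces, blabels)
    point_data = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el:
            arr = np.fromstring(da.text, sep=" ")
            ncomp = int(da.get("NumberOfComponents", "1"))
            if ncomp > 1:
                arr = arr.reshape(-1, ncomp)[:, :dim] if ncomp == 3 else \
                    arr.reshape(-1, ncomp)
            point_data[da.get("Name")] = arr
    return mesh, point_data


def write_field_series(outdir, basename: str, mesh: SimplicialMesh,
                       times, fields_per_time) -> Path:
    """Write one VTU per snapshot plus a ParaView .pvd collection index.

    ``fields_per_time(k)`` returns the point-data dict for snapshot k.
    Returns the path of the .pvd file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, t in enumerate(times):
        fn = f"{basename}_{k:04d}.vtu"
        write_vtu(outdir / fn, mesh, point_data=fields_per_time(k))
        entries.append(f'  <DataSet timestep="{t:.6g}" file="{fn}"/>')
    pvd = outdir / f"{basename}.pvd"
    pvd.write_text('<?xml version="1.0"?>\n'
                   '<VTKFile type="Collection" version="0.1">\n'
                   ' <Collection>\n' + "\n".join(entries) +
                   '\n </Collection>\n</VTKFile>')
    return pvd


def export_flow_field(outdir, field, basename: str = "flow") -> Path:
    """VTU time series of a FlowField: "velocity" (cm/s), "pressure"
    (dyn/cm^2), plus a .pvd index."""
    return write_field_series(
        outdir, basename, field.mesh, field.times,
        lambda k: {"velocity": field.velocity[k],
                   "pressure": field.pressure[k]})


def export_dye_fields(outdir, scalar, washout=None,
                      basename: str = "dye") -> Path:
    """VTU time series of the dye field, with the washout map ("
    washout_time_s", "censored") attached to every snapshot when given."""
    extra = {}
    if washout is not None:
        extra = {"washout_time_s": washout.T,
                 "censored": washout.censored.astype(float)}
    return write_field_series(
        outdir, basename, scalar.mesh, scalar.times,
        lambda k: {"dye": scalar.phi[k], **extra})


# ------------------------------------------------------------------- gmsh

def write_msh(path, mesh: SimplicialMesh) -> None:
    """Write the labeled mesh in Gmsh .msh v4.1 ASCII format.

    Face groups become physical surface (3D) / curve (2D) names; the volume
    carries the physical name "fluid".
    """
    path = Path(path)
    dim = mesh.dim
    groups = mesh.group_names()
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    # physical names: tags 1..n for face groups, n+1 for the volume
    lines.append("$PhysicalNames")
    lines.append(str(len(groups) + 1))
    for i, g in enumerate(groups, start=1):
        lines.append(f'{dim - 1} {i} "{g}"')
    lines.append(f'{dim} {len(groups) + 1} "fluid"')
    lines.append("$EndPhysicalNames")

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    lo3, hi3 = np.zeros(3), np.zeros(3)
    lo3[:dim], hi3[:dim] = lo, hi
    bbox = f"{lo3[0]} {lo3[1]} {lo3[2]} {hi3[0]} {hi3[1]} {hi3[2]}"
    lines.append("$Entities")
    if dim == 3:
        lines.append(f"0 0 {len(groups)} 1")
        for i in range(1, len(groups) + 1):
            lines.append(f"{i} {bbox} 1 {i} 0")
        lines.append(f"1 {bbox} 1 {len(groups) + 1} 0")
    else:
        lines.append(f"0 {len(groups)} 1 0")
        for i in range(1, len(groups) + 1):
            lines.append(f"{i} {bbox} 1 {i} 0")
        lines.append(f"1 {bbox} 1 {len(groups) + 1} 0")
    lines.append("$EndEntities")

    lines.append("$Nodes")
    n = mesh.n_nodes
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"{dim} 1 0 {n}")
    lines.extend(str(i) for i in range(1, n + 1))
    p3 = _pad3(mesh.nodes)
    lines.extend(f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in p3)
    lines.append("$EndNodes")

    etype_face = 2 if dim == 3 else 1      # triangle / line
    etype_cell = 4 if dim == 3 else 2      # tet / triangle
    n_elem = mesh.n_cells + mesh.boundary_faces.shape[0]
    lines.append("$Elements")
    lines.append(f"{len(groups) + 1} {n_elem} 1 {n_elem}")
    tag = 1
    for i, g in enumerate(groups, start=1):
        faces = mesh.boundary_faces[mesh.group_faces(g)]
        lines.append(f"{dim - 1} {i} {etype_face} {faces.shape[0]}")
        for f in faces:
            lines.append(f"{tag} " + " ".join(str(v + 1) for v in f))
            tag += 1
    lines.append(f"{dim} 1 {etype_cell} {mesh.n_cells}")
    for c in mesh.cells:
        lines.append(f"{tag} " + " ".join(str(v + 1) for v in c))
        tag += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> SimplicialMesh:
    """Read a labeled simplicial mesh from Gmsh .msh v4.1 ASCII."""
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def until(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"section {tag} not found")

    until("$MeshFormat")
    ver = next(it).split()
    if not ver[0].startswith("4"):
        raise ValueError(f"unsupported msh version {ver[0]}")
    until("$PhysicalNames")
    n_phys = int(next(it))
    phys = {}
    for _ in range(n_phys):
        d, tag, name = next(it).split(maxsplit=2)
        phys[(int(d), int(tag))] = name.strip('"')
    until("$Entities")
    np_, nc, ns, nv = map(int, next(it).split())
    ent_phys = {}
    for _ in range(np_):
        next(it)
    for dim_ent, count in ((1, nc), (2, ns), (3, nv)):
        for _ in range(count):
            parts = next(it).split()
            tag = int(parts[0])
            nphys = int(parts[7])
            if nphys:
                ent_phys[(dim_ent, tag)] = int(parts[8])
    until("$Nodes")
    nb, nn, _, _ = map(int, next(it).split())
    coords = np.empty((nn + 1, 3))
    max_dim = 0
    for _ in range(nb):
        edim, _, _, cnt = map(int, next(it).split())
        max_dim = max(max_dim, edim)
        tags = [int(next(it)) for _ in range(cnt)]
        for t in tags:
            coords[t] = list(map(float, next(it).split()))
    until("$Elements")
    nb, _, _, _ = map(int, next(it).split())
    cells, faces, face_labels = [], [], []
    dim = None
    for _ in range(nb):
        edim, etag, etype, cnt = map(int, next(it).split())
        for _ in range(cnt):
            parts = list(map(int, next(it).split()))
            verts = [v - 1 for v in parts[1:]]
            if etype in (4,):
                cells.append(verts)
                dim = 3
            elif etype == 2 and max_dim == 3:
                faces.append(verts)
                face_labels.append(phys.get((edim, ent_phys.get((edim, etag), -1)), str(etag)))
            elif etype == 2 and max_dim == 2:
                cells.append(verts)
                dim = 2
            elif etype == 1:
                faces.append(verts)
                face_labels.append(phys.get((edim, ent_phys.get((edim, etag), -1)), str(etag)))
    cells = np.asarray(cells, np.int64)
    used = np.unique(cells)
    dim = dim or 2
    nodes = coords[1:, :dim]
    return SimplicialMesh(nodes, cells,
                          np.asarray(faces, np.int64),
                          np.asarray(face_labels, dtype=object))
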