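"""Labeled simplicial meshes (triangles in 2D, tetrahedra in 3D) and their audits.

The mesh is the single geometric currency of the package: generators produce
it, the flow and scalar solvers assemble on it, and the endpoint extractors
integrate over its labeled boundary groups.  Boundary faces carry exactly one
string label each (port or wall group); orientation is outward everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["SimplicialMesh", "MeshQuality"]


@dataclass
class MeshQuality:
    """Element-quality summary used in run manifests."""

    n_cells: int
    n_nodes: int
    mean_aspect_ratio: float
    min_dihedral_deg: float
    min_volume: float

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_nodes": self.n_nodes,
            "mean_aspect_ratio": float(self.mean_aspect_ratio),
            "min_dihedral_deg": float(self.min_dihedral_deg),
            "min_volume": float(self.min_volume),
        }


@dataclass
class SimplicialMesh:
    """Simplicial mesh with labeled boundary faces.

    Parameters
    ----------
    nodes : (n_nodes, dim) float array, coordinates in cm.
    cells : (n_cells, dim+1) int array, simplex connectivity, positively
        oriented (positive signed volume/area).
    boundary_faces : (n_faces, dim) int array, outward-oriented boundary
        facets (edges in 2D, triangles in 3D).
    face_labels : (n_faces,) array of str, one group name per boundary face.
    """

    nodes: np.ndarray
    cells: np.ndarray
    boundary_faces: np.ndarray
    face_labels: np.ndarray
    dim: int = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self.boundary_faces = np.ascontiguousarray(self.boundary_faces, dtype=np.int64)
        self.face_labels = np.asarray(self.face_labels, dtype=object)
        self.dim = self.nodes.shape[1]
        if self.cells.shape[1] != self.dim + 1:
            raise ValueError("cells must be (n, dim+1) simplices")
        if self.boundary_faces.shape[0] != self.face_labels.shape[0]:
            raise ValueError("every boundary face needs exactly one label")

    # ------------------------------------------------------------------ sizes
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def group_names(self) -> list[str]:
        return sorted(set(self.face_labels.tolist()))

    def group_faces(self, name: str) -> np.ndarray:
        """Indices into ``boundary_faces`` belonging to group ``name``."""
        idx = np.nonzero(self.face_labels == name)[0]
        if idx.size == 0:
            raise KeyError(f"no boundary faces labeled {name!r}")
        return idx

    def group_nodes(self, name: str) -> np.ndarray:
        """Unique node indices touched by group ``name``."""
        return np.unique(self.boundary_faces[self.group_faces(name)])

    # -------------------------------------------------------------- geometry
    def cell_volumes(self) -> np.ndarray:
        """Signed simplex measures (areas in 2D, volumes in 3D)."""
        p = self.nodes[self.cells]
        e = p[:, 1:, :] - p[:, :1, :]
        if self.dim == 2:
            return 0.5 * np.linalg.det(e)
        return np.linalg.det(e) / 6.0

    def face_areas_normals(self, faces: np.ndarray | None = None):
        """Measures and outward unit normals of boundary faces.

        Orientation convention: ``boundary_faces`` are stored so that the
        right-hand rule (3D) / 90-degree-clockwise rotation of the edge
        vector (2D) gives the outward normal.
        """
        bf = self.boundary_faces if faces is None else self.boundary_faces[faces]
        p = self.nodes[bf]
        if self.dim == 2:
            t = p[:, 1, :] - p[:, 0, :]
            areas = np.linalg.norm(t, axis=1)
            normals = np.column_stack([t[:, 1], -t[:, 0]]) / areas[:, None]
        else:
            c = np.cross(p[:, 1, :] - p[:, 0, :], p[:, 2, :] - p[:, 0, :])
            areas = 0.5 * np.linalg.norm(c, axis=1)
            normals = 0.5 * c / areas[:, None]
        return areas, normals

    def group_area(self, name: str) -> float:
        """Wetted area (length in 2D) of a boundary group."""
        areas, _ = self.face_areas_normals(self.group_faces(name))
        return float(areas.sum())

    def node_normals(self, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Area-weighted outward unit normals at the nodes of given faces.

        Returns (node_ids, normals).
        """
        areas, normals = self.face_areas_normals(faces)
        bf = self.boundary_faces[faces]
        nodes = np.unique(bf)
        remap = {n: i for i, n in enumerate(nodes)}
        acc = np.zeros((nodes.size, self.dim))
        w = areas / self.dim
        for loc in range(self.dim):
            np.add.at(acc, [remap[n] for n in bf[:, loc]], w[:, None] * normals)
        acc /= np.linalg.norm(acc, axis=1)[:, None]
        return nodes, acc

    # ---------------------------------------------------------------- audits
    def extract_boundary(self) -> np.ndarray:
        """Recompute boundary facets (those incident on exactly one cell)."""
        faces = _cell_facets(self.cells, self.dim)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def is_watertight(self) -> bool:
        """Boundary facets form a closed surface partition.

        Checks that (a) stored boundary faces coincide with the facets of
        single cell incidence, and (b) in 3D every edge of the boundary
        surface is shared by exactly 2 boundary triangles (in 2D every
        boundary vertex by exactly 2 boundary edges).
        """
        computed = {tuple(f) for f in np.sort(self.extract_boundary(), axis=1)}
        stored = {tuple(f) for f in np.sort(self.boundary_faces, axis=1)}
        if computed != stored:
            return False
        if self.dim == 3:
            edges = np.vstack([self.boundary_faces[:, [0, 1]],
                               self.boundary_faces[:, [1, 2]],
                               self.boundary_faces[:, [2, 0]]])
            _, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
            return bool(np.all(counts == 2))
        _, counts = np.unique(self.boundary_faces.ravel(), return_counts=True)
        return bool(np.all(counts == 2))

    def boundary_euler_characteristic(self) -> int:
        """Euler characteristic V - E + F of the boundary surface (3D)."""
        if self.dim != 3:
            raise ValueError("defined for 3D meshes only")
        f = self.boundary_faces
        v = np.unique(f).size
        edges = np.unique(np.sort(np.vstack(
            [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0)
        return int(v - edges.shape[0] + f.shape[0])

    def dihedral_angles_deg(self) -> np.ndarray:
        """All interior dihedral angles of every cell, in degrees."""
        p = self.nodes[self.cells]
        if self.dim == 2:
            # triangle interior angles
            angles = []
            for i in range(3):
                a = p[:, (i + 1) % 3] - p[:, i]
                b = p[:, (i + 2) % 3] - p[:, i]
                cosang = np.einsum("ij,ij->i", a, b) / (
                    np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
                angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            return np.concatenate(angles)
        # tetrahedra: dihedral along each of the 6 edges = angle between the
        # two faces sharing the edge, computed from face normals.
        angles = []
        verts = range(4)
        for e in combinations(verts, 2):
            oth = [v for v in verts if v not in e]
            a, b = p[:, e[0]], p[:, e[1]]
            c, d = p[:, oth[0]], p[:, oth[1]]
            n1 = np.cross(b - a, c - a)
            n2 = np.cross(b - a, d - a)
            cosang = np.einsum("ij,ij->i", n1, n2) / (
                np.linalg.norm(n1, axis=1) * np.linalg.norm(n2, axis=1))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            angles.append(180.0 - ang)
        return np.concatenate(angles)

    def quality(self) -> MeshQuality:
        vols = self.cell_volumes()
        p = self.nodes[self.cells]
        edges = []
        for i, j in combinations(range(self.dim + 1), 2):
            edges.append(np.linalg.norm(p[:, i] - p[:, j], axis=1))
        lmax = np.max(edges, axis=0)
        if self.dim == 2:
            # aspect ratio: longest edge / (2 * inradius), 1 for equilateral
            s = 0.5 * np.sum(edges, axis=0)
            inr = vols / s
            ar = lmax / (2.0 * np.sqrt(3.0) * inr)
        else:
            # inradius r = 3V / (total face area)
            area = np.zeros(self.n_cells)
            for f in combinations(range(4), 3):
                c = np.cross(p[:, f[1]] - p[:, f[0]], p[:, f[2]] - p[:, f[0]])
                area += 0.5 * np.linalg.norm(c, axis=1)
            inr = 3.0 * vols / area
            ar = lmax / (2.0 * np.sqrt(6.0) * inr)
        return MeshQuality(
            n_cells=self.n_cells,
            n_nodes=self.n_nodes,
            mean_aspect_ratio=float(np.mean(ar)),
            min_dihedral_deg=float(np.min(self.dihedral_angles_deg())),
            min_volume=float(np.min(vols)),
        )

    def validate(self) -> None:
        """Raise ValueError on any failed structural audit."""
        vols = self.cell_volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{int(np.sum(vols <= 0))} non-positive cell volumes")
        if not self.is_watertight():
            raise ValueError("boundary surface is not closed/watertight")


def _cell_facets(cells: np.ndarray, dim: int) -> np.ndarray:
    """All facets of all cells, oriented outward w.r.t. their cell.

    For a positively oriented simplex (v0..vd), the facet opposite vertex i
    with the conventional ordering has outward orientation after an
    appropriate parity swap.
    """
    n = cells.shape[0]
    if dim == 2:
        # edges opposite each vertex, CCW triangle -> outward = rotate edge
        return np.vstack([cells[:, [1, 2]], cells[:, [2, 0]], cells[:, [0, 1]]])
    # tetrahedron with positive orientation: faces with outward normals
    return np.vstack([
        cells[:, [1, 2, 3]],
        cells[:, [0, 3, 2]],
        cells[:, [0, 1, 3]],
        cells[:, [0, 2, 1]],
    ])


def orient_cells(nodes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Return cells reordered to positive signed volume."""
    cells = np.array(cells, dtype=np.int64, copy=True)
    p = nodes[cells]
    e = p[:, 1:, :] - p[:, :1, :]
    det = np.linalg.det(e) if nodes.shape[1] == 3 else np.linalg.det(e)
    flip = det < 0
    cells[flip, 0], cells[flip, 1] = cells[flip, 1].copy(), cells[flip, 0].copy()
    return cells


def build_mesh(nodes: np.ndarray, cells: np.ndarray,
               label_fn) -> SimplicialMesh:
    """Assemble a SimplicialMesh from raw connectivity.

    Drops unused nodes, fixes orientation, extracts the boundary and labels
    each boundary face by calling ``label_fn(centroids) -> array of str``
    (or ``label_fn(centroids, normals)`` if it accepts outward normals).
    """
    nodes = np.asarray(nodes, float)
    cells = np.asarray(cells, np.int64)
    used = np.unique(cells)
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = nodes[used]
    cells = orient_cells(nodes, remap[cells])
    dim = nodes.shape[1]
    faces = _cell_facets(cells, dim)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bfaces = faces[counts[inv] == 1]
    centroids = nodes[bfaces].mean(axis=1)
    probe = SimplicialMesh(nodes, cells, bfaces,
                           np.full(bfaces.shape[0], "x", dtype=object))
    _, normals = probe.face_areas_normals()
    try:
        labels = np.asarray(label_fn(centroids, normals), dtype=object)
    except TypeError:
        labels = np.asarray(label_fn(centroids), dtype=object)
    return SimplicialMesh(nodes, cells, bfaces, labels)
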