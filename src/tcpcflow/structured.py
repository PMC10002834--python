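"""Structured meshes: circular pipes (3D), channels and boxes.

The pipe mesh is the workhorse verification fixture: a disk cross-section
built from concentric rings (optionally graded into boundary layers near the
wall), triangulated, extruded along the axis into prisms and split into
tetrahedra with a globally consistent diagonal rule.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay

from .mesh import SimplicialMesh, build_mesh
from .distmesh import MeshingError

__all__ = ["disk_points", "pipe_mesh", "rectangle_mesh"]


def disk_points(radius: float, h: float, n_boundary_layers: int = 0,
                layer_ratio: float = 0.5) -> np.ndarray:
    """Points covering a disk: uniform core rings + geometrically thinned
    wall layers (the n-th innermost layer has thickness ratio**n * h)."""
    if radius <= 0 or h <= 0:
        raise ValueError("radius and h must be positive")
    gaps = [h * layer_ratio ** n for n in range(1, n_boundary_layers + 1)]
    r_inner = radius - sum(gaps)
    if r_inner <= 0.25 * h:
        raise MeshingError("boundary layers consume the whole pipe radius")
    n_core = max(1, int(round(r_inner / h)))
    radii = list(np.linspace(0.0, r_inner, n_core + 1))
    r = r_inner
    for g in gaps:            # thinnest gap lands adjacent to the wall
        r += g
        radii.append(r)
    radii[-1] = radius
    pts = [np.zeros((1, 2))]
    for rr in radii[1:]:
        n = max(6, int(np.ceil(2 * np.pi * rr / h)))
        th = 2 * np.pi * np.arange(n) / n
        pts.append(np.column_stack([rr * np.cos(th), rr * np.sin(th)]))
    return np.vstack(pts)


_PRISM_TEMPLATES = {
    # Dompierre et al. templates, prism locally rotated so vertex 0 is the
    # global minimum; choice between the two templates by the smaller of
    # the competing diagonal endpoints on the quad face (1,2,5,4).
    True: [(0, 1, 2, 5), (0, 1, 5, 4), (0, 4, 5, 3)],   # diagonal 1-5
    False: [(0, 1, 2, 4), (0, 4, 2, 5), (0, 4, 5, 3)],  # diagonal 2-4
}
_ROTATIONS = [
    (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
]


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (n, 6) into tetrahedra with conforming quad diagonals.

    Each quad face diagonal emanates from the face's smallest global vertex
    index, which is a consistent rule between neighbouring prisms.
    """
    tets = []
    for pr in prisms:
        rot = min(_ROTATIONS, key=lambda r: pr[r[0]])
        v = pr[list(rot)]
        # quad face (v1, v2, v5, v4): diagonal from min corner
        use_15 = min(v[1], v[5]) < min(v[2], v[4])
        for t in _PRISM_TEMPLATES[use_15]:
            tets.append(v[list(t)])
    return np.asarray(tets, dtype=np.int64)


def pipe_mesh(diameter: float, length: float, target_h: float,
              n_boundary_layers: int = 0, layer_ratio: float = 0.5,
              axis: int = 2) -> SimplicialMesh:
    """Labeled tetrahedral mesh of a circular pipe.

    The pipe spans [0, length] along ``axis`` with face groups
    {inlet, outlet, wall}; inlet at coordinate 0.
    """
    if diameter <= 0 or length <= 0 or target_h <= 0:
        raise ValueError("diameter, length and target_h must be positive")
    try:
        disk = disk_points(diameter / 2.0, target_h, n_boundary_layers,
                           layer_ratio)
        tri = Delaunay(disk)
    except MeshingError:
        raise
    except Exception as exc:  # pragma: no cover - qhull failure path
        raise MeshingError(f"disk triangulation failed: {exc}") from exc
    tris = tri.simplices
    # drop degenerate rim triangles qhull may create on the convex hull
    p = disk[tris]
    e1, e2 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    area = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    tris = tris[area > 1e-12 * (diameter / 2) ** 2]

    nz = max(1, int(round(length / target_h)))
    zs = np.linspace(0.0, length, nz + 1)
    nd = disk.shape[0]
    nodes = np.empty((nd * (nz + 1), 3))
    for k, z in enumerate(zs):
        sl = slice(k * nd, (k + 1) * nd)
        nodes[sl, :2] = disk
        nodes[sl, 2] = z
    prisms = []
    for k in range(nz):
        lo, hi = k * nd, (k + 1) * nd
        prisms.append(np.hstack([tris + lo, tris + hi]))
    tets = _split_prisms(np.vstack(prisms))

    if axis != 2:
        order = {0: [2, 1, 0], 1: [0, 2, 1]}[axis]
        nodes = nodes[:, order]

    radius = diameter / 2.0
    ax = axis

    def label(cent: np.ndarray) -> np.ndarray:
        lab = np.empty(cent.shape[0], dtype=object)
        lab[:] = "wall"
        tol = 1e-6 * length
        lab[np.abs(cent[:, ax]) < tol] = "inlet"
        lab[np.abs(cent[:, ax] - length) < tol] = "outlet"
        return lab

    mesh = build_mesh(nodes, tets, label)
    mesh.validate()
    return mesh


def rectangle_mesh(lx: float, ly: float, nx: int, ny: int,
                   labels: dict | None = None) -> SimplicialMesh:
    """Crossed-triangle mesh of [0,lx] x [0,ly] for 2D verification runs.

    ``labels`` optionally renames the sides {left, right, bottom, top}.
    """
    labels = {"left": "inlet", "right": "outlet",
              "bottom": "wall", "top": "wall"} | (labels or {})
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]

    tol = 1e-9 * max(lx, ly)

    def label(cent):
        lab = np.empty(cent.shape[0], dtype=object)
        lab[:] = labels["bottom"]
        lab[cent[:, 1] > ly - tol] = labels["top"]
        lab[cent[:, 0] < tol] = labels["left"]
        lab[cent[:, 0] > lx - tol] = labels["right"]
        return lab

    mesh = build_mesh(nodes, np.asarray(tris), label)
    mesh.validate()
    return mesh
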