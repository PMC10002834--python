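"""Parametric geometry of the idealized cavopulmonary test section.

The physical device sits in a planar four-port cross junction: the two venae
cavae (SVC/IVC) enter along the +y/-y axes, the two pulmonary arteries
(RPA/LPA) leave along +x/-x, and a spherical housing bulge (diameter
``housing_max_diameter``) encloses the junction.  The optional static pump
insert is an idealized bicone (two cones joined base-to-base) whose axis lies
along the caval (y) axis so that each cone apex faces an inlet, supported by
cylindrical struts in the equatorial plane.  Blade height is represented as
an annular enlargement of the bicone equator radius.

Geometries are expressed as signed distance functions (SDFs, negative
inside) consumed by the mesh generator, plus a boundary labeling rule that
assigns each boundary face to its port or wall group.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["JunctionGeometryParams", "JunctionGeometry"]


@dataclass
class JunctionGeometryParams:
    """Parameters of the idealized junction, lengths in cm.

    Defaults mirror the bench test section: 1.91 cm internal tube diameter,
    3.4 cm maximum housing diameter, and the larger of the two tested blade
    heights (1.62 mm).
    """

    tube_diameter: float = 1.91
    housing_max_diameter: float = 3.4
    arm_length: float = 5.0
    insert_kind: str = "none"            # {"none", "bicone"}
    bicone_height: float = 2.4
    bicone_equator_diameter: float = 2.4
    blade_height: float = 0.162
    n_struts: int = 4
    strut_diameter: float = 0.3
    fillet_edges: bool = False

    def __post_init__(self) -> None:
        if self.tube_diameter <= 0 or self.housing_max_diameter <= 0:
            raise ValueError("diameters must be positive")
        if self.tube_diameter >= self.housing_max_diameter:
            raise ValueError("tube_diameter must be smaller than housing_max_diameter")
        if self.arm_length <= 4.0:
            raise ValueError("arm_length must exceed 4 cm so the pressure "
                             "cut planes at 4 cm fit inside the arms")
        if self.insert_kind not in ("none", "bicone"):
            raise ValueError(f"unknown insert_kind {self.insert_kind!r}")
        if self.insert_kind == "bicone":
            r_h = self.housing_max_diameter / 2.0
            if self.equator_radius_effective >= r_h:
                raise ValueError(
                    "insert does not fit: effective equator radius "
                    f"{self.equator_radius_effective:.3f} cm >= housing radius "
                    f"{r_h:.3f} cm (no primary-flow gap)")
            if self.bicone_height / 2.0 >= r_h:
                raise ValueError("bicone apex pokes through the housing")

    @property
    def tube_radius(self) -> float:
        return self.tube_diameter / 2.0

    @property
    def housing_radius(self) -> float:
        return self.housing_max_diameter / 2.0

    @property
    def equator_radius_effective(self) -> float:
        """Bicone equator radius including the annular blade ridge."""
        r = self.bicone_equator_diameter / 2.0
        if self.insert_kind == "bicone":
            r += self.blade_height
        return r

    @property
    def primary_gap(self) -> float:
        """Radial clearance between insert equator and housing wall."""
        return self.housing_radius - self.equator_radius_effective


# --------------------------------------------------------------- primitives

def _sd_capped_cylinder(p: np.ndarray, axis: int, half_length: float,
                        radius: float, dim: int) -> np.ndarray:
    """SDF of a finite cylinder centred at the origin along ``axis``."""
    ax = p[:, axis]
    if dim == 2:
        oth = p[:, 1 - axis]
        dr = np.abs(oth) - radius
    else:
        others = [i for i in range(3) if i != axis]
        dr = np.hypot(p[:, others[0]], p[:, others[1]]) - radius
    dz = np.abs(ax) - half_length
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dz, 0.0))
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    return outside + inside


def _sd_sphere(p: np.ndarray, radius: float) -> np.ndarray:
    return np.linalg.norm(p, axis=1) - radius


def _sd_segment_2d(q: np.ndarray, a, b) -> np.ndarray:
    """Unsigned distance from 2D points q to segment ab."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    t = np.clip(((q - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(q - proj, axis=1)


def _sd_bicone(p: np.ndarray, axis: int, half_height: float,
               equator_radius: float, dim: int) -> np.ndarray:
    """SDF of a solid bicone (two cones base-to-base) along ``axis``.

    The solid of revolution of the triangle with vertices (r=0, z=-h),
    (r=r_eq, z=0), (r=0, z=+h) in the (radial, axial) half-plane.
    """
    z = np.abs(p[:, axis])
    if dim == 2:
        r = np.abs(p[:, 1 - axis])
    else:
        others = [i for i in range(3) if i != axis]
        r = np.hypot(p[:, others[0]], p[:, others[1]])
    q = np.column_stack([r, z])
    # lateral edge from equator (r_eq, 0) to apex (0, h)
    d_lat = _sd_segment_2d(q, (equator_radius, 0.0), (0.0, half_height))
    inside = (z < half_height) & (r < equator_radius * (1.0 - z / half_height))
    return np.where(inside, -d_lat, d_lat)


def _sd_strut(p: np.ndarray, angle: float, radius: float,
              r_outer: float) -> np.ndarray:
    """SDF of one cylindrical strut in the equatorial (x-z) plane (3D only).

    The strut axis runs radially outward at ``angle`` (measured from +x
    toward +z) from the origin to beyond the housing wall.
    """
    c, s = np.cos(angle), np.sin(angle)
    # coordinates along (u) and transverse to (v, w) the strut axis
    u = p[:, 0] * c + p[:, 2] * s
    v = -p[:, 0] * s + p[:, 2] * c
    w = p[:, 1]
    du = np.abs(u - 0.5 * r_outer) - 0.5 * r_outer
    dr = np.hypot(v, w) - radius
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(du, 0.0))
    inside = np.minimum(np.maximum(dr, du), 0.0)
    return outside + inside


# ---------------------------------------------------------------- assembly

class JunctionGeometry:
    """SDF and boundary labeling for one junction configuration.

    Coordinate convention: junction center at the origin; IVC along -y,
    SVC along +y, RPA along +x, LPA along -x.  In 2D mode the same cross
    layout lives in the x-y plane and the insert is the axis-plane section
    of the bicone (a diamond with apexes toward the inlets); struts are
    omitted in 2D because they lie out of plane.
    """

    PORTS = {
        "outlet_RPA": (0, +1.0),
        "outlet_LPA": (0, -1.0),
        "inlet_SVC": (1, +1.0),
        "inlet_IVC": (1, -1.0),
    }

    def __init__(self, params: JunctionGeometryParams, dim: int = 3):
        if dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        self.params = params
        self.dim = dim

    # fluid SDF -------------------------------------------------------------
    def sdf(self, p: np.ndarray) -> np.ndarray:
        g = self.params
        arms_x = _sd_capped_cylinder(p, 0, g.arm_length, g.tube_radius, self.dim)
        arms_y = _sd_capped_cylinder(p, 1, g.arm_length, g.tube_radius, self.dim)
        housing = _sd_sphere(p, g.housing_radius)
        d = np.minimum(np.minimum(arms_x, arms_y), housing)
        if g.insert_kind == "bicone":
            d = np.maximum(d, -self._sd_insert(p))
        return d

    def _sd_insert(self, p: np.ndarray) -> np.ndarray:
        g = self.params
        d = _sd_bicone(p, 1, g.bicone_height / 2.0,
                       g.equator_radius_effective, self.dim)
        if self.dim == 3:
            for k in range(g.n_struts):
                ang = np.pi / 4 + k * 2 * np.pi / g.n_struts
                d = np.minimum(d, _sd_strut(p, ang, g.strut_diameter / 2.0,
                                            g.housing_radius + g.tube_radius))
        return d

    def _sd_struts_only(self, p: np.ndarray) -> np.ndarray:
        g = self.params
        d = np.full(p.shape[0], np.inf)
        if self.dim == 3 and g.insert_kind == "bicone":
            for k in range(g.n_struts):
                ang = np.pi / 4 + k * 2 * np.pi / g.n_struts
                d = np.minimum(d, _sd_strut(p, ang, g.strut_diameter / 2.0,
                                            g.housing_radius + g.tube_radius))
        return d

    # sizing ----------------------------------------------------------------
    #: far-field-to-insert element-size ratio when an insert is present
    REFINE_RATIO = 1.8

    def size_field(self, p: np.ndarray, h_fine: float) -> np.ndarray:
        """Relative mesh-size function, minimum 1 (= h_fine) at the insert.

        Grows linearly with distance from the insert surfaces up to
        ``REFINE_RATIO`` in the far field, echoing the bench study's finer
        surface discretization of impeller and struts.
        """
        if self.params.insert_kind != "bicone":
            return np.ones(p.shape[0])
        d_ins = np.abs(self._sd_insert(p))
        grow = 1.0 + (self.REFINE_RATIO - 1.0) * d_ins / (4.0 * h_fine)
        return np.clip(grow, 1.0, self.REFINE_RATIO)

    # labeling --------------------------------------------------------------
    def label_faces(self, centroids: np.ndarray,
                    normals: np.ndarray | None = None) -> np.ndarray:
        """Assign each boundary face to its port or wall group.

        Port caps are planar disks at the arm ends: a face belongs to a
        port when its centroid sits near the cap plane and (when normals
        are supplied) its outward normal is roughly axis-aligned, which
        separates caps from lateral tube walls even on very coarse meshes.
        """
        g = self.params
        labels = np.empty(centroids.shape[0], dtype=object)
        labels[:] = "wall_housing"
        if g.insert_kind == "bicone":
            d_ins = self._sd_insert(centroids)
            labels[np.abs(d_ins) < 0.25 * g.tube_radius] = "wall_rotor"
            d_str = self._sd_struts_only(centroids)
            labels[np.abs(d_str) < 0.5 * g.strut_diameter] = "wall_strut"
        if normals is None:
            port_tol = 0.05 * g.tube_radius
            for name, (axis, sign) in self.PORTS.items():
                on_cap = np.abs(centroids[:, axis] - sign * g.arm_length) < port_tol
                labels[on_cap] = name
        else:
            port_tol = 0.5 * g.tube_radius
            for name, (axis, sign) in self.PORTS.items():
                near = np.abs(centroids[:, axis] - sign * g.arm_length) < port_tol
                aligned = sign * normals[:, axis] > 0.5
                labels[near & aligned] = name
        return labels

    def bbox(self) -> np.ndarray:
        g = self.params
        L = g.arm_length
        r = max(g.housing_radius, g.tube_radius)
        lo = [-L, -L, -r][: self.dim]
        hi = [L, L, r][: self.dim]
        return np.array([lo, hi])

    def port_fixed_points(self, h: float) -> np.ndarray:
        """Rings of fixed nodes on the four port rims (keeps ports planar)."""
        g = self.params
        pts = []
        for name, (axis, sign) in self.PORTS.items():
            if self.dim == 2:
                for side in (-1.0, 1.0):
                    q = np.zeros(2)
                    q[axis] = sign * g.arm_length
                    q[1 - axis] = side * g.tube_radius
                    pts.append(q)
            else:
                n = max(8, int(np.ceil(2 * np.pi * g.tube_radius / h)))
                th = 2 * np.pi * np.arange(n) / n
                q = np.zeros((n, 3))
                q[:, axis] = sign * g.arm_length
                others = [i for i in range(3) if i != axis]
                q[:, others[0]] = g.tube_radius * np.cos(th)
                q[:, others[1]] = g.tube_radius * np.sin(th)
                pts.append(q)
        return np.vstack([np.atleast_2d(q) for q in pts])
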