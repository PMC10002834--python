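"""Hemodynamic endpoints: wall shear metrics, pressures, splits, power loss.

Shear-based thrombosis surrogates follow the standard definitions: the wall
traction is the tangential projection of the fluid stress vector,
tau = sigma.n - (sigma.n.n)n with sigma = -pI + mu(grad v + grad v^T);
TAWSS is the magnitude of the time-averaged traction vector (vector average
first, then magnitude); OSI = (1 - |int tau dt| / int |tau| dt)/2 in
[0, 0.5], zero for unidirectional shear and 0.5 for full reversal; low-WSS
regions are those with TAWSS below 5 dyn/cm^2.

Pressure endpoints are area-averaged over mesh/plane intersection sections
(cut planes 4 cm from the junction center by default), time-averaged over a
window, and reported in mmHg; power loss is the net static+dynamic pressure
energy flux through the ports, reported in mW.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import P1Basis
from .flow import FlowField, boundary_flux
from .mesh import SimplicialMesh
from .units import ERG_PER_S_TO_MW, mmhg

__all__ = [
    "WallTractionSeries", "CutPlane", "EndpointReport",
    "wall_traction", "tawss", "osi", "low_wss_area_fraction",
    "cut_plane_pressure", "pressure_loss", "flow_split", "power_loss",
    "compute_endpoint_report", "LOW_WSS_THRESHOLD",
]

LOW_WSS_THRESHOLD = 5.0
"""Empirical low-WSS threshold, dyn/cm^2."""

#: junction port -> (axis, direction) in the geometry convention
_PORT_AXES = {
    "outlet_RPA": (0, +1.0), "outlet_LPA": (0, -1.0),
    "inlet_SVC": (1, +1.0), "inlet_IVC": (1, -1.0),
}


@dataclass
class WallTractionSeries:
    """Tangential wall stress history on one or more wall groups."""

    mesh: SimplicialMesh
    groups: tuple
    nodes: np.ndarray            # (n_w,) node ids
    normals: np.ndarray          # (n_w, dim) outward unit normals
    times: np.ndarray            # (n_t,)
    traction: np.ndarray         # (n_t, n_w, dim) tangential stress, dyn/cm^2

    def window_indices(self, window) -> np.ndarray:
        t0, t1 = window
        idx = np.nonzero((self.times >= t0 - 1e-12)
                         & (self.times <= t1 + 1e-12))[0]
        if idx.size == 0:
            raise ValueError(f"window {window} contains no snapshots")
        return idx


@dataclass
class CutPlane:
    """Plane transverse to one junction arm, ``offset`` cm from the origin."""

    arm: str                      # port group name, e.g. "outlet_RPA"
    offset: float = 4.0

    def origin_normal(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        axis, sign = _PORT_AXES[self.arm]
        origin = np.zeros(dim)
        origin[axis] = sign * self.offset
        normal = np.zeros(dim)
        normal[axis] = sign
        return origin, normal


@dataclass
class EndpointReport:
    """Scalar endpoint summary for one case (pressures mmHg, power mW)."""

    case_id: str
    co_l_min: float
    model: str
    dp_pairs_mmhg: dict = field(default_factory=dict)
    dp_max_mmhg: float = np.nan
    flow_split_rpa_pct: float = np.nan
    power_loss_mw: float = np.nan
    mean_tawss: dict = field(default_factory=dict)      # per wall group
    low_wss_fraction: dict = field(default_factory=dict)
    mean_osi: dict = field(default_factory=dict)
    mean_washout_s: float = np.nan
    washout_censored_fraction: float = np.nan
    solver_status: str = ""

    def as_row(self) -> dict:
        row = {"case_id": self.case_id, "CO_L_min": self.co_l_min,
               "model": self.model, "dP_max_mmHg": self.dp_max_mmhg,
               "flow_split_RPA_pct": self.flow_split_rpa_pct,
               "power_loss_mW": self.power_loss_mw,
               "mean_washout_s": self.mean_washout_s,
               "washout_censored_fraction": self.washout_censored_fraction,
               "solver_status": self.solver_status}
        for k, v in self.dp_pairs_mmhg.items():
            row[f"dP_{k}_mmHg"] = v
        for k, v in self.mean_tawss.items():
            row[f"TAWSS_{k}_dyn_cm2"] = v
        for k, v in self.low_wss_fraction.items():
            row[f"lowWSS_{k}"] = v
        for k, v in self.mean_osi.items():
            row[f"OSI_{k}"] = v
        return row


# -------------------------------------------------------------- wall stress

def _recovered_gradients(mesh: SimplicialMesh, basis: P1Basis,
                         v: np.ndarray) -> np.ndarray:
    """Volume-weighted recovery of grad v at nodes, (n, dim, dim)."""
    ge = basis.gradient(v)                       # (m, d, d)
    n, d = mesh.n_nodes, mesh.dim
    acc = np.zeros((n, d, d))
    w = np.zeros(n)
    cells = mesh.cells
    nn = d + 1
    np.add.at(acc, cells.ravel(),
              np.repeat(basis.vols[:, None, None] * ge, nn, axis=0
                        ).reshape(-1, d, d))
    np.add.at(w, cells.ravel(), np.repeat(basis.vols, nn))
    return acc / w[:, None, None]


def wall_traction(field: FlowField, groups) -> WallTractionSeries:
    """Tangential stress vector history on the given wall groups."""
    mesh = field.mesh
    groups = tuple(groups)
    faces = np.concatenate([mesh.group_faces(g) for g in groups])
    if faces.size == 0:
        raise ValueError("wall groups contain no faces")
    nodes, normals = mesh.node_normals(faces)
    mu = field.fluid.viscosity
    basis = P1Basis(mesh.nodes, mesh.cells)
    out = np.empty((field.n_snapshots, nodes.size, mesh.dim))
    for k in range(field.n_snapshots):
        v, p = field.velocity[k], field.pressure[k]
        grad = _recovered_gradients(mesh, basis, v)[nodes]
        sigma = mu * (grad + np.swapaxes(grad, 1, 2))
        sigma -= p[nodes, None, None] * np.eye(mesh.dim)[None]
        tn = np.einsum("nij,nj->ni", sigma, normals)
        tnn = np.einsum("ni,ni->n", tn, normals)
        out[k] = tn - tnn[:, None] * normals
    return WallTractionSeries(mesh, groups, nodes, normals,
                              field.times, out)


def tawss(series: WallTractionSeries, window=None) -> np.ndarray:
    """Magnitude of the time-averaged traction vector per wall node."""
    if window is None:
        window = (series.times[0], series.times[-1])
    idx = series.window_indices(window)
    if idx.size == 1:
        mean = series.traction[idx[0]]
    else:
        t = series.times[idx]
        mean = np.trapezoid(series.traction[idx], t, axis=0) / (t[-1] - t[0])
    return np.linalg.norm(mean, axis=1)


def osi(series: WallTractionSeries, window=None) -> np.ndarray:
    """Oscillatory shear index in [0, 0.5]; 0 where shear never acts."""
    if window is None:
        window = (series.times[0], series.times[-1])
    idx = series.window_indices(window)
    if idx.size == 1:
        return np.zeros(series.nodes.size)
    t = series.times[idx]
    num = np.linalg.norm(np.trapezoid(series.traction[idx], t, axis=0),
                         axis=1)
    den = np.trapezoid(np.linalg.norm(series.traction[idx], axis=2), t,
                       axis=0)
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = 0.5 * (1.0 - num[ok] / den[ok])
    return np.clip(out, 0.0, 0.5)


def low_wss_area_fraction(series: WallTractionSeries, tawss_values: np.ndarray,
                          group: str,
                          threshold: float = LOW_WSS_THRESHOLD) -> float:
    """Area fraction of a wall group with TAWSS below the threshold."""
    mesh = series.mesh
    faces = mesh.group_faces(group)
    areas, _ = mesh.face_areas_normals(faces)
    bf = mesh.boundary_faces[faces]
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[series.nodes] = np.arange(series.nodes.size)
    loc = remap[bf]
    if np.any(loc < 0):
        raise ValueError(f"group {group!r} not covered by the traction series")
    face_tawss = tawss_values[loc].mean(axis=1)
    return float(areas[face_tawss < threshold].sum() / areas.sum())


def mean_over_group(series: WallTractionSeries, values: np.ndarray,
                    group: str) -> float:
    """Area-weighted mean of a nodal wall quantity over one group."""
    mesh = series.mesh
    faces = mesh.group_faces(group)
    areas, _ = mesh.face_areas_normals(faces)
    bf = mesh.boundary_faces[faces]
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[series.nodes] = np.arange(series.nodes.size)
    face_val = values[remap[bf]].mean(axis=1)
    return float(np.sum(areas * face_val) / areas.sum())


# ------------------------------------------------------------- cut planes

def _plane_sections(mesh: SimplicialMesh, origin, normal):
    """Intersect the mesh with a plane.

    Returns (weights, vertex_pairs): per intersection sub-element quadrature
    data such that the plane integral of a nodal field f is
    sum_k weights_k * mean(f at the crossing-point interpolants).
    Concretely: a list of (area, node_a, node_b, w_interp) per polygon
    vertex is reduced to arrays for vectorized evaluation.
    """
    s = (mesh.nodes - origin) @ normal
    # nudge nodes lying exactly on the plane so every section is a clean
    # transversal cut (an offset far below any element size)
    tol = 1e-9 * float(np.ptp(mesh.nodes))
    s = np.where(np.abs(s) < tol, tol, s)
    cells = mesh.cells
    sc = s[cells]
    crossing = np.nonzero((sc.min(axis=1) < 0) & (sc.max(axis=1) > 0))[0]
    if crossing.size == 0:
        raise ValueError("cut plane does not intersect the mesh")
    polys = []        # (area, list of (na, nb, w)) with point = (1-w) xa + w xb
    d = mesh.dim
    for c in crossing:
        verts = cells[c]
        sv = s[verts]
        pts, interp = [], []
        for i in range(d + 1):
            for j in range(i + 1, d + 1):
                si, sj = sv[i], sv[j]
                if (si < 0) != (sj < 0):
                    w = si / (si - sj)
                    pts.append((1 - w) * mesh.nodes[verts[i]]
                               + w * mesh.nodes[verts[j]])
                    interp.append((verts[i], verts[j], w))
        pts = np.asarray(pts)
        if len(pts) < d - 1 + 1:
            continue
        if d == 2:
            # segment: measure = length
            if len(pts) < 2:
                continue
            area = np.linalg.norm(pts[1] - pts[0])
            polys.append((area, interp[:2]))
        else:
            # polygon (3 or 4 points): order by angle, fan-triangulate
            center = pts.mean(axis=0)
            e1 = pts[0] - center
            e1 /= max(np.linalg.norm(e1), 1e-300)
            e2 = np.cross(normal, e1)
            ang = np.arctan2((pts - center) @ e2, (pts - center) @ e1)
            order = np.argsort(ang)
            pts, interp = pts[order], [interp[k] for k in order]
            for k in range(1, len(pts) - 1):
                tri = [0, k, k + 1]
                area = 0.5 * np.linalg.norm(
                    np.cross(pts[tri[1]] - pts[tri[0]],
                             pts[tri[2]] - pts[tri[0]]))
                polys.append((area, [interp[t] for t in tri]))
    if not polys:
        raise ValueError("cut plane intersection is empty")
    return polys


def _plane_average(mesh, polys, nodal: np.ndarray) -> float:
    total_a = 0.0
    total = 0.0
    for area, interp in polys:
        vals = [(1 - w) * nodal[na] + w * nodal[nb] for na, nb, w in interp]
        total += area * float(np.mean(vals))
        total_a += area
    return total / total_a


def cut_plane_pressure(field: FlowField, plane: CutPlane,
                       window=None) -> float:
    """Area-averaged section pressure, time-averaged over window, in mmHg."""
    mesh = field.mesh
    origin, normal = plane.origin_normal(mesh.dim)
    polys = _plane_sections(mesh, origin, normal)
    if window is None:
        idx = np.array([field.n_snapshots - 1])
    else:
        t0, t1 = window
        idx = np.nonzero((field.times >= t0 - 1e-12)
                         & (field.times <= t1 + 1e-12))[0]
        if idx.size == 0:
            raise ValueError(f"window {window} contains no snapshots")
    vals = np.array([_plane_average(mesh, polys, field.pressure[k])
                     for k in idx])
    if idx.size == 1:
        return mmhg(float(vals[0]))
    t = field.times[idx]
    return mmhg(float(np.trapezoid(vals, t) / (t[-1] - t[0])))


def pressure_loss(field: FlowField, inlet_plane: CutPlane,
                  outlet_plane: CutPlane, window=None) -> float:
    """Mean inlet-section minus outlet-section pressure, mmHg."""
    return (cut_plane_pressure(field, inlet_plane, window)
            - cut_plane_pressure(field, outlet_plane, window))


def pressure_loss_matrix(field: FlowField, offset: float = 4.0,
                         window=None) -> tuple[dict, float]:
    """All four inlet-to-outlet pressure losses and their maximum (mmHg)."""
    inlets = [g for g in field.mesh.group_names() if g.startswith("inlet")]
    outlets = [g for g in field.mesh.group_names() if g.startswith("outlet")]
    p_in = {g: cut_plane_pressure(field, CutPlane(g, offset), window)
            for g in inlets}
    p_out = {g: cut_plane_pressure(field, CutPlane(g, offset), window)
             for g in outlets}
    pairs = {}
    for gi in inlets:
        for go in outlets:
            key = f"{gi.split('_')[-1]}_{go.split('_')[-1]}"
            pairs[key] = p_in[gi] - p_out[go]
    return pairs, max(pairs.values())


# ------------------------------------------------------------ port budgets

def flow_split(field: FlowField, window=None) -> float:
    """Percentage of total outflow leaving through the RPA, time-averaged."""
    mesh = field.mesh
    idx = (np.arange(field.n_snapshots) if window is None
           else np.nonzero((field.times >= window[0] - 1e-12)
                           & (field.times <= window[1] + 1e-12))[0])
    qr = np.mean([boundary_flux(mesh, field.velocity[k], "outlet_RPA")
                  for k in idx])
    ql = np.mean([boundary_flux(mesh, field.velocity[k], "outlet_LPA")
                  for k in idx])
    if qr + ql <= 0:
        raise ValueError("no net outflow; flow split undefined")
    return 100.0 * qr / (qr + ql)


def _energy_flux(mesh: SimplicialMesh, v, p, rho, group) -> float:
    """Outward flux of total pressure, int (p + rho|v|^2/2)(v.n) dGamma."""
    faces = mesh.group_faces(group)
    areas, normals = mesh.face_areas_normals(faces)
    bf = mesh.boundary_faces[faces]
    vf = v[bf]                                  # (f, d, dim)
    pf = p[bf]
    etot = pf + 0.5 * rho * np.einsum("fad,fad->fa", vf, vf)
    vn = np.einsum("fad,fd->fa", vf, normals)
    return float(np.sum(areas / mesh.dim * np.sum(etot * vn, axis=1)))


def power_loss(field: FlowField, window=None) -> float:
    """Net rate of total-pressure energy dissipated between ports, in mW.

    Positive for any dissipative flow: energy carried in through the venae
    cavae exceeds the energy carried out through the pulmonary arteries.
    """
    mesh = field.mesh
    rho = field.fluid.density
    inlets = [g for g in mesh.group_names() if g.startswith("inlet")]
    outlets = [g for g in mesh.group_names() if g.startswith("outlet")]
    idx = (np.arange(field.n_snapshots) if window is None
           else np.nonzero((field.times >= window[0] - 1e-12)
                           & (field.times <= window[1] + 1e-12))[0])
    vals = []
    for k in idx:
        v, p = field.velocity[k], field.pressure[k]
        net = -sum(_energy_flux(mesh, v, p, rho, g)
                   for g in inlets + outlets)
        vals.append(net)
    return float(np.mean(vals)) * ERG_PER_S_TO_MW


# ----------------------------------------------------------------- report

def compute_endpoint_report(field: FlowField, case_id: str, co_l_min: float,
                            model: str, cut_offset: float = 4.0,
                            window=None,
                            wss_threshold: float = LOW_WSS_THRESHOLD,
                            ) -> EndpointReport:
    """Evaluate every scalar endpoint of one solved case."""
    mesh = field.mesh
    rep = EndpointReport(case_id, co_l_min, model,
                         solver_status=field.status)
    rep.dp_pairs_mmhg, rep.dp_max_mmhg = pressure_loss_matrix(
        field, cut_offset, window)
    rep.flow_split_rpa_pct = flow_split(field, window)
    rep.power_loss_mw = power_loss(field, window)
    wall_groups = [g for g in mesh.group_names() if g.startswith("wall")]
    series = wall_traction(field, wall_groups)
    ts = tawss(series, window)
    os_ = osi(series, window)
    for g in wall_groups:
        rep.mean_tawss[g] = mean_over_group(series, ts, g)
        rep.low_wss_fraction[g] = low_wss_area_fraction(series, ts, g,
                                                        wss_threshold)
        rep.mean_osi[g] = mean_over_group(series, os_, g)
    return rep


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack endpoint reports into a tidy one-row-per-case table."""
    return pd.DataFrame([r.as_row() for r in reports])
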