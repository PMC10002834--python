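"""Stabilized equal-order FEM solver for incompressible Newtonian flow.

Discretization: continuous piecewise-linear velocity and pressure on
simplices with residual-based SUPG/PSPG stabilization and a grad-div
(continuity least-squares) term, the classical remedy for both the
advection instability and the inf-sup deficiency of equal-order pairs.
Element stabilization parameters follow the covariant-metric form

    tau_M = (4/dt^2 + v.G.v + C_I nu^2 G:G)^(-1/2),   C_I = 36,
    tau_C = 1 / (tau_M tr G),

with G the element metric tensor.  Boundary conditions: strong no-slip on
wall groups, strong parabolic/plug inlet profiles, resistance tractions
h = -(R Q + P_distal) n on outlets (implicitly coupled, contributing a
rank-one Jacobian block), and convective backflow stabilization on outlet
faces with locally reversed flow.

Time integration is the second-order generalized-alpha method for
first-order systems; the steady mode is pseudo-transient continuation
(backward Euler with a geometrically growing pseudo step) that reports
whether a stalled residual looks like genuinely unsteady physics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import P1Basis
from .mesh import SimplicialMesh
from .synthetic import BCSet

__all__ = [
    "SolverSettings", "FlowField", "SolverError",
    "solve_steady", "solve_transient", "inlet_profile",
    "resistance_outlet_traction", "backflow_traction_correction",
    "check_mass_conservation", "boundary_flux",
]

C_I = 36.0  # inverse-estimate constant for linear simplices


class SolverError(RuntimeError):
    """Nonlinear or linear solve failure; carries diagnostic context."""

    def __init__(self, msg: str, step: int | None = None,
                 residuals: list | None = None):
        super().__init__(msg)
        self.step = step
        self.residuals = residuals or []


@dataclass
class SolverSettings:
    """Numerical controls for the flow solver.

    The transient defaults mirror the bench simulation protocol: dt = 1 ms,
    5 s horizon, snapshots every 20 ms.
    """

    dt: float = 0.001
    t_end: float = 5.0
    save_every: float = 0.02
    rho_inf: float = 0.5
    newton_tol: float = 1e-3
    newton_max_iter: int = 6
    relaxation: float = 1.0
    backflow_beta: float = 0.2
    linear_solver: str = "direct"       # {"direct", "iterative"}
    steady_mode: bool = False
    # pseudo-transient continuation controls (steady mode)
    pseudo_dt0: float = 0.01
    pseudo_dt_max: float = 50.0
    pseudo_dt_growth: float = 2.0
    steady_tol: float = 2e-4
    max_pseudo_steps: int = 60
    ramp_steps: int = 8
    stall_window: int = 8
    reuse_jacobian: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.rho_inf <= 1.0:
            raise ValueError("rho_inf must lie in [0, 1]")
        if not 0.0 <= self.backflow_beta <= 1.0:
            raise ValueError("backflow_beta must lie in [0, 1]")
        n = self.save_every / self.dt
        if abs(n - round(n)) > 1e-8:
            raise ValueError("save_every must be an integer multiple of dt")


@dataclass
class FlowField:
    """Velocity/pressure snapshots on a mesh (CGS units)."""

    mesh: SimplicialMesh
    times: np.ndarray                 # (n_t,)
    velocity: np.ndarray              # (n_t, n_nodes, dim) cm/s
    pressure: np.ndarray              # (n_t, n_nodes) dyn/cm^2
    fluid: object = None              # FluidProperties
    bc: BCSet | None = None
    converged: bool = True
    status: str = "converged"         # {"converged", "unsteady_physics", "stalled"}
    residual_history: list = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def snapshot(self, k: int = -1) -> tuple[np.ndarray, np.ndarray]:
        return self.velocity[k], self.pressure[k]


# ------------------------------------------------------------ boundary data

def boundary_flux(mesh: SimplicialMesh, v: np.ndarray, group: str) -> float:
    """Outward volumetric flux of nodal field v through a boundary group."""
    faces = mesh.group_faces(group)
    areas, normals = mesh.face_areas_normals(faces)
    bf = mesh.boundary_faces[faces]
    vmean = v[bf].mean(axis=1)
    return float(np.sum(areas * np.einsum("fd,fd->f", vmean, normals)))


def _flux_vector(mesh: SimplicialMesh, group: str, n_nodes: int) -> np.ndarray:
    """Nodal weight vector u with u[n] . v[n] summing to the outward flux."""
    faces = mesh.group_faces(group)
    areas, normals = mesh.face_areas_normals(faces)
    bf = mesh.boundary_faces[faces]
    u = np.zeros((n_nodes, mesh.dim))
    w = (areas / mesh.dim)[:, None] * normals
    for loc in range(mesh.dim):
        np.add.at(u, bf[:, loc], w)
    return u


def inlet_profile(mesh: SimplicialMesh, group: str, q: float,
                  kind: str = "parabolic") -> tuple[np.ndarray, np.ndarray]:
    """Nodal inflow velocity on a planar port patch.

    Returns (node_ids, velocities) with the discrete integrated flux equal
    to ``q`` (into the domain).  The parabolic profile vanishes on the patch
    rim and peaks at twice the mean speed, the fully developed tube profile.
    """
    faces = mesh.group_faces(group)
    areas, normals = mesh.face_areas_normals(faces)
    n_mean = np.sum(areas[:, None] * normals, axis=0)
    n_mean /= np.linalg.norm(n_mean)
    if np.min(normals @ n_mean) < 0.8:
        raise ValueError(f"inlet patch {group!r} is not planar")
    bf = mesh.boundary_faces[faces]
    nodes = np.unique(bf)
    coords = mesh.nodes[nodes]
    center = np.sum((areas[:, None] / mesh.dim)[:, None]
                    * mesh.nodes[bf], axis=(0, 1)) / areas.sum()
    if q == 0.0:
        return nodes, np.zeros_like(coords)
    if kind == "parabolic":
        r = np.linalg.norm(coords - center, axis=1)
        w = np.maximum(1.0 - (r / r.max()) ** 2, 0.0)
    elif kind == "plug":
        w = np.ones(nodes.size)
    else:
        raise ValueError(f"unknown inlet profile kind {kind!r}")
    nodal_w = np.zeros(mesh.n_nodes)
    nodal_w[nodes] = w
    inward = -n_mean
    raw_flux = boundary_flux(mesh, nodal_w[:, None] * inward[None, :], group)
    # raw outward flux is negative for inflow; scale so it equals exactly -q
    scale = -q / raw_flux
    return nodes, (scale * w)[:, None] * inward[None, :]


def resistance_outlet_traction(r: float, q_outlet: float, normal: np.ndarray,
                               distal_pressure: float = 0.0) -> np.ndarray:
    """Weak-form outlet traction h = -(R Q + P_distal) n."""
    if r < 0:
        raise ValueError("resistance must be non-negative")
    return -(r * q_outlet + distal_pressure) * np.asarray(normal, float)


def backflow_traction_correction(v: np.ndarray, normals: np.ndarray,
                                 beta: float, rho: float) -> np.ndarray:
    """Convective-inflow penalty traction beta*rho*(v.n)_- v per node.

    Zero wherever the local flow leaves the domain (v.n >= 0); where flow
    re-enters, the added traction opposes the reversed velocity.
    """
    vn = np.einsum("nd,nd->n", v, normals)
    return beta * rho * np.minimum(vn, 0.0)[:, None] * v


# ------------------------------------------------------------------ solver

class _FlowSystem:
    """Assembly and BC machinery for one (mesh, bc, settings) triple."""

    def __init__(self, mesh: SimplicialMesh, bc: BCSet,
                 settings: SolverSettings):
        self.mesh = mesh
        self.bc = bc
        self.set = settings
        self.basis = P1Basis(mesh.nodes, mesh.cells)
        self.d = mesh.dim
        self.nb = self.d + 1              # dofs per node (v..., p)
        self.ndof = mesh.n_nodes * self.nb
        self.rho = bc.fluid.density
        self.mu = bc.fluid.viscosity
        self._prep_bc()
        self._lu = None
        self._lu_key = None

    # ---- boundary conditions
    def _prep_bc(self) -> None:
        mesh, bc = self.mesh, self.bc
        wall_groups = [g for g in mesh.group_names() if g.startswith("wall")]
        wall_nodes = (np.unique(np.concatenate(
            [mesh.group_nodes(g) for g in wall_groups]))
            if wall_groups else np.array([], dtype=np.int64))
        vdir = np.zeros((mesh.n_nodes, self.d))
        mask = np.zeros(mesh.n_nodes, dtype=bool)
        mask[wall_nodes] = True
        for group, q in bc.inlet_flows.items():
            nodes, vals = inlet_profile(mesh, group, q, bc.inlet_profile)
            free = ~mask[nodes]          # wall (rim) nodes keep no-slip
            vdir[nodes[free]] = vals[free]
            if q > 0:
                # rescale interior inlet dofs so the discrete flux stays exact
                probe = np.zeros_like(vdir)
                probe[nodes[free]] = vals[free]
                flux = -boundary_flux(mesh, probe, group)
                if flux > 0:
                    vdir[nodes[free]] *= q / flux
            mask[nodes] = True
        self.dirichlet_mask = mask
        self.dirichlet_values = vdir
        dir_dofs = []
        for i in range(self.d):
            dir_dofs.append(np.nonzero(mask)[0] * self.nb + i)
        self.dirichlet_dofs = np.sort(np.concatenate(dir_dofs))
        # outlet bookkeeping for resistance + backflow terms
        self.outlets = []
        for group, r in bc.outlet_resistances.items():
            u = _flux_vector(mesh, group, mesh.n_nodes)
            nodes, nrm = mesh.node_normals(mesh.group_faces(group))
            w = np.zeros(mesh.n_nodes)
            faces = mesh.group_faces(group)
            areas, _ = mesh.face_areas_normals(faces)
            bf = mesh.boundary_faces[faces]
            np.add.at(w, bf.ravel(), np.repeat(areas / self.d, self.d))
            self.outlets.append({
                "group": group, "R": r, "u": u,
                "nodes": nodes, "normals": nrm, "node_area": w[nodes],
            })

    def apply_dirichlet_state(self, v: np.ndarray) -> np.ndarray:
        v = v.copy()
        v[self.dirichlet_mask] = self.dirichlet_values[self.dirichlet_mask]
        return v

    # ---- core assembly
    def assemble(self, v, p, vdot, acc_coeff, dt_tau, want_jacobian=True):
        """Residual (and Jacobian) of the stabilized weak form.

        acc_coeff: d(vdot)/d(v) factor of the time integrator (0 for a pure
        steady residual); dt_tau: the dt entering tau_M (np.inf drops the
        transient term).
        """
        b = self.basis
        d, nb = self.d, self.nb
        cells = b.cells
        m = cells.shape[0]
        nloc = (d + 1) * nb
        vols, B, G = b.vols, b.grads, b.metric
        N, qw = b.qp_shape, b.qw
        rho, mu = self.rho, self.mu
        f_body = np.asarray(self.bc.body_force[:d], float)

        v_e = v[cells]                      # (m, d+1, d)
        p_e = p[cells]                      # (m, d+1)
        vd_e = vdot[cells]
        grad_v = np.einsum("mai,mad->mid", v_e, B)
        div_v = np.einsum("mii->m", grad_v)
        grad_p = np.einsum("ma,mad->md", p_e, B)

        vbar = v_e.mean(axis=1)
        nu = mu / rho
        vGv = np.einsum("mi,mij,mj->m", vbar, G, vbar)
        GG = np.einsum("mij,mij->m", G, G)
        trG = np.einsum("mii->m", G)
        inv_dt2 = 0.0 if np.isinf(dt_tau) else 4.0 / dt_tau ** 2
        tau_m = 1.0 / np.sqrt(inv_dt2 + vGv + C_I * nu ** 2 * GG)
        tau_c = 1.0 / (tau_m * trG)

        R_el = np.zeros((m, d + 1, nb))
        J_el = np.zeros((m, nloc, nloc)) if want_jacobian else None

        # quadrature-free pieces (constant integrands)
        pbar = p_e.mean(axis=1)
        sym = grad_v + np.swapaxes(grad_v, 1, 2)
        # momentum: viscous + pressure + grad-div
        R_el[:, :, :d] += mu * np.einsum("mad,mid->mai", B, sym) * vols[:, None, None]
        R_el[:, :, :d] -= np.einsum("mai,m->mai", B, pbar * vols)
        R_el[:, :, :d] += (rho * tau_c * div_v * vols)[:, None, None] * B
        # continuity galerkin
        R_el[:, :, d] += (div_v * vols)[:, None] / (d + 1)

        supg_adv = np.zeros((m, d + 1))     # accumulated sum_q wq (v_q . B_a)
        rm_bar = np.zeros((m, d))           # sum_q wq r_m
        for q in range(N.shape[0]):
            Nq = N[q]
            wq = qw[q]
            v_q = np.einsum("a,mad->md", Nq, v_e)
            vd_q = np.einsum("a,mad->md", Nq, vd_e)
            conv_q = np.einsum("mj,mij->mi", v_q, grad_v)
            accel = rho * (vd_q + conv_q - f_body)
            r_m = accel + grad_p
            rm_bar += wq * r_m
            adv_a = np.einsum("mj,maj->ma", v_q, B)   # v_q . grad N_a
            supg_adv += wq * adv_a
            # momentum galerkin inertial/convective
            R_el[:, :, :d] += wq * vols[:, None, None] * \
                Nq[None, :, None] * accel[:, None, :]
            # momentum SUPG
            R_el[:, :, :d] += (wq * tau_m * vols)[:, None, None] * \
                adv_a[:, :, None] * r_m[:, None, :]
            if want_jacobian:
                self._jac_qp(J_el, Nq, wq, v_q, grad_v, adv_a, B, vols,
                             tau_m, acc_coeff)
        # continuity PSPG
        R_el[:, :, d] += (tau_m / rho * vols)[:, None] * \
            np.einsum("mad,md->ma", B, rm_bar)

        if want_jacobian:
            self._jac_const(J_el, B, vols, tau_m, tau_c, supg_adv)

        # scatter
        R = np.zeros(self.ndof)
        gdof = (cells[:, :, None] * nb
                + np.arange(nb)[None, None, :]).reshape(m, nloc)
        np.add.at(R, gdof.ravel(), R_el.reshape(m, nloc).ravel())
        J = None
        if want_jacobian:
            rows = np.repeat(gdof, nloc, axis=1).ravel()
            cols = np.tile(gdof, (1, nloc)).ravel()
            J = sp.coo_matrix((J_el.ravel(), (rows, cols)),
                              shape=(self.ndof, self.ndof)).tocsr()

        Rb, Jb = self._boundary_terms(v, want_jacobian)
        R += Rb
        if want_jacobian and Jb is not None:
            J = J + Jb
        return (R, J) if want_jacobian else R

    def _jac_qp(self, J_el, Nq, wq, v_q, grad_v, adv_a, B, vols,
                tau_m, acc_coeff):
        """Quadrature-point Jacobian contributions (inertial/convective/SUPG)."""
        d, nb = self.d, self.nb
        rho = self.rho
        m = B.shape[0]
        nn = d + 1
        # test-side weights: galerkin N_a and SUPG tau_m (v.B_a)
        test_g = wq * vols[:, None] * Nq[None, :]                # (m, a)
        test_s = (wq * tau_m * vols)[:, None] * adv_a            # (m, a)
        test = test_g + test_s
        # d(accel_i)/dv_bj = rho (acc_coeff + v.B_b) d_ij + rho N_b dv_i/dx_j
        vBb = adv_a                                              # same array
        diag_b = rho * (acc_coeff * Nq[None, :] + vBb)           # (m, b)
        for a in range(nn):
            for bnode in range(nn):
                blk = J_el[:, a * nb:a * nb + d, bnode * nb:bnode * nb + d]
                coef = test[:, a] * diag_b[:, bnode]
                for i in range(d):
                    blk[:, i, i] += coef
                blk += (test[:, a] * rho * Nq[bnode])[:, None, None] * grad_v
        # PSPG: d r_m/dv contracted with (tau_m/rho) B_a
        pspg_w = (wq * tau_m * vols)                             # (m,)
        for a in range(nn):
            Ba = B[:, a, :]                                      # (m, d)
            for bnode in range(nn):
                row = a * nb + d
                colv = bnode * nb
                # term rho(acc_coeff+v.B_b) delta_kj . B_a[k] -> B_a[j]*coef
                coef = pspg_w / rho * rho * (acc_coeff * Nq[bnode] + vBb[:, bnode])
                J_el[:, row, colv:colv + d] += coef[:, None] * Ba
                # term rho N_b grad_v[k,j] . B_a[k]
                J_el[:, row, colv:colv + d] += (pspg_w * Nq[bnode])[:, None] * \
                    np.einsum("mk,mkj->mj", Ba, grad_v)

    def _jac_const(self, J_el, B, vols, tau_m, tau_c, supg_adv):
        """Constant-in-quadrature Jacobian blocks (viscous, pressure, PSPG-p,
        grad-div, continuity)."""
        d, nb = self.d, self.nb
        mu, rho = self.mu, self.rho
        nn = d + 1
        BaBb = np.einsum("mad,mbd->mab", B, B)
        for a in range(nn):
            for bnode in range(nn):
                blk = J_el[:, a * nb:a * nb + d, bnode * nb:bnode * nb + d]
                coef = mu * vols * BaBb[:, a, bnode]
                for i in range(d):
                    blk[:, i, i] += coef
                blk += (mu * vols)[:, None, None] * \
                    np.einsum("mj,mi->mij", B[:, a, :], B[:, bnode, :])
                blk += (rho * tau_c * vols)[:, None, None] * \
                    np.einsum("mi,mj->mij", B[:, a, :], B[:, bnode, :])
                # momentum-pressure: -B_a[i] /(d+1) + SUPG mean adv
                colp = bnode * nb + d
                J_el[:, a * nb:a * nb + d, colp] += \
                    (-vols / nn)[:, None] * B[:, a, :] + \
                    (tau_m * vols * supg_adv[:, a])[:, None] * B[:, bnode, :]
                # continuity-velocity galerkin
                J_el[:, a * nb + d, bnode * nb:bnode * nb + d] += \
                    (vols / nn)[:, None] * B[:, bnode, :]
                # continuity-pressure PSPG
                J_el[:, a * nb + d, colp] += tau_m / rho * vols * BaBb[:, a, bnode]

    # ---- outlet boundary terms
    def _boundary_terms(self, v, want_jacobian):
        nb = self.nb
        R = np.zeros(self.ndof)
        Jb = None
        tri = ([], [], [])
        for o in self.outlets:
            u = o["u"]                      # (n_nodes, d) flux weights
            q_out = float(np.einsum("nd,nd->", u, v))
            coef = o["R"] * q_out + self.bc.distal_pressure
            # -int w.h = +(R Q + Pd) int w.n
            vel_rows = (np.nonzero(np.any(u != 0, axis=1))[0])
            for n in vel_rows:
                R[n * nb:n * nb + self.d] += coef * u[n]
            if want_jacobian and o["R"] > 0:
                dofs = np.concatenate([vel_rows * nb + i for i in range(self.d)])
                uv = np.concatenate([u[vel_rows, i] for i in range(self.d)])
                outer = o["R"] * np.outer(uv, uv)
                tri[0].append(np.repeat(dofs, dofs.size))
                tri[1].append(np.tile(dofs, dofs.size))
                tri[2].append(outer.ravel())
            # backflow stabilization
            beta = self.set.backflow_beta
            if beta > 0:
                nodes, nrm, w = o["nodes"], o["normals"], o["node_area"]
                vloc = v[nodes]
                vn = np.einsum("nd,nd->n", vloc, nrm)
                neg = np.minimum(vn, 0.0)
                contrib = -self.rho * beta * (w * neg)[:, None] * vloc
                for k, n in enumerate(nodes):
                    R[n * nb:n * nb + self.d] += contrib[k]
                if want_jacobian:
                    act = vn < 0
                    rows = []
                    cols = []
                    vals = []
                    nact = nodes[act]
                    # block: -rho beta w (neg d_ij + n_j v_i)
                    blks = -self.rho * beta * (
                        w[act, None, None] * (
                            neg[act, None, None] * np.eye(self.d)[None]
                            + np.einsum("ni,nj->nij", vloc[act], nrm[act])))
                    for i in range(self.d):
                        for j in range(self.d):
                            rows.append(nact * nb + i)
                            cols.append(nact * nb + j)
                            vals.append(blks[:, i, j])
                    tri[0].append(np.concatenate(rows))
                    tri[1].append(np.concatenate(cols))
                    tri[2].append(np.concatenate(vals))
        if want_jacobian and tri[0]:
            Jb = sp.coo_matrix((np.concatenate(tri[2]),
                                (np.concatenate(tri[0]), np.concatenate(tri[1]))),
                               shape=(self.ndof, self.ndof)).tocsr()
        return R, Jb

    # ---- constrained Newton step
    def _constrain(self, R, J):
        dd = self.dirichlet_dofs
        R = R.copy()
        R[dd] = 0.0
        if J is not None:
            keep = np.ones(self.ndof)
            keep[dd] = 0.0
            fix = np.zeros(self.ndof)
            fix[dd] = 1.0
            J = sp.diags(keep) @ J + sp.diags(fix)
        return R, J

    def solve_linear(self, J, R, reuse_key=None):
        if self.set.linear_solver == "direct":
            if reuse_key is not None and self._lu_key == reuse_key and self._lu is not None:
                return self._lu.solve(R)
            self._lu = spla.splu(J.tocsc())
            self._lu_key = reuse_key
            return self._lu.solve(R)
        M = spla.spilu(J.tocsc(), drop_tol=1e-5, fill_factor=20)
        x, info = spla.lgmres(J, R, M=spla.LinearOperator(J.shape, M.solve),
                              rtol=1e-8, maxiter=300)
        if info != 0:
            raise SolverError("iterative linear solver failed to converge")
        return x

    def steady_residual_norm(self, v, p) -> float:
        R = self.assemble(v, p, np.zeros_like(v), 0.0, np.inf,
                          want_jacobian=False)
        R[self.dirichlet_dofs] = 0.0
        return float(np.linalg.norm(R))


def _pack(v, p):
    n, d = v.shape
    x = np.empty(n * (d + 1))
    x.reshape(n, d + 1)[:, :d] = v
    x.reshape(n, d + 1)[:, d] = p
    return x


def _unpack(x, n, d):
    y = x.reshape(n, d + 1)
    return y[:, :d].copy(), y[:, d].copy()


def solve_steady(mesh: SimplicialMesh, bc: BCSet,
                 settings: SolverSettings | None = None,
                 initial: tuple | None = None) -> FlowField:
    """Stationary flow by pseudo-transient continuation.

    Marches backward-Euler pseudo-steps with a geometrically growing pseudo
    time step until the steady residual drops below ``steady_tol`` relative
    to its initial value.  A residual that stops decreasing while the
    nonlinear solves stay healthy is flagged as ``unsteady_physics`` (the
    physical flow has no stable steady state at this operating point);
    callers should then fall back to a transient solve with time averaging.
    """
    settings = settings or SolverSettings(steady_mode=True)
    sys_ = _FlowSystem(mesh, bc, settings)
    n, d = mesh.n_nodes, mesh.dim
    if initial is not None:
        v, p = initial[0].copy(), initial[1].copy()
    else:
        v, p = np.zeros((n, d)), np.zeros(n)
    v = sys_.apply_dirichlet_state(v)

    ref = sys_.steady_residual_norm(v, p)
    history = [ref]
    if ref < 1e-12:
        return FlowField(mesh, np.array([0.0]), v[None], p[None],
                         fluid=bc.fluid, bc=bc, converged=True,
                         status="converged", residual_history=history)
    full_bc = sys_.dirichlet_values.copy()
    mask = sys_.dirichlet_mask
    rejects = 0

    def _be_step(v, p, dt, key):
        """One backward-Euler pseudo step with inner Newton correction.

        Returns the updated state or None when the step must be rejected.
        """
        v_old = v.copy()
        v, p = v.copy(), p.copy()
        for it in range(max(2, settings.newton_max_iter // 3)):
            vdot = (v - v_old) / dt
            R, J = sys_.assemble(v, p, vdot, 1.0 / dt, dt)
            R, J = sys_._constrain(R, J)
            rn = float(np.linalg.norm(R))
            if not np.isfinite(rn):
                return None
            try:
                dx = sys_.solve_linear(J, R, reuse_key=key if settings.reuse_jacobian else None)
            except RuntimeError as exc:
                raise SolverError(f"linear solve failed in steady mode: {exc}",
                                  residuals=history) from exc
            dv, dp = _unpack(dx, n, d)
            v -= settings.relaxation * dv
            p -= settings.relaxation * dp
        if not np.all(np.isfinite(v)):
            return None
        return v, p

    # phase A: ramp the inlet flow at a small fixed pseudo step, tracking
    # the physical start-up transient (skipped on a warm start)
    if initial is None:
        dt = settings.pseudo_dt0
        for step in range(settings.ramp_steps * 2):
            ramp = min(1.0, (step + 1) / settings.ramp_steps)
            sys_.dirichlet_values = ramp * full_bc
            v[mask] = ramp * full_bc[mask]
            out = _be_step(v, p, dt, key=("ramp", step))
            if out is None:
                raise SolverError("steady solve diverged during inflow ramp",
                                  step=step, residuals=history)
            v, p = out

    # phase B: grow the pseudo step toward a Newton iteration on the
    # stationary equations; reject steps that inflate the steady residual
    sys_.dirichlet_values = full_bc
    status = "stalled"
    dt = 2.0 * settings.pseudo_dt0
    best = np.inf
    best_state = (v.copy(), p.copy())
    since_best = 0
    for step in range(settings.max_pseudo_steps):
        out = _be_step(v, p, dt, key=("grow", step, rejects))
        if out is not None:
            res = sys_.steady_residual_norm(*out)
        if out is None or res > 3.0 * min(best, ref):
            dt *= 0.25
            rejects += 1
            if rejects > 25 or dt < 1e-8:
                break
            continue
        v, p = out
        history.append(res)
        if res < best:
            if res > 0.8 * best:
                since_best += 1
            else:
                since_best = 0
            best = res
            best_state = (v.copy(), p.copy())
        else:
            since_best += 1
        if res < settings.steady_tol * ref:
            status = "converged"
            break
        if since_best >= settings.stall_window:
            break
        dt = min(dt * settings.pseudo_dt_growth, settings.pseudo_dt_max)

    if status != "converged":
        v, p = best_state
        # a residual parked well below the start-up scale while Newton stays
        # healthy indicates genuinely unsteady physics, not solver failure
        status = "unsteady_physics" if best < 0.2 * ref else "stalled"
    return FlowField(mesh, np.array([0.0]), v[None], p[None],
                     fluid=bc.fluid, bc=bc, converged=(status == "converged"),
                     status=status, residual_history=history)


def solve_transient(mesh: SimplicialMesh, bc: BCSet,
                    settings: SolverSettings | None = None,
                    initial: tuple | None = None) -> FlowField:
    """Transient flow with generalized-alpha time integration.

    Spectral radius ``rho_inf`` controls high-frequency damping
    (alpha_m = (3-rho_inf)/(2(1+rho_inf)), alpha_f = 1/(1+rho_inf),
    gamma = 1/2 + alpha_m - alpha_f); each step is corrected by Newton
    iteration to ``newton_tol`` relative residual.
    """
    settings = settings or SolverSettings()
    sys_ = _FlowSystem(mesh, bc, settings)
    n, d = mesh.n_nodes, mesh.dim
    rho_inf = settings.rho_inf
    am = 0.5 * (3.0 - rho_inf) / (1.0 + rho_inf)
    af = 1.0 / (1.0 + rho_inf)
    gamma = 0.5 + am - af
    dt = settings.dt
    c1 = am / (af * gamma * dt)
    c2 = 1.0 - am / gamma

    if initial is not None:
        v, p = initial[0].copy(), initial[1].copy()
    else:
        v, p = np.zeros((n, d)), np.zeros(n)
    v = sys_.apply_dirichlet_state(v)
    vdot_n = np.zeros_like(v)

    n_steps = int(round(settings.t_end / dt))
    save_stride = int(round(settings.save_every / dt))
    times = [0.0]
    vel = [v.copy()]
    pres = [p.copy()]
    history = []
    for step in range(1, n_steps + 1):
        v_n = v.copy()
        vtil = v.copy()              # predictor: v_{n+af} = v_n
        res_hist = []
        converged = False
        for it in range(settings.newton_max_iter):
            vdot_eval = c1 * (vtil - v_n) + c2 * vdot_n
            R, J = sys_.assemble(vtil, p, vdot_eval, c1, dt)
            R, J = sys_._constrain(R, J)
            rn = float(np.linalg.norm(R))
            res_hist.append(rn)
            if not np.isfinite(rn) or (len(res_hist) > 2 and rn > 50 * res_hist[0]):
                raise SolverError(
                    f"Newton diverged at step {step} (t={step*dt:.4f} s)",
                    step=step, residuals=res_hist)
            if rn < settings.newton_tol * max(res_hist[0], 1e-30) or rn < 1e-12:
                converged = True
                break
            reuse = (step, 0) if settings.reuse_jacobian else (step, it)
            dx = sys_.solve_linear(J, R, reuse_key=reuse)
            dv, dp = _unpack(dx, n, d)
            vtil -= settings.relaxation * dv
            p -= settings.relaxation * dp
        history.append(res_hist)
        v_np1 = v_n + (vtil - v_n) / af
        vdot_n = (1.0 - 1.0 / gamma) * vdot_n + (v_np1 - v_n) / (gamma * dt)
        v = v_np1
        if step % save_stride == 0:
            times.append(step * dt)
            vel.append(v.copy())
            pres.append(p.copy())
    return FlowField(mesh, np.asarray(times), np.asarray(vel),
                     np.asarray(pres), fluid=bc.fluid, bc=bc,
                     converged=True, status="converged",
                     residual_history=history)


def check_mass_conservation(field: FlowField) -> np.ndarray:
    """Per-snapshot inflow/outflow imbalance ratio |Qin - Qout| / Qin.

    With zero total inflow the absolute imbalance is returned instead (the
    ratio would be undefined); callers can detect this via field.bc.
    """
    mesh = field.mesh
    inlets = [g for g in mesh.group_names() if g.startswith("inlet")]
    outlets = [g for g in mesh.group_names() if g.startswith("outlet")]
    out = []
    for k in range(field.n_snapshots):
        v = field.velocity[k]
        q_in = -sum(boundary_flux(mesh, v, g) for g in inlets)
        q_out = sum(boundary_flux(mesh, v, g) for g in outlets)
        if abs(q_in) < 1e-12:
            out.append(abs(q_in - q_out))
        else:
            out.append(abs(q_in - q_out) / abs(q_in))
    return np.asarray(out)
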