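"""Virtual-dye transport and washout-time mapping.

A passive scalar (dye concentration phi, initially 1 inside a release region
and 0 elsewhere) is advected over a frozen or time-interpolated velocity
field by the stabilized advection-diffusion equation

    phi_t + v . grad phi - div((kappa + kappa_DC) grad phi) = 0,

with SUPG stabilization (parameter tau_m = (4/dt^2 + v.G.v +
3 (kappa+kappa_DC)^2 G:G)^(-1/2)) and a residual-based discontinuity-
capturing diffusivity kappa_DC = |L(phi)| / (2 sqrt(grad phi . G grad phi)),
active only where the dye front is steep.  Dye concentration is held at 0 on
inlet ports; transport is one-way (the scalar never feeds back on the flow).

The washout time of a point is the interval from the moment its
concentration starts to decay from its maximum until it first reaches 1% of
that maximum; points that never reach the threshold within the horizon are
censored and flagged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .fem import P1Basis, assemble_csr
from .flow import FlowField
from .mesh import SimplicialMesh

__all__ = ["DyeInitRegion", "ScalarField", "WashoutField", "MeanWashout",
           "init_dye", "advance_scalar", "washout_time", "mean_washout"]


@dataclass
class DyeInitRegion:
    """Axis-aligned cubic release region (edge in cm)."""

    center: tuple = (0.0, 0.0, 0.0)
    edge: float = 3.5
    shape: str = "axis_aligned_cube"

    def __post_init__(self) -> None:
        if self.shape != "axis_aligned_cube":
            raise ValueError(f"unsupported region shape {self.shape!r}")
        if self.edge < 0:
            raise ValueError("edge must be non-negative")

    def contains(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center[: points.shape[1]], float)
        return np.all(np.abs(points - c) <= self.edge / 2.0, axis=1)


@dataclass
class ScalarField:
    """Dye concentration snapshots on a mesh."""

    mesh: SimplicialMesh
    times: np.ndarray            # (n_t,)
    phi: np.ndarray              # (n_t, n_nodes)
    kappa: float = 1e-4          # molecular diffusivity, cm^2/s

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def total_dye(self) -> np.ndarray:
        """Integral of phi over the domain per snapshot (lumped mass)."""
        m = P1Basis(self.mesh.nodes, self.mesh.cells).lumped_mass()
        return self.phi @ m


@dataclass
class WashoutField:
    """Per-node washout bookkeeping (times in s)."""

    mesh: SimplicialMesh
    T: np.ndarray                # washout duration t_1pct - t_max
    t_max: np.ndarray            # earliest time of the nodal maximum
    t_1pct: np.ndarray           # first crossing of the 1% threshold
    censored: np.ndarray         # bool, threshold never reached in horizon
    horizon: float = np.nan
    threshold_fraction: float = 0.01


@dataclass
class MeanWashout:
    """Volume-weighted washout summary over a release region."""

    mean_s: float
    censored_fraction: float
    n_nodes: int


def init_dye(mesh: SimplicialMesh, region: DyeInitRegion,
             kappa: float = 1e-4) -> ScalarField:
    """Initial dye snapshot: phi = 1 inside the region, 0 outside."""
    inside = region.contains(mesh.nodes)
    if region.edge > 0 and not np.any(inside):
        raise ValueError("release region does not intersect the fluid domain")
    phi0 = inside.astype(float)
    return ScalarField(mesh, np.array([0.0]), phi0[None, :], kappa)


class _VelocitySampler:
    """Nodal velocity at arbitrary times from a FlowField.

    A single stored snapshot is treated as frozen; otherwise snapshots are
    linearly interpolated in time (clamped at the ends).
    """

    def __init__(self, flow: FlowField):
        self.flow = flow

    def __call__(self, t: float) -> np.ndarray:
        f = self.flow
        if f.n_snapshots == 1:
            return f.velocity[0]
        k = np.searchsorted(f.times, t)
        if k <= 0:
            return f.velocity[0]
        if k >= f.n_snapshots:
            return f.velocity[-1]
        w = (t - f.times[k - 1]) / (f.times[k] - f.times[k - 1])
        return (1.0 - w) * f.velocity[k - 1] + w * f.velocity[k]


def advance_scalar(field0: ScalarField, velocity: FlowField,
                   t_end: float = 5.0, dt: float = 0.02,
                   save_every: float | None = None,
                   theta: float = 1.0, n_picard: int = 2) -> ScalarField:
    """March the dye field implicitly to ``t_end``.

    ``theta`` selects the time scheme between backward Euler (1, the
    default: robust and monotone at the sharp dye front even at large
    advective CFL) and the trapezoidal rule (0.5, second-order, used by
    the smooth verification oracles).  ``dt`` may
    exceed the flow time step: the implicit discretization is
    unconditionally stable for theta >= 1/2, so the scalar step defaults
    to the snapshot cadence.  The nonlinear discontinuity-capturing
    diffusivity is handled by ``n_picard`` fixed-point passes per step
    (the first pass evaluates it on the previous solution).
    """
    if not 0.5 <= theta <= 1.0:
        raise ValueError("theta must lie in [1/2, 1] (implicit schemes only)")
    mesh = field0.mesh
    if velocity.mesh is not mesh and velocity.mesh.n_nodes != mesh.n_nodes:
        raise ValueError("velocity and dye fields live on different meshes")
    save_every = save_every or dt
    stride = int(round(save_every / dt))
    basis = P1Basis(mesh.nodes, mesh.cells)
    sample = _VelocitySampler(velocity)
    kappa = field0.kappa

    inlet_groups = [g for g in mesh.group_names() if g.startswith("inlet")]
    inlet_nodes = (np.unique(np.concatenate(
        [mesh.group_nodes(g) for g in inlet_groups]))
        if inlet_groups else np.array([], dtype=np.int64))

    n = mesh.n_nodes
    nn = mesh.dim + 1
    cells = basis.cells
    vols, B, G = basis.vols, basis.grads, basis.metric
    GG = np.einsum("mij,mij->m", G, G)

    # consistent mass matrix (exact for P1)
    Mloc = (np.ones((nn, nn)) + np.eye(nn)) / ((nn) * (nn + 1.0))
    M_el = vols[:, None, None] * Mloc[None]
    M = assemble_csr(cells, M_el, n)

    phi = field0.phi[-1].copy()
    phi[inlet_nodes] = 0.0
    t0 = float(field0.times[-1])
    times = [t0]
    snaps = [phi.copy()]
    n_steps = int(round((t_end - t0) / dt))

    BaBb = np.einsum("mad,mbd->mab", B, B)
    for step in range(1, n_steps + 1):
        t_new = t0 + step * dt
        v = sample(t_new)
        vbar = v[cells].mean(axis=1)
        adv_b = np.einsum("mi,mbi->mb", vbar, B)          # v.grad N_b
        vGv = np.einsum("mi,mij,mj->m", vbar, G, vbar)
        phi_old = phi
        phi_new = phi
        # Picard passes: the discontinuity-capturing diffusivity is
        # nonlinear in phi, so the step is re-solved with kappa_DC updated
        # from the current iterate (first pass uses the previous solution)
        for _ in range(n_picard):
            grad_phi = np.einsum("ma,mad->md", phi_new[cells], B)
            # The P1 element Laplacian vanishes, so the diffusive part of
            # the residual is reconstructed from recovered nodal gradients.
            phidot = (phi_new - phi_old) / dt
            grad_nodal = np.zeros((n, mesh.dim))
            wsum = np.zeros(n)
            np.add.at(grad_nodal, cells.ravel(),
                      np.repeat(vols[:, None] * grad_phi, nn,
                                axis=0).reshape(-1, mesh.dim))
            np.add.at(wsum, cells.ravel(), np.repeat(vols, nn))
            grad_nodal /= np.maximum(wsum, 1e-300)[:, None]
            lap_el = np.einsum("mad,mad->m", grad_nodal[cells], B)
            res_el = (np.einsum("ma->m", phidot[cells]) / nn
                      + np.einsum("md,md->m", vbar, grad_phi)
                      - kappa * lap_el)
            gGg = np.einsum("md,mde,me->m", grad_phi, G, grad_phi)
            kdc = np.where(gGg > 1e-14,
                           np.abs(res_el) / (2.0 * np.sqrt(np.maximum(gGg, 1e-300))),
                           0.0)
            keff = kappa + kdc
            tau = 1.0 / np.sqrt(4.0 / dt ** 2 + vGv + 3.0 * keff ** 2 * GG)

            # element operator: advection + diffusion + SUPG
            K_el = vols[:, None, None] / nn * adv_b[:, None, :]
            K_el = K_el + (keff * vols)[:, None, None] * BaBb
            K_el = K_el + (tau * vols)[:, None, None] * \
                np.einsum("ma,mb->mab", adv_b, adv_b)
            # SUPG mass: tau (v.grad N_a) N_b / (d+1)
            K_el_m = (tau * vols / nn)[:, None, None] * \
                adv_b[:, :, None] * np.ones((1, 1, nn))
            K = assemble_csr(cells, K_el, n)
            Ms = M + assemble_csr(cells, K_el_m, n)

            A = (Ms / dt + theta * K).tolil()
            rhs = Ms @ phi_old / dt - (1.0 - theta) * (K @ phi_old)
            A[inlet_nodes, :] = 0.0
            A[inlet_nodes, inlet_nodes] = 1.0
            rhs[inlet_nodes] = 0.0
            phi_new = spla.spsolve(A.tocsr().tocsc(), rhs)
        phi = phi_new
        if step % stride == 0:
            times.append(t_new)
            snaps.append(phi.copy())
    return ScalarField(mesh, np.asarray(times), np.asarray(snaps), kappa)


def washout_time(field: ScalarField, threshold_fraction: float = 0.01,
                 horizon: float | None = None) -> WashoutField:
    """Per-node washout time from the dye history.

    t_max is the earliest time of the nodal maximum (plateaus resolve to
    their start); t_1pct is the first subsequent crossing of
    ``threshold_fraction`` times the maximum, linearly interpolated between
    snapshots.  Nodes whose history never crosses are censored at the
    horizon; nodes that never carried dye get T = 0, uncensored.
    """
    if field.n_snapshots < 2:
        raise ValueError("washout needs at least two snapshots")
    t = field.times
    phi = field.phi
    horizon = horizon if horizon is not None else float(t[-1])
    n = phi.shape[1]
    kmax = np.argmax(phi, axis=0)
    vmax = phi[kmax, np.arange(n)]
    t_max = t[kmax]
    thr = threshold_fraction * vmax

    T = np.zeros(n)
    t1 = np.full(n, np.nan)
    censored = np.zeros(n, bool)
    never_dyed = vmax <= 0.0
    for i in np.nonzero(~never_dyed)[0]:
        hist = phi[kmax[i]:, i]
        tt = t[kmax[i]:]
        below = hist <= thr[i]
        if not np.any(below):
            censored[i] = True
            t1[i] = horizon
            T[i] = horizon - t_max[i]
            continue
        k = int(np.argmax(below))
        if k == 0:
            t1[i] = tt[0]
        else:
            f0, f1 = hist[k - 1], hist[k]
            w = (f0 - thr[i]) / max(f0 - f1, 1e-300)
            t1[i] = tt[k - 1] + w * (tt[k] - tt[k - 1])
        T[i] = t1[i] - t_max[i]
    t1[never_dyed] = t_max[never_dyed]
    return WashoutField(field.mesh, T, t_max, t1, censored, horizon,
                        threshold_fraction)


def mean_washout(wf: WashoutField, region: DyeInitRegion) -> MeanWashout:
    """Volume-weighted mean washout time over uncensored nodes of a region.

    The weight of a node is its lumped-mass volume share; the censored
    fraction is reported volume-weighted as well.
    """
    mesh = wf.mesh
    w = P1Basis(mesh.nodes, mesh.cells).lumped_mass()
    inside = region.contains(mesh.nodes)
    if not np.any(inside):
        raise ValueError("region contains no mesh nodes")
    w_in = w[inside]
    cens = wf.censored[inside]
    cens_frac = float(w_in[cens].sum() / w_in.sum())
    keep = ~cens
    if not np.any(keep):
        raise ValueError(f"all nodes censored (fraction {cens_frac:.2f}); "
                         "increase the horizon")
    mean = float(np.sum(w_in[keep] * wf.T[inside][keep]) / w_in[keep].sum())
    return MeanWashout(mean, cens_frac, int(inside.sum()))
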