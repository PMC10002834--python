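"""Flow-solver verification: Poiseuille oracle, BC contracts, symmetry."""
import numpy as np
import pytest

from tcpcflow.flow import (SolverSettings, backflow_traction_correction,
                           boundary_flux, check_mass_conservation,
                           inlet_profile, resistance_outlet_traction,
                           solve_steady, solve_transient)
from tcpcflow.structured import rectangle_mesh
from tcpcflow.synthetic import BCSet, make_bc_set, make_pipe_mesh
from tcpcflow.units import MMHG_TO_DYN_CM2

from conftest import MU, PIPE_D, PIPE_L, PIPE_Q


def _slab_pressure(mesh, p, z, width=0.1):
    w = np.exp(-((mesh.nodes[:, 2] - z) / width) ** 2)
    return float((p * w).sum() / w.sum())


class TestPoiseuille:
    def test_developed_pressure_gradient(self, poiseuille_field):
        mesh = poiseuille_field.mesh
        _, p = poiseuille_field.snapshot()
        dpdz = (_slab_pressure(mesh, p, 2.5)
                - _slab_pressure(mesh, p, 5.5)) / 3.0
        exact = 128 * MU * PIPE_Q / (np.pi * PIPE_D ** 4)
        assert dpdz == pytest.approx(exact, rel=0.10)

    def test_inlet_flux_matches_prescription(self, poiseuille_field):
        mesh = poiseuille_field.mesh
        v, _ = poiseuille_field.snapshot()
        q_in = -boundary_flux(mesh, v, "inlet")
        assert q_in == pytest.approx(PIPE_Q, rel=0.005)

    def test_mass_conservation(self, poiseuille_field):
        imb = check_mass_conservation(poiseuille_field)
        assert np.all(imb < 1e-3)

    def test_steady_matches_long_transient(self, pipe_mesh_medium,
                                           poiseuille_field):
        """Pseudo-transient stationary state equals the time-marched one.

        The time step is chosen large enough that the 4/dt^2 term in tau_M
        is subdominant, so both discretizations share the same
        stabilization in the steady limit."""
        bc = BCSet(inlet_flows={"inlet": PIPE_Q},
                   outlet_resistances={"outlet": 0.0})
        tset = SolverSettings(dt=0.25, t_end=1.5, save_every=0.75)
        ft = solve_transient(pipe_mesh_medium, bc, tset,
                             initial=poiseuille_field.snapshot())
        mesh = pipe_mesh_medium
        dp_s = (_slab_pressure(mesh, poiseuille_field.pressure[-1], 2.5)
                - _slab_pressure(mesh, poiseuille_field.pressure[-1], 5.5))
        dp_t = (_slab_pressure(mesh, ft.pressure[-1], 2.5)
                - _slab_pressure(mesh, ft.pressure[-1], 5.5))
        assert dp_t == pytest.approx(dp_s, rel=0.01)


class TestConvergenceAndStability:
    def test_pressure_gradient_error_decreases_with_h(self):
        """Developed-flow gradient approaches Hagen-Poiseuille under
        refinement (two-mesh error-decrease check at Re = 50)."""
        exact = 128 * MU * PIPE_Q / (np.pi * PIPE_D ** 4)
        errs = []
        for h in (0.45, 0.25):
            mesh = make_pipe_mesh(PIPE_D, PIPE_L, h, n_boundary_layers=1)
            bc = BCSet(inlet_flows={"inlet": PIPE_Q},
                       outlet_resistances={"outlet": 0.0})
            field = solve_steady(mesh, bc)
            _, p = field.snapshot()
            dpdz = (_slab_pressure(mesh, p, 2.5)
                    - _slab_pressure(mesh, p, 5.5)) / 3.0
            errs.append(abs(dpdz - exact) / exact)
        assert errs[1] < errs[0]

    def test_no_pressure_checkerboard(self, poiseuille_field):
        """Equal-order stability: adjacent-element mean pressures vary
        smoothly (jumps bounded by a few local gradient increments)."""
        mesh = poiseuille_field.mesh
        _, p = poiseuille_field.snapshot()
        pbar = p[mesh.cells].mean(axis=1)
        from tcpcflow.mesh import _cell_facets
        faces = np.sort(_cell_facets(mesh.cells, mesh.dim), axis=1)
        owner = np.tile(np.arange(mesh.n_cells), mesh.dim + 1)
        order = np.lexsort(faces.T[::-1])
        faces, owner = faces[order], owner[order]
        shared = np.all(faces[1:] == faces[:-1], axis=1)
        jumps = np.abs(pbar[owner[:-1][shared]] - pbar[owner[1:][shared]])
        assert jumps.max() < 0.05 * np.ptp(p)

    def test_stokes_regime_junction_converges_quickly(
            self, junction_mesh_insert_2d):
        """Creeping flow is linear: few pseudo-steps after the ramp."""
        bc = make_bc_set(0.02)     # Re of order 1
        field = solve_steady(junction_mesh_insert_2d, bc)
        assert field.converged
        assert len(field.residual_history) < 20


class TestTrivialSolutions:
    def test_zero_inflow_gives_zero_field(self):
        mesh = make_pipe_mesh(2.0, 4.0, 0.4)
        bc = BCSet(inlet_flows={"inlet": 0.0},
                   outlet_resistances={"outlet": 100.0})
        field = solve_steady(mesh, bc)
        v, p = field.snapshot()
        assert field.converged
        assert np.abs(v).max() < 1e-10
        assert np.ptp(p) < 1e-6
        # absolute imbalance flagged for zero-inflow audits
        assert check_mass_conservation(field)[0] < 1e-10

    def test_no_slip_on_walls(self, poiseuille_field):
        mesh = poiseuille_field.mesh
        v, _ = poiseuille_field.snapshot()
        wall = mesh.group_nodes("wall")
        assert np.abs(v[wall]).max() < 1e-10


class TestInletProfile:
    def test_parabolic_peak_is_twice_mean(self):
        """Fully developed profile: centerline speed twice the mean.

        Needs a finely resolved patch; the quadrature error of the
        rescaled nodal parabola scales with (h/R)^2."""
        q = 70.0
        mesh = make_pipe_mesh(PIPE_D, 0.6, 0.07)
        nodes, vals = inlet_profile(mesh, "inlet", q, "parabolic")
        area = np.pi * (PIPE_D / 2) ** 2
        peak = np.linalg.norm(vals, axis=1).max()
        assert peak == pytest.approx(2 * q / area, rel=0.005)

    def test_parabolic_vanishes_on_rim(self, pipe_mesh_medium):
        nodes, vals = inlet_profile(pipe_mesh_medium, "inlet", 70.0,
                                    "parabolic")
        r = np.hypot(pipe_mesh_medium.nodes[nodes, 0],
                     pipe_mesh_medium.nodes[nodes, 1])
        rim = r > 0.999 * r.max()
        assert np.abs(vals[rim]).max() < 1e-10

    def test_plug_profile_uniform(self, pipe_mesh_medium):
        nodes, vals = inlet_profile(pipe_mesh_medium, "inlet", 70.0, "plug")
        speeds = np.linalg.norm(vals, axis=1)
        assert np.ptp(speeds) < 1e-9 * speeds.max()

    def test_flux_exact(self, pipe_mesh_medium):
        for kind in ("parabolic", "plug"):
            nodes, vals = inlet_profile(pipe_mesh_medium, "inlet", 70.0, kind)
            full = np.zeros((pipe_mesh_medium.n_nodes, 3))
            full[nodes] = vals
            q = -boundary_flux(pipe_mesh_medium, full, "inlet")
            assert q == pytest.approx(70.0, rel=1e-3)

    def test_zero_flow_zero_profile(self, pipe_mesh_medium):
        _, vals = inlet_profile(pipe_mesh_medium, "inlet", 0.0)
        assert np.abs(vals).max() == 0.0


class TestResistanceOutlet:
    def test_traction_contract(self):
        h = resistance_outlet_traction(204.51, 95.33, np.array([0, 0, 1.0]))
        assert h[2] == pytest.approx(-204.51 * 95.33)

    def test_outlet_pressure_equals_rq(self):
        mesh = make_pipe_mesh(PIPE_D, 4.0, 0.3)
        R = 204.51
        bc = BCSet(inlet_flows={"inlet": PIPE_Q},
                   outlet_resistances={"outlet": R})
        field = solve_steady(mesh, bc)
        v, p = field.snapshot()
        q_out = boundary_flux(mesh, v, "outlet")
        p_out = p[mesh.group_nodes("outlet")].mean()
        assert p_out == pytest.approx(R * q_out, rel=0.01)

    def test_doubling_r_doubles_outlet_pressure(self):
        mesh = make_pipe_mesh(PIPE_D, 4.0, 0.4)
        outs = {}
        for R in (100.0, 200.0):
            bc = BCSet(inlet_flows={"inlet": PIPE_Q},
                       outlet_resistances={"outlet": R})
            field = solve_steady(mesh, bc)
            _, p = field.snapshot()
            outs[R] = p[mesh.group_nodes("outlet")].mean()
        assert outs[200.0] == pytest.approx(2 * outs[100.0], rel=0.01)


class TestBackflowStabilization:
    def test_forward_flow_inactive(self):
        v = np.array([[1.0, 0.0], [2.0, 0.5]])
        n = np.array([[1.0, 0.0], [1.0, 0.0]])
        corr = backflow_traction_correction(v, n, beta=0.2, rho=1.06)
        assert np.all(corr == 0.0)

    def test_reversed_patch_opposes_velocity(self):
        v = np.array([[-3.0, 1.0]])
        n = np.array([[1.0, 0.0]])
        corr = backflow_traction_correction(v, n, beta=0.2, rho=1.06)
        # added traction is anti-parallel to the reversed velocity
        assert np.dot(corr[0], v[0]) < 0

    def test_beta_zero_no_correction(self):
        v = np.array([[-3.0, 1.0]])
        n = np.array([[1.0, 0.0]])
        assert np.all(backflow_traction_correction(v, n, 0.0, 1.06) == 0.0)


class TestJunctionFlow:
    def test_symmetric_junction_splits_evenly(self, junction_mesh_blank):
        """Equal outlet resistances on the mirror-symmetric housing."""
        bc = make_bc_set(3.0, r_rpa=210.0, r_lpa=210.0)
        field = solve_steady(junction_mesh_blank, bc)
        v, _ = field.snapshot()
        qr = boundary_flux(junction_mesh_blank, v, "outlet_RPA")
        ql = boundary_flux(junction_mesh_blank, v, "outlet_LPA")
        assert 100 * qr / (qr + ql) == pytest.approx(50.0, abs=0.5)

    def test_junction_mass_conservation(self, insert_field_co7):
        assert check_mass_conservation(insert_field_co7)[0] < 5e-3

    def test_insert_outlet_pressures_match_rq(self, insert_field_co7):
        mesh = insert_field_co7.mesh
        v, p = insert_field_co7.snapshot()
        for g, R in (("outlet_RPA", 204.51), ("outlet_LPA", 222.49)):
            q = boundary_flux(mesh, v, g)
            p_out = p[mesh.group_nodes(g)].mean()
            assert p_out == pytest.approx(R * q, rel=0.01)
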