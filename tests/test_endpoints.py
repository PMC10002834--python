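"""Endpoint extraction: traction projection, TAWSS/OSI, planes, budgets."""
import numpy as np
import pytest

from tcpcflow.endpoints import (CutPlane, WallTractionSeries,
                                cut_plane_pressure, flow_split,
                                low_wss_area_fraction, mean_over_group, osi,
                                power_loss, pressure_loss,
                                pressure_loss_matrix, tawss, wall_traction)
from tcpcflow.flow import FlowField
from tcpcflow.structured import rectangle_mesh
from tcpcflow.units import MMHG_TO_DYN_CM2

from conftest import MU, PIPE_D, PIPE_L, PIPE_Q


def _series(times, traction):
    """Synthetic single-node traction series (3D vectors)."""
    times = np.asarray(times, float)
    traction = np.asarray(traction, float)[:, None, :]
    mesh = rectangle_mesh(1.0, 1.0, 2, 2)
    return WallTractionSeries(mesh, ("wall",), np.array([0]),
                              np.array([[0.0, 0.0, 1.0]]), times, traction)


class TestWallTraction:
    def test_poiseuille_wall_shear(self, poiseuille_field):
        series = wall_traction(poiseuille_field, ["wall"])
        mesh = poiseuille_field.mesh
        z = mesh.nodes[series.nodes][:, 2]
        mid = (z > 2.0) & (z < 6.0)
        mag = np.linalg.norm(series.traction[-1], axis=1)
        exact = 32 * MU * PIPE_Q / (np.pi * PIPE_D ** 3)
        assert np.mean(mag[mid]) == pytest.approx(exact, rel=0.10)

    def test_traction_is_tangential(self, poiseuille_field):
        series = wall_traction(poiseuille_field, ["wall"])
        dots = np.einsum("ni,ni->n", series.traction[-1], series.normals)
        assert np.abs(dots).max() < 1e-9

    def test_zero_flow_zero_traction(self, pipe_mesh_medium):
        n = pipe_mesh_medium.n_nodes
        field = FlowField(pipe_mesh_medium, np.array([0.0]),
                          np.zeros((1, n, 3)), np.zeros((1, n)),
                          fluid=__import__("tcpcflow.synthetic",
                                           fromlist=["BLOOD_ANALOG"]).BLOOD_ANALOG)
        series = wall_traction(field, ["wall"])
        assert np.abs(series.traction).max() == 0.0

    def test_hydrostatic_pressure_has_no_tangential_part(self,
                                                         pipe_mesh_medium):
        from tcpcflow.synthetic import BLOOD_ANALOG
        n = pipe_mesh_medium.n_nodes
        field = FlowField(pipe_mesh_medium, np.array([0.0]),
                          np.zeros((1, n, 3)),
                          np.full((1, n), 1234.5), fluid=BLOOD_ANALOG)
        series = wall_traction(field, ["wall"])
        assert np.abs(series.traction).max() < 1e-9

    def test_missing_group_raises(self, poiseuille_field):
        with pytest.raises(KeyError):
            wall_traction(poiseuille_field, ["wall_rotor"])


class TestTawssOsi:
    def test_steady_traction(self):
        s = _series([0.0, 1.0], [[3.0, 0, 0], [3.0, 0, 0]])
        assert tawss(s)[0] == pytest.approx(3.0)
        assert osi(s)[0] == 0.0

    def test_full_reversal_cancels(self):
        s = _series([0.0, 0.5, 1.0],
                    [[2.0, 0, 0], [-2.0, 0, 0], [2.0, 0, 0]])
        assert tawss(s)[0] == pytest.approx(0.0, abs=1e-12)
        assert osi(s)[0] == pytest.approx(0.5)

    def test_orthogonal_snapshots_vector_mean(self):
        s = _series([0.0, 1.0], [[2.0, 0, 0], [0.0, 2.0, 0]])
        assert tawss(s)[0] == pytest.approx(np.sqrt(2.0))

    def test_collinear_unequal_magnitudes_zero_osi(self):
        s = _series([0.0, 0.5, 1.0],
                    [[2.0, 0, 0], [2.0, 0, 0], [1.0, 0, 0]])
        assert osi(s)[0] == pytest.approx(0.0, abs=1e-12)

    def test_osi_bounds_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        tr = rng.normal(size=(20, 1, 3))
        s = _series(np.linspace(0, 1, 20), tr[:, 0, :])
        o = osi(s)
        assert 0.0 <= o[0] <= 0.5
        t = np.linspace(0, 1, 20)
        mean_mag = np.trapezoid(np.linalg.norm(tr[:, 0, :], axis=1), t)
        assert tawss(s)[0] <= mean_mag / (t[-1] - t[0]) + 1e-12

    def test_empty_window_raises(self):
        s = _series([0.0, 1.0], [[1, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            tawss(s, window=(5.0, 6.0))


class TestLowWss:
    def _uniform_series(self, mesh, group="wall"):
        faces = mesh.group_faces(group)
        nodes, normals = mesh.node_normals(faces)
        return WallTractionSeries(mesh, (group,), nodes, normals,
                                  np.array([0.0]),
                                  np.zeros((1, nodes.size, mesh.dim)))

    def test_uniform_above_threshold(self, pipe_mesh_medium):
        s = self._uniform_series(pipe_mesh_medium)
        vals = np.full(s.nodes.size, 10.0)
        assert low_wss_area_fraction(s, vals, "wall", 5.0) == 0.0

    def test_uniform_below_threshold(self, pipe_mesh_medium):
        s = self._uniform_series(pipe_mesh_medium)
        vals = np.full(s.nodes.size, 1.0)
        assert low_wss_area_fraction(s, vals, "wall", 5.0) == 1.0

    def test_half_below(self, pipe_mesh_medium):
        s = self._uniform_series(pipe_mesh_medium)
        z = pipe_mesh_medium.nodes[s.nodes][:, 2]
        vals = np.where(z < PIPE_L / 2, 1.0, 10.0)
        frac = low_wss_area_fraction(s, vals, "wall", 5.0)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_monotone_in_threshold(self, pipe_mesh_medium):
        s = self._uniform_series(pipe_mesh_medium)
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, s.nodes.size)
        fracs = [low_wss_area_fraction(s, vals, "wall", thr)
                 for thr in (1.0, 3.0, 5.0, 8.0)]
        assert np.all(np.diff(fracs) >= 0)


class _AxialPlane:
    """Cut plane normal to the pipe axis at a given z."""

    def __init__(self, z):
        self.z = z

    def origin_normal(self, dim):
        o = np.zeros(dim)
        o[2] = self.z
        n = np.zeros(dim)
        n[2] = 1.0
        return o, n


class TestCutPlanes:
    def test_uniform_pressure_unit_conversion(self, pipe_mesh_medium):
        n = pipe_mesh_medium.n_nodes
        field = FlowField(pipe_mesh_medium, np.array([0.0]),
                          np.zeros((1, n, 3)),
                          np.full((1, n), MMHG_TO_DYN_CM2))
        assert cut_plane_pressure(field, _AxialPlane(4.0)) == \
            pytest.approx(1.0, rel=1e-9)

    def test_poiseuille_gradient_between_planes(self, poiseuille_field):
        p1 = cut_plane_pressure(poiseuille_field, _AxialPlane(2.0))
        p2 = cut_plane_pressure(poiseuille_field, _AxialPlane(6.0))
        exact = 128 * MU * PIPE_Q * 4.0 / (np.pi * PIPE_D ** 4)
        assert (p1 - p2) * MMHG_TO_DYN_CM2 == pytest.approx(exact, rel=0.10)

    def test_identical_planes_zero_loss_and_antisymmetry(self,
                                                        poiseuille_field):
        a, b = _AxialPlane(3.0), _AxialPlane(5.0)
        assert pressure_loss(poiseuille_field, a, a) == 0.0
        assert pressure_loss(poiseuille_field, a, b) == \
            pytest.approx(-pressure_loss(poiseuille_field, b, a))

    def test_plane_outside_mesh_raises(self, poiseuille_field):
        with pytest.raises(ValueError):
            cut_plane_pressure(poiseuille_field, _AxialPlane(50.0))


class TestPortBudgets:
    def test_flow_split_matches_resistance_divider(self, insert_field_co7):
        """0D oracle: split set by the two outlet resistances."""
        split = flow_split(insert_field_co7)
        oracle = 100.0 * 222.49 / (204.51 + 222.49)
        assert split == pytest.approx(oracle, abs=1.0)

    def test_power_loss_positive_and_near_dpq(self, poiseuille_field):
        pl = power_loss(poiseuille_field)
        dp = 128 * MU * PIPE_Q * PIPE_L / (np.pi * PIPE_D ** 4)
        assert pl == pytest.approx(dp * PIPE_Q * 1e-4, rel=0.10)
        assert pl > 0

    def test_zero_flow_zero_power(self, pipe_mesh_medium):
        from tcpcflow.synthetic import BLOOD_ANALOG
        n = pipe_mesh_medium.n_nodes
        field = FlowField(pipe_mesh_medium, np.array([0.0]),
                          np.zeros((1, n, 3)), np.zeros((1, n)),
                          fluid=BLOOD_ANALOG)
        assert power_loss(field) == 0.0

    def test_junction_dp_pairs_and_max(self, insert_field_co7):
        pairs, dp_max = pressure_loss_matrix(insert_field_co7, 4.0)
        assert set(pairs) == {"IVC_RPA", "IVC_LPA", "SVC_RPA", "SVC_LPA"}
        assert dp_max == pytest.approx(max(pairs.values()))
        assert dp_max > 0
        # second-law audit: the converged junction flow dissipates energy
        assert power_loss(insert_field_co7) > 0


class TestStokesScaling:
    def test_losses_scale_linearly_with_viscosity(self):
        """Stokes regime: dP and power loss proportional to mu at fixed Q."""
        from tcpcflow.flow import solve_steady
        from tcpcflow.synthetic import BCSet, FluidProperties, make_pipe_mesh
        mesh = make_pipe_mesh(2.0, 6.0, 0.4)
        q = 0.05       # deep Stokes regime for both viscosities
        results = {}
        for mu in (0.035, 0.14):
            bc = BCSet(inlet_flows={"inlet": q},
                       outlet_resistances={"outlet": 0.0},
                       fluid=FluidProperties(1.06, mu))
            field = solve_steady(mesh, bc)
            results[mu] = (pressure_loss(field, _AxialPlane(1.0),
                                         _AxialPlane(5.0)),
                           power_loss(field))
        for k in (0, 1):
            ratio = results[0.14][k] / results[0.035][k]
            assert ratio == pytest.approx(4.0, rel=0.05)
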