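"""Dye transport oracles and washout-time bookkeeping."""
import numpy as np
import pytest

from tcpcflow.dye import (DyeInitRegion, ScalarField, advance_scalar,
                          init_dye, mean_washout, washout_time)
from tcpcflow.flow import FlowField
from tcpcflow.structured import rectangle_mesh


def _uniform_flow(mesh, u):
    n = mesh.n_nodes
    v = np.zeros((n, mesh.dim))
    v[:, 0] = u
    return FlowField(mesh, np.array([0.0]), v[None],
                     np.zeros((1, n)))


class TestInitDye:
    def test_cube_initialization(self, junction_mesh_insert):
        mesh = junction_mesh_insert
        region = DyeInitRegion(center=(0, 0, 0), edge=3.5)
        f = init_dye(mesh, region)
        inside = region.contains(mesh.nodes)
        assert np.all(f.phi[0][inside] == 1.0)
        far = np.abs(mesh.nodes[:, 0]) > 4.0
        assert np.all(f.phi[0][far] == 0.0)

    def test_region_larger_than_domain(self):
        mesh = rectangle_mesh(1.0, 1.0, 4, 4)
        f = init_dye(mesh, DyeInitRegion(center=(0.5, 0.5), edge=10.0))
        assert np.all(f.phi[0] == 1.0)

    def test_degenerate_region_yields_empty_field(self):
        mesh = rectangle_mesh(1.0, 1.0, 4, 4)
        f = init_dye(mesh, DyeInitRegion(center=(0.33, 0.21), edge=0.0))
        assert np.all(f.phi == 0.0)


class TestAdvanceScalar:
    def test_advected_front_position(self):
        """Method of characteristics: a step travels at the flow speed."""
        mesh = rectangle_mesh(6.0, 0.5, 120, 10)
        flow = _uniform_flow(mesh, 10.0)
        f0 = init_dye(mesh, DyeInitRegion(center=(0.5, 0.25), edge=1.0),
                      kappa=1e-6)
        sf = advance_scalar(f0, flow, t_end=0.2, dt=0.004, theta=0.6)
        line = np.abs(mesh.nodes[:, 1] - 0.25) < 1e-9
        xs, ph = mesh.nodes[line, 0], sf.phi[-1][line]
        o = np.argsort(xs)
        xs, ph = xs[o], ph[o]
        cross = np.nonzero((ph[:-1] >= 0.5) & (ph[1:] < 0.5))[0]
        # trailing edge started at 1.0, after 0.2 s at 10 cm/s -> 3.0 cm
        assert abs(xs[cross[-1]] - 3.0) < 0.05  # one element width

    def test_no_transport_leaves_field_unchanged(self):
        mesh = rectangle_mesh(2.0, 0.5, 20, 5,
                              labels={"left": "wall", "right": "wall"})
        flow = _uniform_flow(mesh, 0.0)
        f0 = init_dye(mesh, DyeInitRegion(center=(1.0, 0.25), edge=0.6),
                      kappa=0.0)
        sf = advance_scalar(f0, flow, t_end=0.1, dt=0.02)
        assert np.abs(sf.phi[-1] - sf.phi[0]).max() < 1e-12

    def test_gaussian_diffusion_oracle(self):
        """Heat-kernel spreading: sigma^2(t) = sigma0^2 + 2 kappa t."""
        kappa, sig0 = 0.05, 0.3
        mesh = rectangle_mesh(6.0, 0.5, 120, 10,
                              labels={"left": "wall", "right": "wall"})
        n = mesh.n_nodes
        flow = _uniform_flow(mesh, 0.0)
        phi0 = np.exp(-((mesh.nodes[:, 0] - 3.0) ** 2) / (2 * sig0 ** 2))
        f0 = ScalarField(mesh, np.array([0.0]), phi0[None], kappa)
        sf = advance_scalar(f0, flow, t_end=0.5, dt=0.005, theta=0.5)
        line = np.abs(mesh.nodes[:, 1] - 0.25) < 1e-9
        xx, pp = mesh.nodes[line, 0], sf.phi[-1][line]
        mu = (xx * pp).sum() / pp.sum()
        var = ((xx - mu) ** 2 * pp).sum() / pp.sum()
        assert var == pytest.approx(sig0 ** 2 + 2 * kappa * 0.5, rel=0.02)
        # L2 agreement with the closed-form solution
        sig2 = sig0 ** 2 + 2 * kappa * 0.5
        exact = sig0 / np.sqrt(sig2) * np.exp(-((xx - 3.0) ** 2) / (2 * sig2))
        assert np.linalg.norm(pp - exact) < 0.02 * np.linalg.norm(exact)

    def test_boundedness_and_outflow_monotonicity(self, insert_washout_co3):
        """On the study case, dye stays within [-0.05, 1.05] and the total
        dye content never grows between snapshots."""
        _, sf, _ = insert_washout_co3
        assert sf.phi.min() >= -0.05
        assert sf.phi.max() <= 1.05
        total = sf.total_dye()
        assert np.all(np.diff(total) <= 5e-3 * total[0])


class TestWashoutTime:
    def test_linear_decay_crossing(self):
        """phi(t) = max(0, 1 - t) crosses 1% of max at t = 0.99 s."""
        mesh = rectangle_mesh(1.0, 1.0, 2, 2)
        t = np.linspace(0.0, 1.2, 61)
        phi = np.tile(np.maximum(0.0, 1.0 - t)[:, None], (1, mesh.n_nodes))
        wf = washout_time(ScalarField(mesh, t, phi))
        assert wf.T == pytest.approx(0.99, abs=1e-6)
        assert not wf.censored.any()

    def test_constant_history_censored(self):
        mesh = rectangle_mesh(1.0, 1.0, 2, 2)
        t = np.linspace(0.0, 5.0, 11)
        phi = np.ones((11, mesh.n_nodes))
        wf = washout_time(ScalarField(mesh, t, phi))
        assert wf.censored.all()
        assert np.all(wf.T == 5.0)

    def test_never_dyed_node_has_zero_washout(self):
        mesh = rectangle_mesh(1.0, 1.0, 2, 2)
        t = np.linspace(0.0, 1.0, 6)
        phi = np.zeros((6, mesh.n_nodes))
        wf = washout_time(ScalarField(mesh, t, phi))
        assert np.all(wf.T == 0.0)
        assert not wf.censored.any()

    def test_plateau_resolves_to_earliest_maximum(self):
        mesh = rectangle_mesh(1.0, 1.0, 2, 2)
        t = np.array([0.0, 1.0, 2.0, 3.0])
        hist = np.array([1.0, 1.0, 0.5, 0.0])
        phi = np.tile(hist[:, None], (1, mesh.n_nodes))
        wf = washout_time(ScalarField(mesh, t, phi))
        assert np.all(wf.t_max == 0.0)


class TestMeanWashout:
    def _wf(self, mesh, T, censored=None):
        n = mesh.n_nodes
        from tcpcflow.dye import WashoutField
        c = np.zeros(n, bool) if censored is None else censored
        return WashoutField(mesh, T, np.zeros(n), T, c, horizon=5.0)

    def test_uniform_field(self):
        mesh = rectangle_mesh(1.0, 1.0, 4, 4)
        wf = self._wf(mesh, np.full(mesh.n_nodes, 0.5))
        mw = mean_washout(wf, DyeInitRegion(center=(0.5, 0.5), edge=2.0))
        assert mw.mean_s == pytest.approx(0.5)

    def test_two_level_mean(self):
        """Equal-volume halves at 0.2 and 0.6 s average to 0.4 s."""
        mesh = rectangle_mesh(2.0, 1.0, 8, 4)
        x = mesh.nodes[:, 0]
        T = np.where(x < 1.0 - 1e-9, 0.2, 0.6)
        T[np.abs(x - 1.0) < 1e-9] = 0.4   # shared mid-line column
        wf = self._wf(mesh, T)
        mw = mean_washout(wf, DyeInitRegion(center=(1.0, 0.5), edge=4.0))
        assert mw.mean_s == pytest.approx(0.4, abs=1e-12)

    def test_all_censored_raises(self):
        mesh = rectangle_mesh(1.0, 1.0, 4, 4)
        wf = self._wf(mesh, np.ones(mesh.n_nodes),
                      censored=np.ones(mesh.n_nodes, bool))
        with pytest.raises(ValueError, match="censored"):
            mean_washout(wf, DyeInitRegion(center=(0.5, 0.5), edge=2.0))

    def test_plug_flow_transit_oracle(self):
        """Mean washout of a slab in plug flow = (edge/2)/U + front width."""
        mesh = rectangle_mesh(6.0, 0.5, 240, 8)
        flow = _uniform_flow(mesh, 10.0)
        region = DyeInitRegion(center=(0.5, 0.25), edge=1.0)
        f0 = init_dye(mesh, region, kappa=1e-6)
        sf = advance_scalar(f0, flow, t_end=0.5, dt=0.002, theta=0.5)
        mw = mean_washout(washout_time(sf), region)
        assert mw.mean_s == pytest.approx(0.05, rel=0.30)
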