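"""Mesh generation audits: structure, watertightness, labels, symmetry."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

from tcpcflow.geometry import JunctionGeometryParams
from tcpcflow.synthetic import make_junction_mesh, make_pipe_mesh
from tcpcflow.distmesh import MeshingError


class TestPipeMesh:
    def test_boundary_area_matches_cylinder(self):
        D, L = 1.91, 10.0
        mesh = make_pipe_mesh(D, L, 0.3)
        area = sum(mesh.group_area(g) for g in mesh.group_names())
        exact = 2 * np.pi * (D / 2) ** 2 + np.pi * D * L
        assert area == pytest.approx(exact, rel=0.05)

    def test_boundary_surface_is_topological_sphere(self):
        mesh = make_pipe_mesh(1.91, 10.0, 0.3)
        assert mesh.boundary_euler_characteristic() == 2
        assert mesh.is_watertight()

    def test_quality_with_boundary_layers(self):
        mesh = make_pipe_mesh(2.0, 4.0, 0.5, n_boundary_layers=2)
        q = mesh.quality()
        assert q.min_volume > 0
        assert q.min_dihedral_deg > 5.0

    def test_boundary_layer_grading(self):
        """Wall-adjacent radial spacing thins by the configured ratio."""
        mesh = make_pipe_mesh(2.0, 4.0, 0.5, n_boundary_layers=2,
                              layer_ratio=0.5)
        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        radii = np.unique(np.round(r, 6))
        gaps = np.diff(radii)[-2:]
        # outermost gap half of the one before it
        assert gaps[1] == pytest.approx(0.5 * gaps[0], rel=0.05)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            make_pipe_mesh(-1.0, 4.0, 0.5)
        with pytest.raises(MeshingError):
            make_pipe_mesh(0.4, 4.0, 0.5, n_boundary_layers=6)


class TestJunctionMesh:
    def test_blank_has_six_groups_without_insert_labels(self,
                                                        junction_mesh_blank):
        groups = junction_mesh_blank.group_names()
        assert len(groups) == 5  # 4 ports + housing wall (no secondary path)
        assert "wall_rotor" not in groups
        assert "wall_strut" not in groups

    def test_insert_adds_rotor_and_strut_walls(self, junction_mesh_insert):
        groups = junction_mesh_insert.group_names()
        assert "wall_rotor" in groups
        assert "wall_strut" in groups

    def test_audits_hold_across_parameter_sweep(self):
        rng = np.random.default_rng(7)
        for k in range(3):
            params = JunctionGeometryParams(
                insert_kind=("none", "bicone")[k % 2],
                bicone_equator_diameter=float(rng.uniform(2.0, 2.6)),
                arm_length=float(rng.uniform(4.5, 5.5)),
            )
            mesh = make_junction_mesh(params, 0.45, seed=k)
            mesh.validate()           # positive volumes + watertight
            assert np.all(mesh.cell_volumes() > 0)
            counts = {g: len(mesh.group_faces(g))
                      for g in mesh.group_names()}
            assert sum(counts.values()) == mesh.boundary_faces.shape[0]

    def test_rotor_wetted_area_grows_with_blade_height(self):
        areas = {}
        for bh in (0.109, 0.162):
            params = JunctionGeometryParams(insert_kind="bicone",
                                            blade_height=bh)
            mesh = make_junction_mesh(params, 0.3, seed=0)
            areas[bh] = mesh.group_area("wall_rotor")
        assert areas[0.162] > areas[0.109]

    def test_mirror_symmetry_of_blank_junction(self, junction_mesh_blank):
        """Reflection swapping RPA/LPA maps nodes onto nodes within h."""
        mesh = junction_mesh_blank
        reflected = mesh.nodes.copy()
        reflected[:, 0] *= -1
        d, _ = cKDTree(mesh.nodes).query(reflected)
        assert d.max() < 0.35  # the target element size
        rpa = mesh.group_area("outlet_RPA")
        lpa = mesh.group_area("outlet_LPA")
        assert rpa == pytest.approx(lpa, rel=0.01)

    def test_oversized_insert_rejected(self):
        with pytest.raises(ValueError, match="fit|gap"):
            JunctionGeometryParams(insert_kind="bicone",
                                   bicone_equator_diameter=3.4)

    def test_2d_mode(self, junction_mesh_insert_2d):
        mesh = junction_mesh_insert_2d
        assert mesh.dim == 2
        assert mesh.is_watertight()
        assert "wall_rotor" in mesh.group_names()
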