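"""Shared fixtures: meshes and solved flow fields reused across test modules.

Everything here is generated at session scope so expensive solves (the
stabilized 3D junction cases) run once and feed many assertions.
"""
from __future__ import annotations

import numpy as np
import pytest

from tcpcflow.geometry import JunctionGeometryParams
from tcpcflow.synthetic import (BCSet, make_bc_set, make_junction_mesh,
                                make_pipe_mesh)
from tcpcflow.flow import SolverSettings, solve_steady

# Poiseuille verification condition: Re = 50 in the bench tube
PIPE_D = 1.91
PIPE_L = 8.0
RHO, MU = 1.06, 0.035
PIPE_RE = 50.0
PIPE_Q = PIPE_RE * np.pi * PIPE_D * MU / (4.0 * RHO)


@pytest.fixture(scope="session")
def pipe_mesh_medium():
    return make_pipe_mesh(PIPE_D, PIPE_L, 0.25, n_boundary_layers=1)


@pytest.fixture(scope="session")
def poiseuille_field(pipe_mesh_medium):
    bc = BCSet(inlet_flows={"inlet": PIPE_Q},
               outlet_resistances={"outlet": 0.0})
    field = solve_steady(pipe_mesh_medium, bc)
    assert field.converged
    return field


@pytest.fixture(scope="session")
def junction_mesh_blank():
    return make_junction_mesh(JunctionGeometryParams(), 0.35)


@pytest.fixture(scope="session")
def junction_mesh_insert():
    return make_junction_mesh(
        JunctionGeometryParams(insert_kind="bicone"), 0.35)


@pytest.fixture(scope="session")
def insert_field_co7(junction_mesh_insert):
    field = solve_steady(junction_mesh_insert, make_bc_set(7.0))
    assert field.converged
    return field


@pytest.fixture(scope="session")
def junction_mesh_insert_2d():
    return make_junction_mesh(
        JunctionGeometryParams(insert_kind="bicone"), 0.12, dim=2)


@pytest.fixture(scope="session")
def co3_field_2d(junction_mesh_insert_2d):
    field = solve_steady(junction_mesh_insert_2d, make_bc_set(3.0))
    assert field.converged
    return field


@pytest.fixture(scope="session")
def insert_washout_co3(junction_mesh_insert):
    """Full washout computation for the insert model at CO = 3 L/min:
    frozen steady velocity, 3.5 cm dye cube, 5 s horizon."""
    from tcpcflow.dye import DyeInitRegion, advance_scalar, init_dye
    mesh = junction_mesh_insert
    field = solve_steady(mesh, make_bc_set(3.0))
    assert field.converged
    region = DyeInitRegion(center=(0.0, 0.0, 0.0), edge=3.5)
    f0 = init_dye(mesh, region, kappa=1e-4)
    scalar = advance_scalar(f0, field, t_end=5.0, dt=0.02)
    return field, scalar, region
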