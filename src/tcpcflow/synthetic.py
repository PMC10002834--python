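"""Synthetic study inputs: meshes, operating points, and mock-loop data.

Everything the pipeline consumes is generated here — parametric junction and
pipe meshes, boundary-condition sets mirroring the bench mock circulatory
loop (MCL) operating points, and synthetic paired "simulated vs measured"
pressure-loss datasets for the agreement statistics — so no external data is
ever required.

Operating-point conventions (bench rig values):
cardiac output CO in {3, 5, 7, 9, 11} L/min, IVC/SVC split 60/40, blood
analog with density 1.06 g/cm^3 and viscosity 0.035 P, RPA/LPA outlet
resistances 204.51 and 222.49 dyn.s/cm^5, and pulmonary pressure-flow
relations 6.0 + 0.74*CO (RPA) and 6.0 + 0.77*CO (LPA) mmHg.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distmesh import distmesh
from .geometry import JunctionGeometry, JunctionGeometryParams
from .mesh import SimplicialMesh, build_mesh
from .structured import pipe_mesh as _structured_pipe_mesh
from .units import L_PER_MIN_TO_CM3_PER_S

__all__ = [
    "FluidProperties", "BCSet", "MCLDataset", "BLOOD_ANALOG",
    "R_RPA_DEFAULT", "R_LPA_DEFAULT", "CO_SWEEP_L_MIN",
    "make_pipe_mesh", "make_junction_mesh", "make_bc_set",
    "reynolds_number", "mcl_target_pa_pressure", "synth_mcl_measurements",
]

#: printed outlet resistances, dyn.s/cm^5
R_RPA_DEFAULT = 204.51
R_LPA_DEFAULT = 222.49
#: bench cardiac-output sweep, L/min
CO_SWEEP_L_MIN = (3.0, 5.0, 7.0, 9.0, 11.0)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density in g/cm^3, dynamic viscosity in Poise."""

    density: float = 1.06
    viscosity: float = 0.035

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


BLOOD_ANALOG = FluidProperties()
"""The 40/60 glycerol/water blood analog used on the bench."""


@dataclass
class BCSet:
    """Boundary conditions for one operating point.

    inlet_flows: map inlet group -> volumetric flow (cm^3/s, positive INTO
    the domain); outlet_resistances: map outlet group -> R (dyn.s/cm^5);
    distal_pressure: pressure offset added downstream of every resistance
    (dyn/cm^2); body_force: force density vector (dyn/cm^3).
    """

    inlet_flows: dict[str, float]
    outlet_resistances: dict[str, float]
    fluid: FluidProperties = field(default_factory=FluidProperties)
    inlet_profile: str = "parabolic"          # {"parabolic", "plug"}
    distal_pressure: float = 0.0
    body_force: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.inlet_flows.values()):
            raise ValueError("inlet flows must be non-negative")
        if any(r < 0 for r in self.outlet_resistances.values()):
            raise ValueError("outlet resistances must be non-negative")
        if self.inlet_profile not in ("parabolic", "plug"):
            raise ValueError(f"unknown inlet_profile {self.inlet_profile!r}")

    @property
    def total_inflow(self) -> float:
        return float(sum(self.inlet_flows.values()))


@dataclass
class MCLDataset:
    """Synthetic paired pressure-loss measurements (one row per case).

    ``table`` columns: case_id, CO_L_min, model, dP_mmHg, source.
    """

    table: pd.DataFrame
    noise_sd: float
    bias: float
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, noise_sd=np.nan, bias=np.nan, seed=-1) -> "MCLDataset":
        return cls(pd.read_csv(path), noise_sd, bias, seed)


# ------------------------------------------------------------------- meshes

def make_pipe_mesh(diameter: float, length: float, target_h: float,
                   n_boundary_layers: int = 0,
                   layer_ratio: float = 0.5) -> SimplicialMesh:
    """Structured tetrahedral pipe with groups {inlet, outlet, wall}.

    Boundary layers thin geometrically toward the wall: the n-th innermost
    layer has thickness ``layer_ratio**n * target_h``.
    """
    return _structured_pipe_mesh(diameter, length, target_h,
                                 n_boundary_layers, layer_ratio)


def make_junction_mesh(params: JunctionGeometryParams, target_h: float,
                       dim: int = 3, seed: int = 0,
                       max_iter: int = 120) -> SimplicialMesh:
    """Mesh the four-port junction (optionally with the bicone insert).

    ``target_h`` is the far-field element size; with an insert present the
    mesh refines towards the rotor/strut surfaces by the geometry's
    ``REFINE_RATIO``.  Deterministic for fixed ``seed``.
    """
    if target_h <= 0:
        raise ValueError("target_h must be positive")
    geo = JunctionGeometry(params, dim=dim)
    h_fine = target_h / (geo.REFINE_RATIO if params.insert_kind == "bicone"
                         else 1.0)
    pts, cells = distmesh(geo.sdf, lambda p: geo.size_field(p, h_fine),
                          h_fine, geo.bbox(),
                          pfix=geo.port_fixed_points(h_fine),
                          seed=seed, max_iter=max_iter)
    mesh = build_mesh(pts, cells, geo.label_faces)
    mesh.validate()
    return mesh


# ---------------------------------------------------------- operating point

def make_bc_set(co_l_min: float, ivc_fraction: float = 0.6,
                r_rpa: float = R_RPA_DEFAULT, r_lpa: float = R_LPA_DEFAULT,
                fluid: FluidProperties = BLOOD_ANALOG,
                distal_pressure: float = 0.0,
                inlet_profile: str = "parabolic") -> BCSet:
    """Boundary-condition set for a cardiac output and caval split.

    Flow partition: IVC carries ``ivc_fraction`` of CO, SVC the remainder,
    both converted to cm^3/s.
    """
    if co_l_min <= 0:
        raise ValueError("cardiac output must be positive")
    if not 0.0 < ivc_fraction < 1.0:
        raise ValueError("ivc_fraction must lie strictly between 0 and 1")
    q_total = co_l_min * L_PER_MIN_TO_CM3_PER_S
    return BCSet(
        inlet_flows={"inlet_IVC": ivc_fraction * q_total,
                     "inlet_SVC": (1.0 - ivc_fraction) * q_total},
        outlet_resistances={"outlet_RPA": r_rpa, "outlet_LPA": r_lpa},
        fluid=fluid,
        inlet_profile=inlet_profile,
        distal_pressure=distal_pressure,
    )


def reynolds_number(bc: BCSet, diameter: float, inlet: str) -> float:
    """Tube Reynolds number Re = 4 rho Q / (pi D mu) for one inlet."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if inlet not in bc.inlet_flows:
        raise KeyError(f"inlet {inlet!r} not in BC set")
    q = bc.inlet_flows[inlet]
    return 4.0 * bc.fluid.density * q / (np.pi * diameter * bc.fluid.viscosity)


def mcl_target_pa_pressure(co_l_min: float, side: str) -> float:
    """Bench pulmonary-artery pressure target (mmHg) at a cardiac output.

    The rig's pulmonary impedance networks impose 6.0 + 0.74*CO mmHg on the
    RPA and 6.0 + 0.77*CO mmHg on the LPA.
    """
    if co_l_min < 0:
        raise ValueError("cardiac output must be non-negative")
    slope = {"RPA": 0.74, "LPA": 0.77}.get(side.upper())
    if slope is None:
        raise ValueError("side must be 'RPA' or 'LPA'")
    return 6.0 + slope * co_l_min


# ------------------------------------------------------------ measurements

def synth_mcl_measurements(model_pressure_losses, bias: float = 0.0,
                           noise_sd: float = 0.0, seed: int = 0,
                           co_l_min=None, model: str = "blank") -> MCLDataset:
    """Synthesize paired bench measurements from model pressure losses.

    measured = model + bias + N(0, noise_sd); reproducible for fixed seed.
    ``model_pressure_losses`` may be a list of mmHg values; ``co_l_min``
    optionally attaches the operating points (defaults to an index).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    losses = np.asarray(list(model_pressure_losses), dtype=float)
    rng = np.random.default_rng(seed)
    measured = losses + bias + (rng.normal(0.0, noise_sd, losses.size)
                                if noise_sd > 0 else 0.0)
    cos = (np.arange(losses.size, dtype=float) if co_l_min is None
           else np.asarray(co_l_min, dtype=float))
    table = pd.DataFrame({
        "case_id": [f"{model}_CO{c:g}" for c in cos],
        "CO_L_min": cos,
        "model": model,
        "dP_mmHg": measured,
        "source": "synthetic_mcl",
    })
    return MCLDataset(table=table, noise_sd=noise_sd, bias=bias, seed=seed)
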