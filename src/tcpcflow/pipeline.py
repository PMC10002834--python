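"""Config-driven orchestration: mesh -> flow -> endpoints -> dye -> stats.

A RunConfig describes one study (geometry family, mesh resolution, the
cardiac-output sweep, solver and dye settings, statistics seeds); run_case
executes a single (CO, model) case, sweep the full grid plus the agreement
analysis against synthetic mock-loop data, and mesh_sensitivity the nested
refinement study at the highest cardiac output.

Protocol: each case first attempts the stationary solve; when the solver
reports genuinely unsteady physics (vortex shedding at high flow, or the
blank housing's impinging caval jets) the case falls back to a transient
continuation window whose snapshots are time-averaged, mirroring the bench
protocol of averaging a quasi-steady transient.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from . import endpoints as ep
from .dye import DyeInitRegion, advance_scalar, init_dye, mean_washout, washout_time
from .flow import FlowField, SolverSettings, solve_steady, solve_transient
from .geometry import JunctionGeometryParams
from .synthetic import (BCSet, FluidProperties, make_bc_set,
                        make_junction_mesh, synth_mcl_measurements)
from .stats import PairedComparison, bland_altman, comparison_table, pearson_r

__all__ = ["RunConfig", "CaseResult", "run_case", "sweep", "mesh_sensitivity",
           "MODEL_GEOMETRIES"]


def MODEL_GEOMETRIES(model: str) -> JunctionGeometryParams:
    """Geometry parameters for a named model variant."""
    presets = {
        "blank": dict(insert_kind="none"),
        "vip109": dict(insert_kind="bicone", blade_height=0.109),
        "vip162": dict(insert_kind="bicone", blade_height=0.162,
                       fillet_edges=True),
    }
    if model not in presets:
        raise ValueError(f"unknown model {model!r}; options {list(presets)}")
    return JunctionGeometryParams(**presets[model])


@dataclass
class RunConfig:
    """Serializable description of one study."""

    dim: int = 3
    target_h: float = 0.35
    mesh_seed: int = 0
    models: tuple = ("blank", "vip162")
    co_sweep: tuple = (3.0, 5.0, 7.0, 9.0, 11.0)
    ivc_fraction: float = 0.6
    r_rpa: float = 204.51
    r_lpa: float = 222.49
    density: float = 1.06
    viscosity: float = 0.035
    solver: SolverSettings = field(default_factory=lambda: SolverSettings(steady_mode=True))
    transient_window: float = 1.2       # fallback averaging window, s
    transient_dt: float = 0.01
    dye_enabled: bool = True
    dye_edge: float = 3.5
    dye_kappa: float = 1e-4
    dye_horizon: float = 5.0
    dye_dt: float = 0.02
    cut_offset: float = 4.0
    wss_threshold: float = 5.0
    mcl_bias: float = 0.23
    mcl_noise_sd: float = 0.15
    seed: int = 0
    output_dir: str | None = None

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["solver"] = dataclasses.asdict(self.solver)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "solver" in d and isinstance(d["solver"], dict):
            d["solver"] = SolverSettings(**d["solver"])
        for k in ("models", "co_sweep"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def fluid(self) -> FluidProperties:
        return FluidProperties(self.density, self.viscosity)

    def bc_for(self, co: float) -> BCSet:
        return make_bc_set(co, self.ivc_fraction, self.r_rpa, self.r_lpa,
                           self.fluid())


@dataclass
class CaseResult:
    report: ep.EndpointReport
    field: FlowField
    manifest: dict
    washout = None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage
        self.cause = exc


def _stage(name, fn, *args, **kw):
    try:
        return fn(*args, **kw)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


def build_mesh_for(config: RunConfig, model: str):
    params = MODEL_GEOMETRIES(model)
    return make_junction_mesh(params, config.target_h, dim=config.dim,
                              seed=config.mesh_seed)


def run_case(config: RunConfig, co: float, model: str,
             mesh=None, verbose: bool = False) -> CaseResult:
    """Run one operating point end to end.

    Returns the endpoint report plus the flow field and a manifest with the
    config hash, mesh quality, and solver residual summary.  Artifacts
    (endpoint CSV row, manifest JSON) are persisted when
    ``config.output_dir`` is set.
    """
    if co <= 0:
        raise ValueError("cardiac output must be positive")
    t_start = time.time()
    case_id = f"{model}_CO{co:g}"
    if mesh is None:
        mesh = _stage("meshing", build_mesh_for, config, model)
    bc = _stage("boundary_conditions", config.bc_for, co)

    field = _stage("flow_solve", solve_steady, mesh, bc, config.solver)
    protocol = "steady"
    if not field.converged and field.status == "unsteady_physics":
        # bench-style protocol: transient continuation + window averaging
        tset = SolverSettings(dt=config.transient_dt,
                              t_end=config.transient_window,
                              save_every=max(config.transient_dt, 0.02),
                              rho_inf=config.solver.rho_inf,
                              backflow_beta=config.solver.backflow_beta)
        field = _stage("transient_fallback", solve_transient, mesh, bc,
                       tset, initial=field.snapshot())
        field.status = "transient_averaged"
        protocol = "transient_averaged"
    elif not field.converged:
        raise StageError("flow_solve",
                         RuntimeError(f"solver stalled: {field.status}"))

    # endpoints are averaged over the settled part of the transient window
    # (the bench protocol averages the back 60% of its quasi-steady run)
    window = None
    if protocol == "transient_averaged":
        window = (0.4 * field.times[-1], field.times[-1])
    report = _stage("endpoints", ep.compute_endpoint_report, field, case_id,
                    co, model, config.cut_offset, window,
                    config.wss_threshold)

    washout = None
    if config.dye_enabled:
        region = DyeInitRegion(center=(0.0,) * config.dim,
                               edge=config.dye_edge)
        f0 = _stage("dye_init", init_dye, mesh, region, config.dye_kappa)
        sf = _stage("dye_transport", advance_scalar, f0, field,
                    t_end=config.dye_horizon, dt=config.dye_dt)
        washout = _stage("washout", washout_time, sf)
        mw = _stage("washout", mean_washout, washout, region)
        report.mean_washout_s = mw.mean_s
        report.washout_censored_fraction = mw.censored_fraction

    quality = mesh.quality().as_dict()
    manifest = {
        "case_id": case_id,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "protocol": protocol,
        "mesh_quality": quality,
        "solver_status": field.status,
        "residual_summary": {
            "n_entries": len(field.residual_history),
            "final": (float(np.ravel(field.residual_history[-1])[-1])
                      if len(field.residual_history) else None),
        },
        "wall_time_s": round(time.time() - t_start, 2),
    }
    if config.output_dir:
        out = Path(config.output_dir) / case_id
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        pd.DataFrame([report.as_row()]).to_csv(out / "endpoints.csv",
                                               index=False)
    res = CaseResult(report, field, manifest)
    res.washout = washout
    return res


def sweep(config: RunConfig, verbose: bool = False) -> dict:
    """Run the full CO x model grid plus the agreement statistics.

    Individual case failures are recorded and skipped; the comparison and
    Bland-Altman stages run on the cases that completed.
    """
    if not config.co_sweep:
        raise ValueError("empty cardiac-output sweep")
    if not config.models:
        raise ValueError("no models configured")
    reports, failures = [], []
    meshes = {m: build_mesh_for(config, m) for m in config.models}
    for model in config.models:
        for co in config.co_sweep:
            try:
                res = run_case(config, co, model, mesh=meshes[model],
                               verbose=verbose)
                reports.append(res.report)
            except StageError as exc:
                failures.append({"model": model, "CO_L_min": co,
                                 "stage": exc.stage, "error": str(exc)})
    frame = ep.reports_to_frame(reports)
    mcl = synth_mcl_measurements(
        frame["dP_max_mmHg"], bias=config.mcl_bias,
        noise_sd=config.mcl_noise_sd, seed=config.seed,
        co_l_min=frame["CO_L_min"])
    mcl.table["model"] = frame["model"].values
    joined, unmatched = comparison_table(frame, mcl)
    pc = PairedComparison(joined["model"] + joined["CO_L_min"].astype(str),
                          joined["dP_cfd_mmHg"], joined["dP_mcl_mmHg"])
    out = {
        "reports": frame,
        "comparison": joined,
        "bland_altman": bland_altman(pc),
        "pearson_r": pearson_r(pc) if len(joined) >= 3 else np.nan,
        "failures": failures,
        "unmatched": unmatched,
    }
    if config.output_dir:
        root = Path(config.output_dir)
        root.mkdir(parents=True, exist_ok=True)
        frame.to_csv(root / "endpoint_reports.csv", index=False)
        joined.to_csv(root / "comparison.csv", index=False)
        (root / "stats_summary.txt").write_text(
            out["bland_altman"].summary()
            + f"\nPearson r = {out['pearson_r']:.4f}\n")
        config.to_yaml(root / "config.yaml")
    return out


def _interp_state(coarse_mesh, fine_mesh, v, p):
    """Nearest-neighbour transfer of a flow state onto a finer mesh."""
    tree = cKDTree(coarse_mesh.nodes)
    _, idx = tree.query(fine_mesh.nodes)
    return v[idx], p[idx]


def mesh_sensitivity(config: RunConfig, levels: int = 3,
                     h_coarsest: float | None = None,
                     model: str = "vip162",
                     co: float | None = None,
                     arm_length: float | None = None,
                     verbose: bool = False) -> pd.DataFrame:
    """Nested mesh refinement study of the pressure loss.

    Runs ``levels`` meshes, each halving the target element size from
    ``h_coarsest``, at the highest configured cardiac output, warm-starting
    each level from the previous solution.  Returns one row per level with
    the pressure loss and the relative difference to the previous level;
    the last row's ``rel_diff_prev_pct`` is the two-finest-levels figure.
    """
    if levels < 2:
        raise ValueError("need at least 2 refinement levels")
    h0 = h_coarsest if h_coarsest is not None else 2.0 * config.target_h
    co = co if co is not None else max(config.co_sweep)
    bc = config.bc_for(co)
    geom = MODEL_GEOMETRIES(model)
    if arm_length is not None:
        # shorter arms (cut planes must still fit) shrink the refinement
        # study's footprint without touching the junction region itself
        geom = dataclasses.replace(geom, arm_length=arm_length)
    rows = []
    prev = None     # (mesh, v, p)
    for lev in range(levels):
        h = h0 / 2 ** lev
        mesh = make_junction_mesh(geom, h,
                                  dim=config.dim, seed=config.mesh_seed)
        initial = None
        if prev is not None:
            initial = _interp_state(prev[0], mesh, prev[1], prev[2])
        field = solve_steady(mesh, bc, config.solver, initial=initial)
        status = field.status
        if not field.converged and field.status == "unsteady_physics":
            tset = SolverSettings(dt=config.transient_dt,
                                  t_end=config.transient_window,
                                  save_every=max(config.transient_dt, 0.02))
            field = solve_transient(mesh, bc, tset, initial=field.snapshot())
            status = "transient_averaged"
        _, dp_max = ep.pressure_loss_matrix(field, config.cut_offset)
        rows.append({"level": lev, "target_h_cm": h,
                     "n_cells": mesh.n_cells, "dP_max_mmHg": dp_max,
                     "status": status})
        v, p = field.snapshot()
        prev = (mesh, v, p)
        if verbose:
            print(f"level {lev}: h={h:.3f} cells={mesh.n_cells} "
                  f"dP={dp_max:.4f} mmHg [{status}]")
    df = pd.DataFrame(rows)
    dp = df["dP_max_mmHg"].to_numpy()
    rel = np.full(levels, np.nan)
    rel[1:] = 100.0 * np.abs(dp[1:] - dp[:-1]) / np.abs(dp[1:])
    df["rel_diff_prev_pct"] = rel
    if config.output_dir:
        root = Path(config.output_dir)
        root.mkdir(parents=True, exist_ok=True)
        df.to_csv(root / "mesh_sensitivity.csv", index=False)
    return df
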