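# Methods

This note documents the models, discretizations, parameter defaults and
known limitations behind `tcpcflow`. All internal quantities are CGS
(cm, g, s, dyn, Poise); pressures are reported in mmHg using
1 mmHg = 1333.22 dyn/cm², power in mW (1 erg/s = 10⁻⁴ mW).

## Geometry idealization

The test section is a planar four-port cross junction: inflow arms (SVC
along +y, IVC along −y) and outflow arms (RPA along +x, LPA along −x) of
internal diameter 1.91 cm and length 5 cm (so that pressure cut planes at
4 cm from the center sit inside the arms), joined through a spherical
housing bulge of maximum diameter 3.4 cm centered at the origin.

The static pump insert is an **idealized bicone**: two cones joined
base-to-base, axis along the caval (y) axis so each apex faces an inlet and
the equator faces the pulmonary outlets. Defaults: height 2.4 cm, equator
diameter 2.4 cm. Hydraulic blades are represented as an annular ridge by
enlarging the equator radius by the blade height (1.09 mm baseline, 1.62 mm
filleted variant), which captures their flow blockage and gives a strictly
monotone rotor wetted area in blade height. Four cylindrical struts
(diameter 0.3 cm) span radially from the bicone to the housing in the
equatorial plane at 45° to the outlet axis. The thin-film secondary flow
path of the real device carries < 1 % of the venous return; it is fused
shut in this idealization and the `wall_secondary` group is absent by
default. The real pump's proprietary blade shapes are **not** reproduced;
consequences are discussed under Limitations.

A 2D verification mode meshes the same cross layout in the plane, with the
insert as the axis-plane cross-section of the bicone (a diamond with apexes
toward the inlets); struts are omitted in 2D because they lie out of plane.
Every operator in the package is dimension-agnostic.

## Mesh generation

Geometries are expressed as signed distance functions (SDFs) and meshed by
iterative truss relaxation (the Persson–Strang DistMesh algorithm):
candidate points inside the SDF are connected by Delaunay triangulation and
relaxed as a spring network whose rest lengths follow a size field, with
escaped points projected back onto the zero level set. Post-processing
removes boundary slivers, keeps the largest facet-connected component, and
repairs non-manifold boundary ridges, so every delivered mesh passes the
structural audits (strictly positive cell volumes, closed watertight
boundary, exactly one group label per boundary face, outward-consistent
normals). Meshing is deterministic for a fixed seed. With an insert
present the size field refines by a factor 1.8 toward the rotor and strut
surfaces, echoing the bench study's finer discretization of the impeller.
Port faces are labeled by proximity to the cap plane plus outward-normal
alignment, which stays robust on coarse meshes; rotor and strut faces are
labeled by nearest-SDF proximity.

Straight pipes (the main verification fixture) use a structured mesh:
concentric-ring disk triangulation, extruded to prisms and split into
tetrahedra with a min-vertex diagonal rule that guarantees conformity.
Boundary layers thin geometrically toward the wall: the n-th innermost
layer has thickness `ratio^n · h` with ratio 1/2 by default (exposed as a
parameter).

## Flow model

Incompressible Newtonian flow with rigid no-slip walls,

    ρ(v_t + v·∇v) − ∇·σ = f,   ∇·v = 0,   σ = −pI + μ(∇v + ∇vᵀ),

with blood-analog properties ρ = 1.06 g/cm³, μ = 0.035 P. Body force
defaults to zero (the bench rig is horizontal). The discretization is
continuous piecewise-linear velocity **and** pressure on simplices with
residual-based stabilization — SUPG/PSPG plus a grad-div (continuity
least-squares) term — which cures both the advective instability and the
inf-sup deficiency of the equal-order pair. With G the covariant element
metric (G = J⁻ᵀJ⁻¹ of the reference map), the stabilization parameters are

    τ_M = (4/Δt² + v·G·v + C_I ν² G:G)^(−1/2),   C_I = 36,
    τ_C = 1 / (τ_M · tr G),

applied as Σₑ∫ τ_M (v·∇w + ∇q/ρ)·r_M with the momentum residual
r_M = ρ(v_t + v·∇v − f) + ∇p, and ρ τ_C (∇·w)(∇·v). Degree-2 simplex
quadrature is used for the convective and inertial terms.

**Boundary conditions.** Inlets impose parabolic (or plug) velocity
profiles strongly, scaled so that the *discrete* flux equals the prescribed
flow exactly; at an operating point of CO L/min the IVC carries 60 % and
the SVC 40 % of CO·1000/60 cm³/s. Outlets carry the resistance traction
h = −(R·Q + P_distal) n with Q the instantaneous outlet flux; the coupling
is implicit (the flux of the current iterate), contributing a rank-one
block to the Jacobian, so the pressure level is set by R·Q without
sub-iteration. Printed bench resistances: 204.51 (RPA) and 222.49 (LPA)
dyn·s/cm⁵. Backflow stabilization adds the convective-inflow penalty
β ρ (v·n)₋ v on outlet faces with locally reversed flow, β = 0.2.

**Time integration** is the second-order generalized-α method for
first-order systems with spectral radius ρ∞ = 0.5 by default
(α_m = (3−ρ∞)/(2(1+ρ∞)), α_f = 1/(1+ρ∞), γ = ½+α_m−α_f), with full
Newton–Raphson correction per step (analytic Jacobian of the Galerkin and
dominant stabilization terms, τ frozen within an iteration; relative
residual tolerance 10⁻³, at most 6 iterations). The sparse systems are
solved by direct LU factorization, reused across inner iterations of a
step; an ILU-preconditioned GMRES option exists behind the same interface.

**Steady solves** use pseudo-transient continuation: the inflow is ramped
over 8 backward-Euler pseudo-steps at Δτ = 0.01 s, after which the pseudo
step grows geometrically (×2 per accepted step, capped at 50 s) toward a
Newton iteration on the stationary equations; steps that inflate the
steady residual are rejected and retried with Δτ/4. Convergence is a
steady-residual drop of 5·10³ relative to the start-up scale. A residual
that parks well below the start-up scale without converging while the
inner Newton stays healthy is reported as `unsteady_physics` — genuinely
unsteady flow, not solver failure — and the pipeline then falls back to
the bench-style protocol: a generalized-α transient (Δt = 0.01 s, 1.2 s
window) started from the quasi-steady state, with endpoints averaged over
the back 60 % of the window. In practice the insert models converge to
clean steady states at every cardiac output in the sweep, while the blank
housing is unsteady at all of them: its two caval jets collide head-on in
the bulge, and the collision point oscillates. The transient defaults
(Δt = 1 ms, 5 s horizon, snapshots every 20 ms) mirror the bench
simulation protocol and remain available for full-scale runs.

## Virtual dye and washout

Dye concentration φ obeys the advection–diffusion equation
φ_t + v·∇φ − ∇·((κ+κ_DC)∇φ) = 0 on the frozen steady velocity (converged
cases) or on stored transient snapshots with linear time interpolation,
one-way coupled. SUPG stabilization uses
τ_m = (4/Δt² + v·G·v + 3(κ+κ_DC)² G:G)^(−1/2); the discontinuity-capturing
diffusivity κ_DC = |L(φ)| / (2 √(∇φ·G·∇φ)) acts only where the front is
steep. Because the element Laplacian of a P1 field vanishes, the diffusive
part of the residual L(φ) is reconstructed from volume-averaged nodal
gradients — without this, κ_DC spuriously activates in diffusion-dominated
regions. Each implicit step performs 2 Picard passes updating κ_DC from
the current iterate.

The molecular diffusivity is not a measured quantity here; the default
κ = 10⁻⁴ cm²/s keeps the transport advection-dominated and numerically
benign, and no reported result depends on its exact value. Time stepping
is a θ-scheme with Δt = 0.02 s (the snapshot cadence; the implicit scheme
is unconditionally stable so the scalar step may exceed the flow step).
θ = 1 (backward Euler) is the default: at the junction's sharp-front,
large-CFL conditions it is the setting that keeps φ within the bounded
overshoot band [−0.05, 1.05]; θ = 0.5 (trapezoidal, second order) is used
by the smooth verification oracles where front monotonicity is not at
stake, at the price of overshoot near discontinuities.

Initialization sets φ = 1 on the nodes of a 3.5×3.5×3.5 cm axis-aligned
cube at the junction center (no smoothing) and 0 elsewhere; inlet boundary
values are held at 0. The washout time of a node is T = t₁% − t_max, where
t_max is the **earliest** time of the nodal maximum (plateaus resolve to
their start) and t₁% the first subsequent crossing of 1 % of that maximum,
linearly interpolated between snapshots. Nodes that never cross within the
horizon (5 s by default, the bench run length) are censored and flagged —
never extrapolated; nodes that never carried dye get T = 0, uncensored.
The regional mean washout is volume-weighted (lumped-mass node weights)
over uncensored nodes, reported together with the censored fraction.

## Endpoints

Wall traction uses σ = −pI + μ(∇v+∇vᵀ) with ∇v recovered at nodes by
volume-weighted element-gradient averaging (a strategy switch in the
code), node normals as area-weighted face normals, and the tangential
projection τ = σ·n − (n·σ·n)n. TAWSS is the magnitude of the
time-averaged traction **vector** (average first, then magnitude); OSI is
½(1 − |∫τ|/∫|τ|) ∈ [0, 0.5], defined as 0 where ∫|τ| = 0; steady
snapshots give OSI ≡ 0. Averaging windows default to the full transient
window for averaged runs (the paper-style protocol averages t = 2–5 s of a
5 s run) and to the single snapshot for steady runs. Low-WSS area fraction
is the area-weighted fraction of a wall group with TAWSS below 5 dyn/cm².

Cut-plane pressures are exact mesh/plane intersections (per-element
polygon sections, area-weighted linear interpolation), time-averaged, at
4 cm from the junction center by default — matching the bench catheter
positions. Pressure loss is inlet-plane minus outlet-plane mean pressure;
`dP_max` is the maximum over the four inlet–outlet pairs. Flow split is
100·Q_RPA/(Q_RPA+Q_LPA) from the outlet boundary fluxes. Power loss is
the net static-plus-dynamic pressure energy flux through the ports,
Σ_in ∫(p+½ρ|v|²)(v·n) − Σ_out ∫(p+½ρ|v|²)(v·n), the standard energy-loss
definition in Fontan modeling (the source study does not print its
formula; this choice is flagged in reports).

## Agreement statistics

Bland–Altman analysis on paired (simulated, measured) pressure losses:
mean difference (bias), sample SD (n−1), 95 % CI of the bias using the
t distribution (appropriate at the study's n = 15 pairs), and limits of
agreement at ±1.96 SD. Pearson correlation complements it. The synthetic
mock-loop generator produces measured = model + bias + N(0, σ) with
configurable bias and noise, reproducibly per seed, so the recovery of
configured bias and SD is a closed-loop test of the statistics stage.

## Problem sizes and defaults

The working configuration meshes the junction at h = 0.35 cm far-field
(≈ 7–9 k tetrahedra, refined ×1.8 toward insert surfaces), which one CPU
solves steadily in ~20–30 s per operating point; the full sweep runs in
minutes. The nested refinement study uses h = 0.7/0.35/0.175 cm
(1.1 k/8 k/58 k tets) on a 4.3 cm-arm variant of the same geometry (cut
planes at 4 cm still interior), warm-starting each level from the previous
solution. The dye stage advances 250 implicit steps over the 5 s horizon.

## Known limitations

- **Pre-asymptotic mesh sensitivity.** At these desk-scale resolutions the
  SUPG artificial viscosity (~h·|v|) still dominates the physical
  viscosity, so the pressure loss at the highest cardiac output is not yet
  in the asymptotic convergence regime: successive refinements change it
  by ~10–20 %, and demonstrating ≤3 % mesh sensitivity — as the original
  bench-scale study does with ~8 M elements and boundary-layer meshing —
  is out of reach of this configuration. The refinement study reports the
  honest figure rather than a converged one.
- **Idealized insert.** The smooth bicone lacks the real impeller's blade
  and strut detail. One visible consequence: the insert *reduces* the
  pressure loss relative to the blank housing here (increment ≈ −0.8 mmHg
  at CO = 7), because it splits the impinging caval jets and removes the
  central recirculation, while the blank housing's bulge dissipates
  strongly. The bench study measured a small *positive* increment
  (≤ 0.7 mmHg). Both satisfy the clinical bound; the sign differs because
  of the geometry idealization.
- **Printed Reynolds numbers.** The closed form Re = 4ρQ/(πDμ) with the
  printed fluid properties and 60/40 split gives 606…2221 over the sweep,
  whereas the bench report prints 674…2250. The formula is implemented as
  written and the discrepancy is documented, not reconciled.
- Passing the synthetic-data tests shows the pipeline's operators are
  correct on this idealized geometry class and these operating points; it
  does not validate predictions for the proprietary pump shape,
  patient-specific anatomies, pulsatile/respiratory inflow, non-Newtonian
  rheology, or compliant walls, none of which are modeled.
- The 2D mode treats the prescribed volumetric flows as per-depth fluxes;
  its Reynolds regime therefore differs from the 3D tube flow, and it is
  used only for cheap verification of operators and trends.
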