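# Methods

`perfunet` couples three models of an artificial supply network embedded in
engineered tissue: channel-network hydraulics, transport across the porous
channel wall, and reaction–diffusion with cellular oxygen consumption in
the tissue compartment. This note records the model assumptions, the
numerical choices, and the limits of what the tests demonstrate.

## Units

Lengths in mm, time in s, concentration in mol m⁻³, pressure in Pa,
flow rate in mm³ s⁻¹. All conversions happen once at parameter ingestion
(`parameters`). Under this convention the volumetric consumption rate
ρ_T·k_ocr (mol mm⁻³ s⁻¹) carries a factor 10⁹ when acting on
concentrations in mol m⁻³, and a wall flux Π_w·Δc (mm s⁻¹ × mol m⁻³)
carries 10⁻³ to reach SI mol m⁻² s⁻¹. Cross-section wall fluxes Φ (per
unit channel length) are kept in the internal mol m⁻³ mm² s⁻¹; multiply by
10⁻⁶ for mol m⁻¹ s⁻¹.

## Network hydraulics (`netflow`)

Channel segments are rigid cylinders with fully developed laminar flow:
per-edge Hagen–Poiseuille conductance G = πR_c⁴/(8μL), nodal flow
conservation (Kirchhoff), and a sparse SPD pressure solve with
fixed-pressure nodes eliminated and fixed-inflow nodes as sources. Solute
is routed through the resulting directed acyclic flow graph in descending
nodal-pressure order: every junction mixes flow-weighted incoming
concentrations; per-edge depletion uses the closed-form integral of the
axial balance for a constant per-length sink. Blocked edges keep their
geometry but carry zero conductance (and an oxygen-impermeable surface in
the tissue solver), so volume accounting is unaffected by blockage.
Dimensionless validity checks (Re, Pe_z, Gz) warn — never fail — outside
the regime where the 1D channel model is justified: Re > 10 (developing
flow), Pe_z < 10 (axial diffusion), Gz > 1 (radial mixing). At the nominal
operating point (R_c = 50 µm, v̄ = 8 mm s⁻¹, water at 37 °C) Re ≈ 1.15.

## Wall model (`wallmodel`)

Steady radial diffusion through the cylindrical wall annulus has the exact
solution c = A + B·ln r, so the wall collapses into a single flux
coefficient Π_w = D_w/(R_w·ln(R_w/R_c)) applied as a Robin condition at
the outer radius — the wall is never meshed in tissue solves. For a
cylindrical geometry this collapse is exact, not an approximation, which
the series-resistance test confirms numerically to <0.5%. The effective
wall diffusivity uses the porosity mixture D_w = f_p·D_c + (1−f_p)·D_ws
(parallel disconnected pores; no tortuosity corrections). Bare channels
from sacrificial templating are represented by Dirichlet coupling at
R_w = R_c, never by a large finite Π_w, to avoid ill-conditioned Robin
coefficients.

## Geometry and voxelization (`geometry`)

Base units are repeating volume-filling cells with channels along their
edges and zero-normal-flux symmetry on every face, which embeds the unit
in an infinite honeycomb: the cube [0,s]³ (12 edge channels) and the
rhombic dodecahedron with vertices (±u,±u,±u), (±2u,0,0) and permutations,
u = a/√3 (24 edge channels of length a, volume 16u³ = (16/9)√3·a³).
Voxelization is cell-centered with half-open membership decided by the
voxel center: a voxel is channel iff its center lies within R_w of a
segment axis, clipped to the cell interior — so a channel shared between
adjacent cells automatically contributes exactly its sector to each.
Volumes are voxel counts × h³ and converge with first order in h.
Resolution guard: h > R_w/2 is an error (the channel would lose its cross
section), h > R_w/5 warns.

The density generator convolves white noise with an isotropic Gaussian
kernel of standard deviation ℓ, rescales affinely to a target mean and
coefficient of variation over the tissue voxels, and clips at zero
(recording the clipped fraction and warning above 1%). It emulates
spatially correlated seeding/proliferation heterogeneity; it does not
model density-dependent diffusivity, anisotropy, or temporal growth, so
tests passing on these fields say nothing about those effects.

## Reaction–diffusion solver (`rdsolver`)

The tissue oxygen field satisfies 0 = ∇·(D_t∇c) − ρ_T·k_ocr·c/(k_m+c)
with a 7-point cell-centered finite-volume discretization. Channel voxels
are excluded; the channel surface enters through face transmissibilities:
Dirichlet ghost at half-cell distance (2D_t/h per area) or the Robin
coefficient in series with the half-cell resistance
(1/(1/Π_w + h/(2D_t))). D_t is held constant even under heterogeneous
density. The scheme is locally conservative; the flux-vs-consumption
balance closes to ~10⁻⁶ relative at convergence.

The saturating sink is handled by Picard iteration on the lagged
coefficient ρ_T·k_ocr/(k_m+c⁽ⁿ⁾). Each linearized operator is an M-matrix
with non-negative right-hand side, so every iterate obeys
0 ≤ c ≤ max boundary value; the discrete maximum principle is asserted
after every solve. Started from the uniform boundary value, the iterates
decrease monotonically toward the solution, which yields an exact
feasibility short-circuit: if any iterate dips below the hypoxic
threshold, the converged field must too, and design screens abort early.

Numerical settings: Picard relative-update tolerance 10⁻⁶ (≤200
iterations, optional under-relaxation); linear sub-solves are direct
(SuperLU) for ≤4×10³ unknowns or quasi-2D grids (≤5×10⁴), and
Jacobi-preconditioned conjugate gradients elsewhere, warm-started from the
previous Picard iterate with an inexact-Newton-style inner tolerance
(min(0.05×outer update, 10⁻⁴), floored at 10⁻¹⁰). Observed convergence is
second order on smooth 1D problems; stair-cased channel surfaces reduce
boundary accuracy to first order locally, which the resolution floor and
the acceptance tolerances absorb. The 1D spherical problem uses a
conservative radial finite-volume mesh (default 400 cells) with a
parabolic center extrapolation.

## Design procedures (`design`)

The objective is max Ω_t/(Ω_c+Ω_w) subject to c ≥ c_H everywhere. By the
comparison principle the minimum concentration decreases with compartment
size, so the feasible set in the size coordinate is an interval and the
maximization reduces to bracket growth plus bisection — deterministic,
with the returned size re-verified feasible and the bracket top
infeasible. Monotonicity is checked on the evaluations gathered while
bracketing (tolerance 2×10⁻³ relative, the discretization noise floor
between different grids); a gross violation aborts, since it would
indicate a solver defect. Default relative tolerances: 10⁻³ for 1D
spheres, 5×10⁻³ for 2D cross-sections, 10⁻² (high-demand) to 2×10⁻²
(low-demand, large-cell) for 3D units. Infeasible parameter combinations
are first-class results, not exceptions.

3D unit solves use the octant symmetry of both cell kinds and a voxel
size h = clip(s/64, R_w/5, R_w/2): resolution follows the cell size so
that small cells resolve the channel surface finely while the centimeter-
scale low-demand cells (s ≈ 4 mm at 50 µm channels) remain tractable on a
single core; at the coarse cap the channel cross-section still spans
several voxels and the reported volume ratios change by ~2% under
refinement, well inside the design tolerances.

The long-channel march splits a channel of length L into n elements.
Element j sees its channel concentration c_j as a constant wall condition,
maximizes its square cross-section edge s_j in a quarter-domain 2D solve
(symmetry sides, Dirichlet or Robin at the channel circle), integrates the
wall flux per unit length Φ_j from the solved field, and depletes
c_{j+1} = c_j − Φ_j·Δz/Q with Q = πR_c²·v̄ — the axial mixing-cup balance
applied elementwise. Axial diffusion in tissue between elements is
neglected, consistent with the per-element stepping; the global balance
Q(c_in−c_out) = ΣΦ_jΔz then holds to round-off by construction, and the
2D conservation check (Φ vs total consumption, <1%) carries the real
discretization content. When no feasible edge above the geometric bound
2R_w exists, the element is recorded at the bound and the march continues.
The printed "edge length" is interpreted as the full cross-section edge
with the channel centered; with bare 50 µm channels R_c = R_w.

## What the defaults represent

Preset metabolic parameters cover high-demand tissue (liver-like,
ρ_T = 2×10⁵ cells mm⁻³, k_ocr = 10⁻¹⁶ mol cell⁻¹ s⁻¹, k_m = 0.028
mol m⁻³) through low-demand tissue (ρ_T = 1.4×10⁴, k_ocr = 4.2×10⁻¹⁷,
k_m = 0.007), hypoxic threshold c_H = 0.05 mol m⁻³, tissue diffusivity
D_t = 2×10⁻³ mm² s⁻¹. Channel concentrations 0.2 and 1.0 mol m⁻³
correspond to air-saturated medium at incubator conditions and to the
maximal oxygen solubility in water at 37 °C. The culture medium's
viscosity is not part of the metabolic data; defaults use water at 37 °C
(μ = 6.9×10⁻⁴ Pa s, ν = 0.696 mm² s⁻¹), consistent with Re ≈ 1 at the
nominal operating point, and D_c = 3×10⁻³ mm² s⁻¹ (O₂ in water at 37 °C).
Only oxygen is validated; the transport machinery is species-generic, but
glucose and CO₂ are not limiting for aerobic cultures (high solubility
and high metabolic limits respectively), so no presets are shipped for
them.

## Known limitations

- Steady state only: no transients, no cell growth or death feedback, no
  advection inside the tissue (the cellular environment is at rest).
- Newtonian medium in rigid channels; blood rheology and deformable walls
  are out of scope.
- Stair-cased channel surfaces: boundary flux accuracy is first order at
  the surface; design answers are controlled by the far-field minimum and
  are much less sensitive.
- The per-element march neglects axial tissue diffusion between elements
  and radial concentration gradients inside the channel (valid for small
  Graetz number; at the nominal 5 mm/8 mm s⁻¹ operating point Gz ≈ 1.3,
  borderline, and the solver warns).
- The density generator's marginal distribution (clipped Gaussian) is a
  modeling choice; only its mean, variance and correlation length are
  meaningful parameters.
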