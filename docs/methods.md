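# Methods

## Scope and model structure

`vasctrans` simulates how a systemically administered solute distributes
through vascularized brain-like tissue, using the *smeared* (composite)
finite-element concept: within each 3D element the microvasculature is not
resolved geometrically but represented by a capillary volume fraction r_V,
so every mesh node carries co-located capillary-domain and tissue-domain
fields. Larger vessels are explicit 1D elements immersed in the continuum
and tied to it by connectivity (fictitious) coupling pairs. Four coupled
fields are solved: vessel/continuum pressure (steady) and vessel/continuum
concentration (transient), plus a 1D vessel concentration field.

The package deliberately runs at desk scale. A whole-organ model of this
type couples O(10⁵) continuum elements to O(10³) vessel elements from a
micro-CT reconstruction; the synthetic generator reproduces that three-class
element structure (1D ≪ 3D, plus a connectivity set) at roughly 1/30 the
size so that every stage — geometry, flow, transport, post-processing —
executes in seconds on one CPU with no external data.

## Compound physics

Stokes–Einstein, D = k_B T/(6πηα), is evaluated in SI and converted to the
package's canonical units (mm, s, Pa, mol/L, K). Defaults pair
η = 8.905 × 10⁻⁴ Pa·s with T = 298.15 K: that viscosity is water near 25 °C,
and the built-in compound diffusivities are self-consistent with exactly
this pairing, so "physiological temperature" (310 K) is expressible but not
the default. Radius or diffusivity may each be the authoritative input; the
other is derived by the exact inversion α = k_B T/(6πηD), and a supplied
pair must agree to 0.5 %.

Built-in compounds (diffusivity mm²/s, clearance mL s⁻¹ kg⁻¹):
Ph₃SnL₁ (4.31 × 10⁻⁴, 9.356), Ph₃SnL₂ (4.24 × 10⁻⁴, 8.015), galantamine
(5.17 × 10⁻⁴, 6.176). Clearance converts to a first-order volumetric sink
k_e = CL·ρ·10⁻³ s⁻¹ with tissue density ρ = 1.0 kg/L by default.

A deliberate interpretation: whole-organ protocols of this kind quote a
generic slow tissue diffusivity (0.2 mm²/s) *and* per-compound
diffusivities. Here a compound-specific run uses the compound's D as the
tissue-domain diffusivity while the capillary domain keeps the intentionally
huge 10⁴ mm²/s (an intravascular fast-mixing device, not molecular
diffusion); 0.2 mm²/s remains the compound-free default.

## Synthetic geometry

* **Mesh.** Structured Kuhn (Freudenthal) subdivision: each grid cube splits
  into six path-tetrahedra sharing the same diagonal, which is conforming
  and non-obtuse. Per-axis cell counts are chosen so the element count lands
  within ±20 % of the target. Ellipsoids use the standard cube-to-ball map
  p → p·(‖p‖∞/‖p‖₂) scaled per semi-axis; orientation is re-checked after
  mapping. Linear (P1) shape functions throughout.
* **Vessel network.** A seeded capillary tree grows from one inlet by
  randomized extension/bifurcation steps (segment length 0.35–0.8 mm,
  bifurcation probability 0.35); a vein tree grows from the opposite outlet
  with edges oriented toward it; a few junction segments drain capillary
  tips into the vein tree, guaranteeing a directed inlet→outlet path by
  construction. Radii follow root·decay^depth (decay 0.85) with a 4 µm
  floor. All randomness flows from `numpy.random.default_rng(seed)`; equal
  recipes give byte-identical geometry.
* **r_V field.** Capillary segments are treated as cylinders; each segment
  is split into sub-pieces whose volume πr²ΔL is charged to the element
  containing the piece midpoint (KD-tree point location with
  nearest-element fallback). Summed over elements this conserves the total
  capillary volume exactly, which the tests audit. Veins are collectors and
  contribute neither to r_V nor to wall exchange. A uniform-r_V mode exists
  for verification configurations; "derived" is the default.
* **Connectivity.** Each vessel node pairs with the tissue nodes within 1.5
  mean element diameters (nearest node as fallback, so no vessel node is
  orphaned); its total coupling coefficient equals the local lateral surface
  area Σ 2πr·L/2 of adjacent segments, split evenly over its partners.

## Flow

Per segment, Hagen–Poiseuille conductance g = πr⁴/(8μL) with blood viscosity
taken equal to water (10⁻³ Pa·s). The continuum fields obey Darcy's law
v = −κ∇p with Galerkin P1 stiffness weighted by the domain fraction (r_V or
1 − r_V, floored at 10⁻⁶ to keep decoupled rows invertible).

Two printed whole-organ coefficients arrive without usable units and are
interpreted once, logged, and kept configurable:

* the "Darcy coefficient" 10⁻¹³ mm²/s is read as a lumped mobility κ in
  v = −κ∇p (mm s⁻¹ per Pa mm⁻¹);
* the "leakage coefficient" 10⁻¹¹ is read as a transmural hydraulic
  conductance per unit tissue volume (s⁻¹ Pa⁻¹), lumped at mesh nodes.

Vessel↔capillary coupling uses the connectivity coefficient times a
hydraulic conductivity per area (default 10⁻⁸ mm s⁻¹ Pa⁻¹, a Starling-type
filtration coefficient). Dirichlet pressures (inlet 20 mmHg, outlet
10 mmHg; 1 mmHg = 133.322 Pa) are imposed by row replacement at inlet
capillary and outlet vein nodes — how a single network solve hosts both
conditions is itself an interpretation, flagged here. The sparse block
system is solved by direct factorization; fields with no coupling path to a
Dirichlet node (κ = 0 or zero leakage/connectivity) are pinned to the outlet
pressure, which is exact since they carry no flow.

## Transport

For each continuum domain d with fraction φ_d: lumped mass ∫φ_d N, stiffness
∫φ_d D_d ∇N·∇N, and Galerkin advection ∫φ_d N(v_d·∇N) with the element-wise
Darcy velocity. The 1D network carries lumped mass πr²L/2 per node,
diffusion πr²D/L and finite-volume upwind advection of the solved segment
flows. Coupling terms, all assembled so their column sums vanish (they move
mass, never create it):

* diffusive wall exchange k_w·w_i·(c_cap − c_tis) with k_w = 100 s⁻¹ by
  default — the printed "wall permeability of 100" read as a volumetric
  exchange rate — on lumped nodal volumes w_i;
* convective leakage q_leak·c_upwind, upwinded by the sign of
  (p_cap − p_tis) to preserve positivity;
* vessel↔capillary exchange through the connectivity pairs (permeability
  per coupling area, default 0.1 mm/s) plus upwinded convective transfer of
  the connectivity flows;
* clearance −k_e c_tis on the tissue field only.

Time integration is a θ-scheme, θ = 1 (backward Euler) by default for
unconditional stability at the 10 s protocol steps; θ = 0.5 is used in the
temporal-convergence tests. The default protocol is 400 s in 40 equal
steps. The inlet bolus is a rectangular 20 mol/L pulse of 40 s — one tenth
of the horizon, consistent with an early-phase tissue peak — with the end
point inclusive; shape, duration and amplitude are configuration, not
ground truth, since the source protocol names a bolus without printing its
profile. Outlet vein nodes hold 0 mol/L. Initial fields are zero.

Two numerical safeguards matter on distorted meshes: mass matrices are
row-sum lumped, and positive off-diagonal stiffness entries (from obtuse
tets produced by the ellipsoid mapping) are moved to the diagonal — the
standard low-order artificial-diffusion correction, symmetric and row-sum
preserving. Together with upwinding this keeps every nodal concentration
inside [0, bolus amplitude] to solver precision; the cost is locally
first-order diffusion accuracy on the affected elements. The
manufactured-solution convergence study runs on box meshes, where the fix
is inactive and the clean O(h²) rate is observed.

**Mass ledger.** Every step records storage change, boundary influx/outflux
(recovered from the unconstrained residuals at Dirichlet nodes), clearance,
and the Galerkin-advection boundary defect. Because all other operators have
vanishing column sums, the identity storage = in − out − clearance − defect
holds to machine precision and is asserted on every run; the closed-system
conservation test (no boundaries, no clearance) checks constancy of total
mass independently.

**Two-compartment reduction.** An independent well-mixed oracle integrates
dc_cap/dt = −(k_w/φ_c)(c_cap − c_t) + s(t),
dc_t/dt = (k_w/φ_t)(c_cap − c_t) − k_e c_t with fixed-step RK4 (≥10⁴ steps).
A single-tet FE configuration with uniform r_V must reproduce it to 10⁻⁴
relative — this pins the exchange/clearance kinetics against a solver-free
reference.

## Post-processing

Domain means are φ_d-volume weighted: mean_d = Σ w_{d,i} c_i / Σ w_{d,i}
with w_{d,i} the lumped φ_d-weighted nodal volumes. Unweighted nodal
averages are meaningless in a smeared formulation, and using the same
lumped weights as the mass matrix makes mean × domain volume equal the
ledger's stored mass identically. Peak detection returns the earliest time
attaining the maximum. Plane slices interpolate barycentrically on a
regular in-plane grid; points outside the mesh are NaN, never extrapolated.

## Assay arithmetic

Inhibition is (E − S)/E × 100; values outside [0, 100] (activation) are
reported, not clamped. IC50 is estimated by log-linear interpolation between
the first adjacent concentration pair bracketing 50 % — deliberately minimal
since no fitting rule is published with the measured values; a 4-parameter
logistic would add parameters the data cannot pin down. Carrier correction
multiplies the apparent IC50 by the loaded complex mass fraction (4.35 % /
4.46 % for the two hybrids), reading "mass content of organotin" as the
fraction of the whole complex, the only reading that approximately
reproduces the published corrected values. The products (1.041 and
0.599 µM) sit ~3 % from the published corrected IC50s (1.07 and 0.58 µM);
the residual is attributed to rounding of unpublished intermediates and is
documented rather than fitted away. Fold potency is reference/test.

## What the synthetic generator does and does not emulate

It reproduces: the three-element-class structure, a perfused hierarchical
network with one inlet and one outlet, heterogeneous vessel density (hence
heterogeneous r_V), and the parameter regime of the whole-organ protocol.
It does not reproduce: real cortical topology or anatomically calibrated
vessel densities, multiple inlets/outlets, lymphatics, pulsatility, vessel
compliance, binding/saturation kinetics or efflux transporters. Passing
tests therefore demonstrate correctness of the numerics and the qualitative
transport behaviour (early-phase peak, clearance-ranked exposure, bounded
and conservative fields) — not quantitative agreement with any animal's
concentration maps.

## Defaults worth knowing

| parameter | default | unit | note |
|---|---|---|---|
| inlet / outlet pressure | 20 / 10 | mmHg | capillary pressure gradient |
| blood viscosity | 10⁻³ | Pa·s | equal to water |
| Darcy mobility κ | 10⁻¹³ | mm² s⁻¹ Pa⁻¹ | lumped-mobility interpretation |
| leakage coefficient | 10⁻¹¹ | s⁻¹ Pa⁻¹ | per-volume conductance interpretation |
| wall permeability k_w | 100 | s⁻¹ | volumetric exchange-rate interpretation |
| D capillary / tissue | 10⁴ / 0.2 | mm²/s | tissue D replaced per compound |
| bolus | 20 mol/L, 40 s, rectangular | | interpretation, configurable |
| protocol | 400 s, 40 steps, θ = 1 | | |
| tissue density | 1.0 | kg/L | clearance conversion |
| recipe | ellipsoid 6×5×4 mm, 5000 tets, 200 segments | | reduced scale |

## Known limitations

* The r_V apportionment ignores cylinder overlap at junctions and charges
  partial sub-segments to single elements; exact only in aggregate (the 2 %
  audit bound is generous — the implementation conserves exactly).
* Connectivity coefficients split evenly among partners rather than by
  distance weighting.
* The M-matrix correction trades local accuracy for positivity on distorted
  elements; refine the mesh rather than widening tolerances if sharper
  fronts are needed.
* Backward Euler damps the bolus front at 10 s steps; use θ = 0.5 with
  finer steps for time-accurate studies.
* Solvers are direct sparse factorizations, appropriate up to ~10⁵
  unknowns; larger geometries would need an iterative solver, which this
  package does not provide. Likewise no streamline-upwind stabilization is
  offered: every shipped configuration is low-Péclet (huge capillary
  diffusivity, near-zero Darcy velocities), where plain Galerkin plus the
  positivity safeguards above is the better-conditioned choice.
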