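# Methods

## Model overview

`vasotherm` solves steady, incompressible, Newtonian blood flow and steady
heat transport on a voxelized organ domain containing resolved 1D vessel
trees. The flow problem and the thermal problem are each linear; the
thermal problem consumes the solved flow field (one-way coupling).

### Flow

Unknowns: arterial and venous compartment pressures P_a, P_v per tissue
voxel, plus one pressure per vessel-tree node. Equations:

- **Vessel elements.** q_ji = κ_ji (p_j − p_i), κ = πR⁴/(8µL). Flow is
  signed by the solved pressures, not by file orientation.
- **Interior vessel nodes.** Kirchhoff mass balance Σ κ(p_self − p_nbr) = 0.
- **Tissue voxels (per compartment).** TPFA finite volumes:
  Σ_j t_ij (P_i − P_j) ± αV(P_a − P_v) − (source/sink) = 0, with face
  transmissibility t = A·harm(k_i,k_j)/(µ·d). Vessel-labeled voxels carry
  no porous unknowns (blood does not permeate vessel walls); their flow is
  entirely 1D.
- **Terminals.** Each terminal node k is linked to the weighted tissue
  pressure ⟨P⟩_k = Σ_i w_{k,i} P_i of its sphere of influence through a
  virtual-network conductance: κ(p_n − p_k) + (γ/µ)(⟨P⟩_k − p_k) = 0.
- **Roots.** Dirichlet: p = P_in at arterial roots, p = P_out at venous
  roots.

The SoI weights are w_{k,i} = η^ε(x_i − x_k)·V_i with the compact-support
bump η^ε(x) = (C/εⁿ)·exp(1/(|x/ε|²−1)) for |x| < ε and 0 otherwise. C is
calibrated **per terminal against the discrete voxel quadrature** so that
Σ_i w_{k,i} = 1 exactly on the mesh. Calibrating discretely (rather than
using the continuous-space constant) keeps the distribution conservative
even where the ball is clipped by the domain boundary; it also makes the
spatial dimension n a pure rescaling of C with no effect on the weights.
SoI membership is restricted to TISSUE voxels; distances are Euclidean
from the terminal node position to voxel centers.

Derived fields: element flows from κΔp; per-terminal exchange flow from
the terminal element (the (γ/µ)(p_k − ⟨P⟩) form is algebraically equal at
the solution but multiplies pressure round-off by γ/µ ≈ 3·10¹⁶ at the
default γ and is never used for output); per-voxel absolute source/sink
rates Q = w·q (m³/s); perfusion flux u_perf = α(P_a − P_v).

### Heat

Unknowns: one temperature per tissue voxel and one per vessel element
(all voxels covered by an element are isothermal with it). Steady
balances:

- **Tissue voxel.** Face terms U·A·(T_nbr − T) with
  U = K_t/ds (tissue–tissue), U = [ds/2K_t + 1/h_∞]⁻¹ (ambient faces,
  including the domain hull), U = [ds/2K_t + 1/h_b]⁻¹ (vessel faces,
  against the owning element temperature); upwinded advection
  m·c_pb·(T_upstream − T) over the neighbors blood flows in from; SoI
  source advection m_k·c_pb·(T_elem − T); metabolic generation q̇_m·V.
  ds is the axis-aligned center distance of the face (anisotropic), A the
  matching cross-section.
- **Vessel element.** Advection from upstream contributors (the parent
  element in an arterial tree; child elements and/or in-SoI voxels for
  venous elements, mixed proportionally to their mass rates at shared
  nodes) plus exchange with adjacent tissue voxels. Arterial root
  elements are Dirichlet-pinned at T_in; the venous root outlet is
  advective outflow only.

Three deliberate modeling choices, stated because the balance equations
leave them implicit:

1. **Donor-cell upwinding.** Advection uses the difference form
   m(T_upstream − T_local) restricted to inflows; outflow enthalpy at the
   local temperature cancels by per-voxel mass closure of the flow
   solution (which the advection-graph builder verifies before assembly).
   Together with positive exchange coefficients this makes the matrix an
   M-matrix, guaranteeing the discrete maximum principle for q̇_m = 0.
2. **Single thermal node per voxel.** The arterial compartment, venous
   compartment and tissue in a voxel are taken to be in local thermal
   equilibrium, so inter-voxel advected mass sums both compartments' face
   flows, and intra-voxel arterial→venous perfusion carries no heat.
3. **Symmetric wall exchange.** The element-side exchange with tissue uses
   the same overall coefficient [ds/2K_t + 1/h_b]⁻¹·A as the voxel-side
   term, so the pairwise exchange is antisymmetric and energy is conserved
   exactly. (Writing the element side with a bare h_b instead would leak
   the tissue half-cell term; at the default parameters the two
   coefficients differ by ≤ 0.2 %.) Tissue–vessel faces carry no
   conduction term, only this convective exchange; faces between vessel
   voxels are interior to the isothermal elements and carry nothing.

Blood thermal conductivity K_b is accepted in the parameter set but enters
no equation of the steady model (elements exchange heat only by advection
and wall convection); it is parsed and reported unused.

Temperature of blood delivered through a sphere of influence is the
supplying terminal element's temperature: no heat loss is modeled along
the virtual unresolved vessels.

## Parameters

Defaults (SI; temperatures °C) are magnitudes for a thin amphibian-tongue
preparation, the package's reference demonstration domain:

| symbol | meaning | default | unit |
|---|---|---|---|
| k_a, k_v | compartment permeabilities | 1e-12, 5e-10 | m² |
| α | compartmental perfusion coefficient | 1e-6 | coefficient of u_perf = α ΔP |
| µ | blood viscosity | 3e-3 | Pa·s |
| γ_a, γ_v | virtual-network pressure-drop parameter | 1e14 | coefficient of q = (γ/µ) Δp |
| P_in, P_out | root pressures | 10600, 1600 | Pa |
| ε | SoI radius | per problem | m |
| K_t | tissue conductivity | 0.49 | W m⁻¹ °C⁻¹ |
| c_pt, c_pb | specific heats (tissue, blood) | 3421, 3617 | J kg⁻¹ °C⁻¹ |
| ρ_t, ρ_b | densities | 1090, 1050 | kg m⁻³ |
| q̇_m | metabolic generation | 0 | W m⁻³ |
| h_b | vessel-wall film coefficient | 0.001 (`pbm`) / 10 (`wjm`) | W m⁻² °C⁻¹ |
| h_∞ | ambient film coefficient | 20 | W m⁻² °C⁻¹ |
| T_in, T_∞ | inlet blood / ambient temperature | 35, 20 | °C |
| voxel | spacing | 64 × 64 × 333/3 | µm |

α and γ are treated literally as the proportionality coefficients of
their defining laws; their derived units follow from those laws (the
printed unit conventions for these two coefficients are not dimensionally
decisive, so the code does not attach units to them). With γ = 1e14 the
virtual-network resistance µ/γ ≈ 3·10⁻¹⁷ is negligible against every other
resistance in the chain: terminal node pressures track their SoI-averaged
tissue pressures, and essentially the whole compartmental pressure drop
(≈ 8 kPa at the default boundary conditions) occurs across the capillary
bed, as intended by the parameter magnitudes.

Q_a/Q_v are stored as absolute per-voxel volumetric rates (m³/s);
densities per voxel volume are a trivial division and are not duplicated.

## Numerics

- Unknown ordering is fixed and reproducible: [P_a voxels | P_v voxels |
  arterial nodes | venous nodes] and [T voxels | elements], with voxels in
  ascending linear (z-fastest) order and nodes/elements in id order.
- Rows are equilibrated by their maximum absolute entry before solving
  (coefficients span ~30 orders of magnitude between γ/µ terms and
  perfusion terms); unknowns share a physical scale so no column scaling.
- Default solver: GMRES (restart 200, rtol 1e-8) preconditioned with
  scipy's ILU (drop tolerance 1e-6, fill factor 20). Systems below 4000
  unknowns use a direct dense solve by default; the dense path is also the
  verification oracle for the iterative path.
- The thermal residual is additionally reported as max|Ax − b| of the
  physical (unscaled) system — the worst per-cell energy imbalance in
  watts.
- Dirichlet conditions replace rows by identity; a structural check
  rejects thermally unanchored systems (no Dirichlet value, no ambient
  face, no inlet) and isolated unknowns (zero rows) before solving.
- The advection-graph builder checks per-node and per-voxel mass closure
  of the supplied flow solution, with errors normalized by the largest
  volumetric rate present and floored at the round-off scale of the rate
  computations (so an equilibrium field with pure-noise flows passes).
- Degenerate inputs: ε smaller than the voxel neighborhood raises a
  coupling error naming the terminal; h = 0 seals a convective face
  rather than erroring; P_in = P_out is allowed and yields the zero-flow
  equilibrium.

## Synthetic fixtures: what they emulate, what they do not

The fixtures in `vasotherm.fixtures` reproduce the *structure* of the
layered organ domain: a thin three-layer slab whose top layer carries an
arterial tree, middle layer pure tissue, bottom layer a venous tree, with
Dirichlet pressures at tree roots and the default parameter magnitudes
above. The toy domain uses interdigitated axis-aligned vessel combs; its
default ε is chosen as 1.1× the largest tissue-to-nearest-terminal
distance so every tissue voxel has at least one direct arterial source and
one venous sink (the criterion used to pick ε = 10 mm on the real organ).
Test problems are 10–30 voxels across, roughly a millimeter of tissue, so
their surface-to-volume ratio is far higher than a real organ's: absolute
temperatures sit closer to ambient and temperature contrasts are tens of
millikelvin rather than kelvins. Passing tests therefore demonstrate
conservation, ordering and sign structure, analytic-limit agreement, and
solver correctness — not organ-scale temperature magnitudes, vessel
geometry realism (no tortuosity, no radius tapering along branches), or
image-segmentation effects.

Seeded toy variants jitter boundary pressures, perfusion, inlet/ambient
temperatures, film coefficients, radii, and ε over physiological ranges to
exercise robustness (e.g. the maximum-principle battery).

## Sensitivity analysis

One-at-a-time: each parameter is scaled by (1+δ), δ = 0.01 by default; the
per-unknown coefficient is the relative change of the temperature offset
θ = T − T_∞ divided by δ, averaged over all thermal unknowns (tissue
voxels and vessel elements both, switchable). Unknowns with |θ| below a
configurable floor (default 1e-9 °C) are excluded from the mean and
counted, since the ratio diverges as θ → 0. The inlet-temperature row
perturbs the offset itself (T_in ← T_∞ + 1.01·(T_in − T_∞)); because the
steady system with q̇_m = 0 is linear and homogeneous in the offsets, its
mean coefficient is exactly 1 — any excess reported on top of 1 by a
finite-difference implementation is a near-ambient-voxel artifact, not
physics. Flow-only parameters re-solve the flow stage and rebuild the
advection graph; thermal parameters re-use the cached flow solution.

## Field comparison statistics

ΔT maps between two runs are summarized as V₊/V₋/V₀ — percentages of
compared volume with ΔT ≥ τ, ΔT ≤ −τ, and strictly between (τ = 1 °C by
default; boundary values count toward the tails, and the three sum to
exactly 100). Significance uses the two-sided Wilcoxon signed-rank test
with zero differences dropped before ranking and the dropped count
reported; identical fields are flagged degenerate rather than tested.

## Known limitations

- Steady state only: all ∂/∂τ terms are dropped. Transient stepping and
  any time dependence of the SoI distribution are extension points, not
  implemented.
- Newtonian blood, rigid vessels, no pulsatility, no red-cell particulate
  effects, no vasomotion feedback, no radiative/evaporative boundary
  exchange, no tissue damage model.
- Structured voxel meshes only; stair-step boundary error is not
  smoothed.
- Tissue permeabilities, α and γ are inputs; the package does not derive
  them from microvascular geometry.
- ε is a modeling parameter with no first-principles value; the SoI-radius
  comparison tooling exists precisely because results depend on it.
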