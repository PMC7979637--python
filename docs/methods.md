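# Methods

`mbesim` simulates the coupled bioelectricity and poromechanics of a closely
packed cluster of animal cells. This note records the model, its
assumptions, the numerical choices, and what the synthetic benchmark does
and does not establish.

## Model

The cluster is treated as a continuum mixture in a Lagrangian (reference)
frame: at every material point a hyperelastic solid network (cytoskeleton
plus anchoring junctions) coexists with two interpenetrating fluid
compartments — the intracellular (IC) space, connected cell-to-cell by gap
junctions (GJs), and the extracellular (EC) space of intercellular clefts.
Each compartment holds a dilute ideal solution of water and ions (Na+, K+,
Cl−, plus an impermeant monovalent anion representing charged
macromolecules). Because water, ions and the network are individually
incompressible, the volume ratio J is slaved to the water contents of the
two compartments; a shared water pressure p_w enforces this constraint as a
Lagrange multiplier and the IC water concentration is eliminated in its
favor.

Governing equations, all on the reference configuration:

* quasi-static momentum balance, Div P = 0, with a compressible neo-Hookean
  network stress, a −p_w J F⁻ᵀ eigenstress, and (small) Maxwell
  polarization stresses of the two compartments;
* mass balances for EC water and for each mobile ion in each compartment,
  with transmembrane exchange appearing as self-balancing local
  source/sink pairs scaled by the membrane area per cell volume
  A^c/V^c = 2/R^c;
* Gauss laws for the IC and EC electric potentials ψ, ψ^e with free charge
  from all (mobile and fixed) ions.

Bulk fluxes derive from symmetric positive-definite Onsager mobility
matrices: water moves down its pressure gradient (Darcy), by
electro-osmosis with the mobile ions, and down the fixed-ion osmotic
gradient; ions electro-diffuse (Nernst–Planck) and are convected by the
water flux. Transmembrane water flow through aquaporins is purely osmotic
(the shared p_w cancels across the membrane); transmembrane ion flow
through channels follows Goldman–Hodgkin–Katz-type kinetics with a
region-dependent sodium permeability: the innermost disc of the cluster
(reference radius R_cl/2) has a 10× larger transmembrane Na+ diffusivity,
mimicking sodium-channel overexpression. Membrane and tight-junction (TJ)
belts at the cluster rim act as thin planar capacitors against the grounded
bath.

Boundary conditions: traction-free rim; IC water/ion fluxes vanish at the
rim (cells do not open to the bath). With TJs absent the EC compartment is
in chemical and electrical equilibrium with the bath (Dirichlet conditions
derived from equal chemical potentials); with TJs sealed all EC exchange is
blocked and the TJ capacitor closes the EC Gauss law. Initial state:
undeformed, unpressurized, zero potentials, Table-value concentrations that
are electroneutral in both compartments and osmotically balanced.

A dissipation-rate functional (bulk flux·force products plus membrane
terms) is evaluated on every accepted step; by construction of the
mobility structure it must be non-negative, and the integrator logs it as a
second-law diagnostic.

## Parameters

Defaults describe an average animal-cell cluster at body temperature and
are registered as the `reference` preset (SI units internally; configs may
tag values with `um`, `kPa`, `cm^3/mol`, ...):
cell radius R_c = 5 µm, membrane thickness 5 nm, cluster radius
R_cl = 500 µm, porosities Φ0 = 0.695 / Φ0^e = 0.005, T = 310 K,
ε_r = 80 (solutions), ε_r^m = 3, ε_r^tj = 30, TJ thickness 500 nm,
v_w = 18 cm³/mol, E = 0.4 kPa, ν = 0.3 (λ ≈ 0.23 kPa, G ≈ 0.15 kPa);
initial concentrations (mol/m³, IC/EC) Na+ 10/145, K+ 140/5, Cl− 10/110,
fixed anion 140/40, giving equal initial osmotic
concentrations of 300 mol/m³ and ≈0.5% diluteness; diffusivities
D_i^e = 1e−9, D_w^e = 1e−7, D_i = 1e−12 and D_w = 1e−9 (GJs open, zero
otherwise), D_w^m = 1e−8, D_Na^m = 1e−18 (1e−17 in the core),
D_K^m = 5e−18, D_Cl^m = 5e−17 m²/s. The sweep ranges exercised by the
tests (D_w^e over 1e−8..1e−6, D_w^m over 1e−12..1e−8, E over 0.4..4 kPa)
follow the benchmark's exploration ranges.

## Discretization

The axisymmetric benchmark depends on the radius only, so the solver is a
1-D Galerkin finite-element code on [0, R_cl] with the measure R dR,
2-point Gauss quadrature, and a graded mesh that always places a node at
the core/annulus interface (the sodium-permeability jump never straddles a
quadrature cell).

Thirteen equal-order P1 nodal fields are solved monolithically: u, p_w, ψ,
ψ^e, C_w^e, three IC and three EC ion concentrations, the out-of-plane
stretch λ_z, and the volume ratio J. Carrying λ_z and J as fields (with
weakly enforced pointwise equations σ_zz = 0 — the plane-stress condition
on the full stress including polarization terms — and J = F_rr F_tt λ_z)
was a deliberate design choice over per-quadrature-point condensation: it
keeps every Jacobian entry an explicit analytic derivative and gives a
consistent first-order gradient of the eliminated IC water concentration,
which the convective flux terms need. The pointwise plane-stress scalar
solve exists separately (`constitutive.plane_stress_condense`) and the two
routes are cross-checked in tests.

All constitutive laws are written once over forward-mode dual numbers
(`mbesim.jet`), so the sparse Jacobian is exact chain-rule differentiation
of the residual code path; tests verify it against central finite
differences to 1e−5 and the pointwise partials to 1e−6. Time integration
is backward Euler (chosen for robustness across the seconds-vs-hours
two-timescale dynamics) with a damped Newton solver: rows are equilibrated
against the column-scaled Jacobian, steps are limited so concentrations
and stretches stay strictly positive (no clamping anywhere — infeasible
trial states reject the step), and a residual backtracking line search
guards the transient. The step size halves on Newton failure and grows
geometrically (cap 1.5×/step by default) on easy convergence; steadiness
is declared when the largest scaled nodal rate falls below 1e−8 s⁻¹ (the
benchmark only states *when* steady state is reached, not a criterion, so
the threshold is this package's own definition).

The Gauss laws are solved with the physical permittivity by default. The
nanometer Debye length is never resolved on a 500 µm mesh — the bulk is
quasi-electroneutral and ψ acts as the constraint multiplier — and a
`permittivity_scale` knob allows raising the bulk ε_r as a conditioning
experiment; a test freezes the observed insensitivity (≈1e−5 relative
output change per decade of scaling, far below 1%).

Degenerate inputs: logarithms carry hard positivity preconditions;
nonphysical volume ratios (IC collapse) raise; NaN/Inf in a residual is
reported with the offending equation row; the mesh builder rejects
non-monotone gradings.

## Verification strategy

The PDE solver is never its own oracle:

* **Closed-form steady states.** With a permeable boundary and no pumps,
  every mobile ion equilibrates with the bath and the impermeant IC anion
  fixes the swollen water content through electroneutrality: the relative
  IC osmotic and water concentrations reach 2.5, the displacement is linear
  in R with u(R_cl)/R_cl = J^{1/3} − 1 ≈ 0.399 (J = 1 + Φ0·2.5 = 2.7375),
  and the uniform p_w balances the network stress. With sealed TJs,
  conservation of each species and of water, equal current concentrations
  across the membrane, and per-compartment electroneutrality give a closed
  linear-plus-ratio system: EC osmotic ratio ≈ 0.287, IC osmotic and water
  ratios ≈ 1.005, J = 1. The time-stepped solution must match these to 1%
  at reduced resolution (16 elements), and does to ~0.1%.
* **Dual-route checks.** Explicit primal-variable fluxes vs the
  Onsager/potential-gradient route (1e−10 relative); GHK/Nernst/Donnan
  closed forms vs the simulator's early-transient potentials; the
  plane-stress field formulation vs the pointwise scalar root.
* **Manufactured solutions.** Smooth axis-regular fields with numerically
  differentiated strong-form sources drive every equation row; interior
  residuals of the interpolant converge at second order (observed rates
  1.9–4.0 between 32 and 64 elements; the test requires > 1.5).
* **Structural invariants.** Onsager symmetry (bitwise), positive
  definiteness, discrete conservation in sealed runs (drift ~1e−13
  relative; requirement 1e−6), non-negative dissipation on every accepted
  step, exact time-rescaling under uniform halving of all diffusivities,
  and bit-identical determinism.

## What the benchmark does and does not show

The scenario definitions *are* the study conditions: parameter values,
the two-region sodium map, and the junction toggles are fixed by the
benchmark, not tuned. Reduced test resolution (16–32 elements,
relaxed output cadence) changes transient profiles by well under the 1%
acceptance band because the steady states are spatially uniform and exactly
representable.

Not modeled, hence not validated here: ion pumps (so the "resting"
potential is a GHK/Donnan balance, not a pump-leak steady state),
voltage-gated or mechanosensitive channel dynamics, genetic/biochemical
coupling, growth, 2-D/3-D geometry, external loads or non-isotonic baths,
deformation-dependent membrane properties, and non-ideal activity
corrections. The transmembrane flux prefactor uses the mean of the
*reference* concentrations as printed in the source equations; at the
benchmark's deformations the distinction from current concentrations is
below the acceptance tolerances, but it would matter at much larger
swelling. The stiff-cluster (plant-cell) regime has no closed-form oracle;
it is exercised only through property checks (pressure ∝ E, swelling
E-insensitive in the compliant regime).
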