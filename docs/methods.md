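# Methods

## Model overview

The package couples three models in one optimization loop: a parametric
two-phase geometry (scaffold solid + granulation tissue in the pores), a
quasi-static Biot poroelastic boundary-value problem, and a
mechano-regulation rule that converts the mechanical state of each pore
element into a predicted tissue phenotype. The design variables are the
coefficients `A_i` of a piecewise-linear pore-radius law `A(y)`; the
objective is the fraction of the scaffold prism predicted to form mature
bone.

The underlying biological assumptions are the standard ones of
stimulus-regulated differentiation modelling: mesenchymal stem cells have
already dispersed through the pores and occupy them as granulation
tissue; their differentiation is governed by the scalar stimulus
`S = γ/a + v/b` built from the octahedral shear strain γ and the
interstitial fluid speed v; the state is read once, at the end of the
1 s load ramp. No temporal tissue evolution, cell proliferation,
angiogenesis or scaffold resorption is modelled — the prediction is the
instantaneous differentiation propensity of the initial state, not a
regeneration time course.

## Geometry and coordinates

The prism has a square `t × t = 2548 × 2548` μm² base and height
`h = 3822` μm. `y = 0` is the loaded (plate) face and `y = h` the clamped
face. Pores are circular channels (constant along x and z), laid out on a
regular lattice; the default 3 × 5 lattice is the densest regular lattice
for which the maximum admissible radius (300 μm) still leaves > 50 μm
walls everywhere. The exact pore count and spacing of the reference
design are not recoverable from its textual description, so both are
configurable (`ScaffoldSpec`). A pore row's radius is the law evaluated
at the row's center height. Layouts violating a configurable minimum
wall thickness (default 10 μm) raise a `GeometryError` naming the
offending row; during optimization such candidates receive a penalty
objective (+10⁶) so the SQP line search can retreat.

Interior breakpoints of the bi-/tri-linear laws default to an equal
partition of `[y_min, y_max]` (halves, thirds) and may be overridden; the
gradient at an interior breakpoint returns the left segment's slope (a
deterministic convention for a point where the law is not
differentiable).

## Meshing

Meshes are Delaunay triangulations of a deterministic point set:
boundary points at the target element size, an interior grid, and rings
of points on every pore circle at a quarter of the element size (the
meshed pore is then the inscribed polygon, whose area deficit
`≈ (2π)²/6n²` vanishes under refinement; grid points hugging a ring are
dropped to avoid slivers). Elements are labelled scaffold/granulation by
centroid. The construction uses no randomness, so identical inputs give
identical meshes. In `coarse_3d` mode the triangulation is extruded
along z and each prism split into three tetrahedra with globally
consistent diagonals, giving a conforming mesh whose volumes sum exactly
to `t·t·h = 24.814 mm³`. The 3D mode serves geometry bookkeeping and
export; the solver itself operates on the 2D plane-strain cross-section,
which is the faithful desk-scale reduction of a geometry that is
constant along z (full 3D poroelastic optimization at 40 μm resolution
is a cluster-scale computation by construction).

## Poroelastic solver

Linear-kinematics Biot poroelasticity, discretized with Taylor–Hood
triangles (quadratic displacements, linear pressure — inf-sup stable) and
backward-Euler time stepping (default 10 equal steps through the 1 s
ramp). The Biot coefficient and storage follow
`α = 1 − K_drained/K_grain` and `1/M = (α−n)/K_grain + n/K_fluid`.
Assembled matrices live in SI units; because the displacement and
pressure blocks then differ by many orders of magnitude, the reduced
system is symmetrically Jacobi-equilibrated before LU factorization
(without this, superposition checks lose ~10 digits). The API speaks μm
and MPa; fluxes are returned in μm/s to match the stimulus constant `b`.

Boundary conditions: bottom face clamped; top-face displacements tied to
rigid-plate master dofs; pore pressure fixed at zero on drained
boundaries (the lateral faces of the scaffold model; the loaded end of
the consolidation column). The plate tie includes a **moment-free
rotation** dof (`u_y = U_Y + θ·(x − x_c)`): a rigid plate loaded by a
force, not by prescribed displacement, is free to tilt. This matters
physically — with rotation locked the shear problem is symmetric in
height and no porosity gradient can be optimal; with the tilt free,
shear produces bending whose stimulus grows toward the clamp, which is
what makes graded porosity pay off under shear.

Load cases: vertical traction 1 MPa (compression), horizontal 0.5 MPa
(shear, half the compression as scaffolds are primarily
compression-loaded), and their vector sum (mixed), each ramped linearly
over 1 s. Reported fields are element-centroid principal strains
(out-of-plane strain identically zero in plane strain), Darcy flux
magnitude `‖−k∇p‖`, and pore pressure.

`v` is interpreted as the Darcy flux; dividing by porosity to get the
intrinsic fluid velocity would scale the flow contribution by 1/n
(≈ 1.25 for the granulation tissue) — with the strain term dominating at
these load levels, this choice does not change any reported ordering.

### Materials

| phase | E (MPa) | ν | k (m⁴ N⁻¹ s⁻¹) | n | K_grain, K_fluid (MPa) |
|---|---|---|---|---|---|
| granulation tissue | 0.2 | 0.167 | 1e-14 | 0.8 | 2300, 2300 |
| scaffold | 500 / 1000 / 1500 | 0.3 | 1e-14 | 0.5 | 2300, 2300 |

The scaffold's transport properties are not part of the reference
parameter set (only its Young's modulus is); the values above are
typical of biphasic scaffold models and are configurable.

### Verification

* Drained patch test: uniaxial drained compression of a homogeneous
  block with ν = 0 reproduces the closed form ε = σ/E to 1e-6 relative;
  a transient solve with high permeability converges to the drained
  solution.
* Terzaghi consolidation: a laterally constrained column with an
  effectively instantaneous load matches the analytical series — with 60
  elements and 240 geometrically spaced implicit steps the isochrones at
  T_v ∈ {0.1, 0.5, 1.0} agree to better than 0.7% of the undrained
  pressure, and the mid-column Darcy flux matches the differentiated
  series to ~2%. Remaining error is first-order time discretization.
* Exact load linearity and compression+shear superposition (direct
  solver, machine precision after equilibration).

## Mechano-regulation

Constants: `a = 0.0375` (3.75% stored as a fraction so strain divides
correctly), `b = 3` μm/s, band boundaries `n_resorb = 0.01`,
`n_mature = 0.53`, `c = 3`. The band inequalities are strict, which
leaves the boundary values undefined; bands are implemented lower-closed
(`S = n_mature` → immature bone, `S = 0` → resorption) — a deterministic
measure-zero convention. Stimulus and phenotype are computed only on
granulation elements.

## Optimization

SLSQP over the coefficient vector, bounds `[5, 300]` μm, operating on
normalized coordinates `z = (A−5)/295` (the objective is in BO-percent
units while the variables are in μm; without normalization the
unit-Hessian first step is ~0.1 μm and the loop stalls). Gradients are
forward differences with a 5 μm step — large relative to remeshing noise
(each candidate is remeshed, so Ω is piecewise-noisy); for smooth
surrogate objectives in tests a 0.1 μm step is used instead. Stopping:
objective tolerance 1e-2 BO-points, step tolerance 1 μm (enforced by an
iterate-tracking callback, since SLSQP exposes no native step
criterion), and an iteration cap. Multistart from uniform 50/150/250 μm
vectors; the factorial driver additionally seeds every richer law with
the poorer laws' optima re-sampled at the richer family's breakpoints.
Because a constant law is exactly representable in every richer family
and the best-of-history iterate is returned, the optimal graded BO% can
never fall below the optimal homogeneous BO%.

## Scaled-down study conditions

The desk preset uses the 2D cross-section with a 200 μm target element
size (~1100 triangles, one design evaluation ≈ 0.2 s), 10 ramp steps,
multistart plus nesting seeds, and ≤ 15 SQP iterations per start; the
full slice at E = 1000 MPa (3 loads × {constant, tri-linear}) runs in
about a minute. These sizes preserve the qualitative structure —
trilinear ≥ constant BO% for every load, PVPD(shear) ≫
PVPD(compression), non-increasing shear profile, mixed load lowest BO% —
but absolute BO% values are not comparable with full-resolution 3D
optimizations: a coarse mesh resolves only a few elements per pore, the
2D reduction changes drainage paths (closed pore cross-sections drain
through the scaffold rather than along the channel axis), and plane
strain stiffens the response relative to 3D.

## What the synthetic fixtures do and do not show

The consolidation column and patch block are analytical-oracle fixtures:
they validate the coupled solver's physics, units and boundary handling
against closed forms. They do not exercise two-phase material contrast
or pore-scale geometry; those paths are covered by the mesh-convergence
and study-ordering tests, which are themselves subject to the
desk-scale caveats above.

## Known limitations

* 2D plane-strain solve; the 3D mode is geometric only.
* Linear kinematics and linear materials (consistent with the listed
  material data and load levels; no contact or large sliding).
* The pore lattice, scaffold transport properties and interior
  breakpoint positions are package defaults where the reference design
  leaves them unstated.
* BO% uses the full prism volume in its denominator, so it is bounded by
  the granulation fraction — by design.
* SLSQP on a remeshed objective finds local optima; multistart and
  nesting seeds mitigate but do not guarantee global optimality.
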