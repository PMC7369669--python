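# Methods

This note records the model, the numerical choices, and the reasoning behind
the places where the design was genuinely open.  Everything quantitative
stated here is computed by the test suite or the acceptance script; nothing
is asserted that the code does not reproduce.

## Model

The homogenized two-phase description treats blood (volume fraction
σ = 0.03) and tissue (1−σ) as coexisting continua.  States are the blood
oxygen concentration φ (free + hemoglobin-bound) and the tissue
concentration θ, both in mM, on a single 2D domain:

    ∂φ/∂t − α Δφ + v·∇φ = a (θ − g(φ)),
    ∂θ/∂t − β Δθ        = −κ a (θ − g(φ)) − μ(θ),      κ = σ/(1−σ).

The exchange term is driven by the *plasma* concentration ψ = g(φ), the
inverse of the Hill relation f(ψ) = ψ + b ψ^r/(ψ^r + c), c = ψ_H^r.  Oxygen
consumption follows Michaelis–Menten kinetics μ(θ) = μ₀ θ/(θ+θ₅₀).  Both f
and μ are extended to negative arguments as odd functions, so transient
undershoots of the discrete solution remain well defined; no positivity
clamping is applied, and field minima are reported in the diagnostics.
Robin conditions α∂ₙφ + γ(φ−φ_b) = 0 and β∂ₙθ + δ(θ−g(φ_b)) = 0 hold on
every boundary piece; the tissue ambient value is *derived* from φ_b
through g, never set independently (except in the manufactured-solution
harness, which needs a free ambient).

Baseline parameters (mm / s / mM units): α = 2.2·10⁻³ mm²/s,
β = 2.4·10⁻³ mm²/s, a = 39 s⁻¹, b = 9.2 mM, ψ_H = 0.036 mM, r = 2.73,
μ₀ = 0.08 mM/s, θ₅₀ = 5·10⁻⁵ mM, γ = 1000α, δ = 1000β.  Boundary ambient
blood oxygen: 9.2 mM at inlets, 8.2 mM at outlets *and on the outer square
edges* (the outer edge carries the venous value).  The hypoxia-recovery
experiment starts from φ₀ = 4 mM, θ₀ = 0.01 mM.

## Geometry

The domain is a 1.8 mm square with 64 circular holes (radius 0.03 mm by
default): 32 arteriolar inlets and 32 venular outlets.  Published
descriptions of this configuration give only counts, area and mesh density,
not hole coordinates, so the package generates them deterministically: a
checkerboard 8×8 grid with alternating classes, spacing 0.225 mm — close to
the physiological mean inlet–outlet separation (m/(ρN))^(1/3) ≈ 0.25 mm for
N = 76.8·10⁶ junctions in a 1200 g brain at 1.04 g/cm³.  A `jittered`
layout (seeded) exists to probe sensitivity to the arrangement.  The hole
radius is likewise unpublished; 0.03 mm is a capillary-ostium scale that the
default mesh density resolves with 8 boundary segments per hole.

Meshing is self-contained: boundary points of the square (60 segments per
side by default) plus an interior structured cloud at the same spacing and
the hole polygons are Delaunay-triangulated (scipy/Qhull), and triangles
inside holes are discarded.  Each hole center is included as a helper point
so the interior of each polygon triangulates as a fan that is removed
cleanly; grid points within ~0.45 local spacings of a polygon are dropped to
avoid slivers.  Hole polygons place their vertices at the *area-preserving*
radius r·sqrt(2π/(n sin(2π/n))) so the mesh area equals the true domain
area side² − Σπr² to rounding; an `inscribed` mode (vertices exactly on the
circle, area deficit ∝ 1/n²) is kept for convergence studies of the
polygonalization error.  The resulting boundary partition is validated
exactly: 4·60 outer segments plus 64·8 hole segments, each tagged
edge/inlet/outlet; any mismatch raises a geometry error rather than
producing a silently wrong mesh.

## Velocity pre-solve

The convective field is a steady Stokes flow with Dirichlet data:
(0, 0.6) mm/s on the outer square, normal inflow at 3.4 mm/s on inlet rims,
normal outflow at 1.7 mm/s on outlet rims.  With equal rim perimeters these
data carry a nonzero net flux, so the incompressible problem is unsolvable;
the package uses a pressure-penalty (slightly compressible) formulation
∇·v + ε p = 0 with ε = 10⁻⁶ by default, treating the Stokes stage as a
generator of a plausible example field rather than a mass-consistent
hemodynamic solution.  (A flux-balancing rescale of the outlet speed would
be an alternative; it is not the default because it would silently change
the stated boundary speeds.)  Discretization is equal-order P1/P1 with
Brezzi–Pitkaränta pressure stabilization (coefficient 0.05·h²_T), which
avoids a second element family in the code base; the element choice and BC
summary are recorded in the field's metadata.  The solution is linear in
the boundary data (checked to 10⁻⁸), attains its maximum speed 3.4 mm/s on
the inlet rims, and keeps more than half of the domain area inside the
physiological 0.3–1.7 mm/s band (area measured by element-centroid
quadrature).

## Transport discretization

P1 Galerkin in space (mass, stiffness, Robin boundary mass, and the
convection form v·∇φ assembled in non-divergence form with quadrature exact
for quadratics), backward Euler in time with dt = 0.25 s over a 10 s
horizon.  Backward Euler was chosen for its unconditional stability at this
dt; no convection stabilization is applied because the element Péclet
number at the default resolution is modest.

The two nonlinearities are resolved by a fixed number (default 20) of
semi-implicit sweeps per step:

* g(φ) enters through its chord at the current iterate,
  g(φ) ≈ g(φᵏ) + g′(φᵏ)(φ − φᵏ), with g′ = 1/f′(g) evaluated analytically.
  A purely lagged g is *not* contractive for this problem: near the inlets
  a·dt·g′ ≈ 2.7, and the lagged iteration locks into a two-cycle with
  relative increments around 10⁻³ instead of converging.
* μ(θ) uses the classical lagged-denominator form
  μ ≈ μ₀ θ/(θᵏ + θ₅₀), which preserves the sign of θ and converges through
  the half-saturation knee θ ~ θ₅₀, where a full Newton chord on μ
  oscillates.
* The linear exchange and Robin couplings stay implicit.  Each sweep solves
  tissue first, then blood with the fresh tissue iterate, then refreshes
  tissue against the new blood field (a symmetric Gauss–Seidel sweep); this
  refresh roughly halves the sweeps the φ↔θ coupling needs and brings the
  20-sweep increment below 10⁻⁸ of the state norm even on the first,
  hardest step (later steps reach ~10⁻¹⁵ and the loop exits early once
  increments hit rounding level, where further sweeps are no-ops).  A
  divergence guard aborts the step with a suggestion to reduce dt.

Optional nodal source terms on both equations exist solely for the
manufactured-solution harness and are zero in the physical model.

With the σ-weighted sum of the two equations the exchange terms cancel
exactly in the discrete system (both use the same mass matrix and the same
lagged g), so in the closed configuration (γ = δ = 0, v = 0) the total
oxygen ∫σφ + (1−σ)θ decreases per step by the consumed amount
(1−σ)∫μ(θ)·dt up to the sweep residual; the suite checks a relative budget
error ≤ 10⁻⁴ per step.

## Executable a-priori estimates

The energy estimate and the uniqueness contraction bound of the continuous
model are evaluated on every run:

* Coercivity constants k₁, k₂ of A₁ = α·stiffness + γ·boundary-mass and A₂
  are computed as the smallest generalized eigenvalues against the discrete
  H¹ matrix M + K (shift-invert Lanczos, dense-solver cross-checked in the
  tests).  For the baseline configuration k₁ ≈ α, as expected when the
  Robin coefficient is large and holes are dense.
* C₁ = ‖φ₀‖² + ‖θ₀‖² + T·[(2/k₁)‖f₁‖²_* + (1/k₂)‖f₂‖²_*], with dual norms
  via Riesz representation (solve (z, ·)_V = f, take ‖z‖_V); the loads are
  time-constant so the time integral is T times the value.
* C₂ = (2/k₁)‖v‖²_∞ + a(1+κ) and C₃ = (1/(4k₁))‖v‖²_∞ + a/2, with ‖v‖_∞
  taken as the maximum nodal speed (P1 fields attain extrema at nodes).
* The energy check verifies, at every stored time with trapezoid
  quadrature, ‖φ‖² + ‖θ‖² + ∫(k₁‖φ‖²_V + k₂‖θ‖²_V) ≤ C₁ + C₂∫(‖φ‖²+‖θ‖²).
* The contraction check verifies for two runs differing only in initial
  data that ‖δφ(t)‖² + ‖δθ(t)‖² ≤ D₀·exp(2(C₃ + κa/2)t).  The source
  typesetting of the underlying differential inequality is ambiguous about
  the grouping of the rate constant; the implementation uses
  2(C₃ + κa/2) on the squared sum, and the report flags this convention.
  With the baseline constants the rate is so large that the bound is
  informative only at early times; the non-vacuity of both checks is
  demonstrated with constructed counterexamples in the tests (halved C₁,
  stripped exponential factor).

The stabilization time reported for a field is the earliest stored t* such
that ‖u(t+dt) − u(t)‖_{L²}/(dt·‖u(T)‖_{L²}) ≤ ε for all later steps, with
ε = 0.01 s⁻¹ by default; published stabilization windows come without a
formal criterion, so this definition (and ε) is echoed into the output
metadata to keep the numbers auditable.  On the baseline run the tissue
field settles at 4.25 s and the blood field at 1.5 s, inside the expected
6–7 s / 3–4 s windows; the exact values depend on the reconstructed hole
layout, which is why the windows, not point values, are the contract.

## Inverse-Hill table

g is tabulated once per run: knots in φ, each ψ-knot obtained by bracketed
Brent root solving of f(ψ) = φ on [0, φ] (valid since g(λ) ≤ λ), tolerance
10⁻¹² mM, interpolated by a natural cubic spline, clamped with a logged
warning up to 5% beyond the table range and an error beyond that.  The knot
grid is *quadratically graded* toward φ = 0 with 800 knots by default over
[0, 12] mM: near zero the inverse curve behaves like φ − (b/c)φ^r with
b/c ≈ 8·10⁴, giving near-singular curvature, and a uniform grid of a few
hundred knots leaves ~10⁻³ mM interpolation error there and at the upper
saturation knee (φ ≈ 9.3 mM).  The graded default brings the measured
round-trip error |g(f(ψ)) − ψ| below 10⁻⁶ mM over the physiological range
(measured ≈ 2·10⁻⁷).  The discrete table preserves the analytic bounds
0 ≤ g′ ≤ 1 and |g(λ)| ≤ |λ| up to interpolation tolerance, and the tests
sample them.

## Verification design

* **ODE oracle.**  The spatially homogeneous reduction φ′ = a(θ − g(φ)),
  θ′ = −μ(θ) − κa(θ − g(φ)) is integrated with Radau (rtol 10⁻¹⁰) and g
  evaluated by per-call root solving — independent of the spline table and
  of the FEM path.  On a hole-free square with no flow and no flux the FEM
  solution must track it with an O(dt) gap; the suite checks the bound and
  the ∝dt shrinkage.
* **Manufactured solutions.**  The *plasma* field ψ_e is manufactured
  symbolically and φ_e := f(ψ_e), so g(φ_e) = ψ_e in closed form and all
  sources and Robin ambient data come from sympy differentiation — no
  numeric inversion contaminates the oracle.  The spatial order (2) is
  measured with a *steady* manufactured pair driven to the discrete steady
  state by a few huge time steps, which removes the temporal error
  entirely; the temporal order (1) with a *spatially uniform* pair, for
  which the spatial error vanishes identically.  Mixed ladders (dt ∝ h²)
  were found to confound the fits at practical resolutions because the two
  error floors cross inside the ladder.

## Synthetic data and scope

There is no external data: the geometry generator *is* the experiment's
data source, and its defaults encode the study conditions (domain size,
hole counts and density, mesh resolution, boundary and initial values).
What it does not emulate: the true (unpublished) hole arrangement, vessel
radii distributions, 3D effects, pulsatile or oxygen-dependent blood flow,
and Bohr (temperature/pH) corrections to the Hill curve.  Passing tests
therefore demonstrate correctness of the solver and the internal
consistency of the model under the stated conditions — not agreement with
in-vivo measurements.

Problem sizes used by the shipped tests: the full baseline mesh has ≈3850
vertices (7072 triangles); unit tests use a structurally identical 0.9 mm /
16-hole domain and coarse unit squares.  The §-scale baseline run completes
in well under a minute on one core.

## Known limitations

* The Stokes field is a penalized example flow, not a mass-conserving
  network hemodynamics solution; net in/outflux is absorbed by the penalty.
* Consistent-mass P1 with backward Euler does not satisfy a discrete
  maximum principle; small over/undershoots can occur near steep fronts
  (they are reported, not clamped, and the odd extensions keep the
  nonlinearities well defined).
* The diffusion-time helper L²/(cD) keeps c configurable: no standard
  convention reproduces every published travel-time figure from the printed
  L and D, so the constant is left to the user (default c = 1 gives 0.167 s
  for L = 0.02 mm, D = 0.0024 mm²/s).
* 3D geometry, vascular-tree topology, adaptive time stepping and Newton
  linearization are out of scope.
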