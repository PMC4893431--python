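# Methods

This note documents the model, discretization, numerical choices and
calibration behind `lvflow`, and what the synthetic phantom does and does
not demonstrate about real data.

## Problem and model

The quantity of interest is the full velocity field **v**(x, t) of blood in
the left ventricle over a cardiac cycle.  Colour-Doppler ultrasound
measures only the projection 𝒟 = **a**·**v** on the beam direction; the
beam is taken along the x axis, so 𝒟 = v₁.  Blood is modelled as an
incompressible Newtonian fluid (ρ = 1050 kg/m³, μ = 0.00316 Pa·s), and the
beam projection of the momentum equation together with incompressibility
gives a per-frame linear system in the two unmeasured components (v₂, v₃):
a "momentum row" diag(∂y𝒟)v₂ + diag(∂z𝒟)v₃ = f₁(𝒟, ∂t𝒟, p) and a
"continuity row" ∂y v₂ + ∂z v₃ = −∂x𝒟.  Boundary conditions: prescribed
wall velocity (Dirichlet) on the myocardial wall Γʷ, vanishing normal
derivative (Neumann) at the valve openings Γᵘ — valve leaflet motion is
ignored and the valves are modelled as short pipe-type extensions with
elliptic (mitral) and circular (aortic) cross-sections.

## Discretization

* Uniform nx×ny×nz grid, spacing h equal in all axes; node ordering is
  x-fastest (`ravel(order="F")`), used consistently by every operator.
* Full-grid operators are Kronecker products of 1-D central-difference
  matrices (tridiagonal, zero-padded at grid ends); ≤7 nonzeros per row.
  First derivatives are exact on linear fields, the Laplacian on
  quadratics.
* Inside the irregular moving domain, stencils that would cross the
  discrete boundary are closed per 1-D run of inside nodes: second-order
  one-sided differences by default (−3,4,−1)/2h and (2,−5,4,−1)/h², or
  mirrored (even-reflection) ghosts via `scheme="mirror"`.  Degenerate
  runs fall back gracefully: a 2-node run uses first-order differences
  (first derivative) and a zero row (second derivative); a single-node run
  gives zero rows.  These fallbacks only occur at extreme staircase
  tangency; operator-accuracy checks therefore quantify convergence on the
  eroded interior, where the full stencil applies.
* Boundary nodes are inside nodes with an outside 6-neighbour.  Outward
  unit normals come from the negated gradient of a Gaussian-smoothed
  (σ = 1.5 cells) indicator function, with an axis-toward-outside fallback
  for degenerate nodes.
* Dirichlet rows are enforced by row substitution (identity row, datum in
  the right-hand side); valve Neumann rows by one-sided n·∇ stencils
  (second order into the interior where two neighbours exist, first order
  otherwise; isolated nodes are pinned).

## Pressure

The pressure satisfies ∇²p = −ρ∇·((v·∇)v).  Two discrete treatments are
provided:

* **Gradient matching (default, `pressure_bc="consistent"`).**  The
  momentum balance defines the full pressure gradient
  G = ρ(ν∇²v − ∂tv − (v·∇)v); the discrete pressure is the weighted
  least-squares fit of its face differences to G averaged onto faces,
  min_p Σ_faces w((p_j−p_i)/h − G·e)².  The normal matrix is the symmetric
  finite-volume Neumann Laplacian (graph Laplacian with transverse
  face-area weights); the face data impose the physically consistent
  Neumann condition ∂p/∂n = G·n weakly.  Only the beam component of ∂tv is
  measurable; the transverse acceleration is supplied by the outer
  time-coupling pass (below) and set to zero on the first pass.
* **Zero-flux (`pressure_bc="homogeneous"`).**  The classical ∂p/∂n = 0
  closure with the pointwise divergence right-hand side.  This matches
  forward data generated under the same zero-flux wall condition, but for
  data from an arbitrary Navier-Stokes flow the condition is wrong at the
  wall: on the reference phantom it inflates the pressure error from
  ≲1% to tens of percent, which then contaminates the momentum row.

Both solvers handle the constant nullspace by projecting the right-hand
side onto the compatible subspace and gauge-fixing the solution to zero
mean over the mask; the inner conjugate-gradient solve is Jacobi-
preconditioned and runs to `linear_solver_tol` (default 1e-8).  On a box
the manufactured cosine solution is recovered at observed order ≈ 2.0.

## Regularization and iteration

The momentum-row coefficients |∇𝒟| vanish on interior sets, so S has small
singular values and the raw least-squares solution amplifies any data or
model inconsistency.  The damped update
vⁿ⁺¹ = vⁿ + (SᵀS + λ²_eff I)⁻¹Sᵀ(f − Svⁿ) controls this.

* **λ² is dimensionless.**  The data term mixes physical units (momentum
  rows in m/s², continuity rows in 1/s) while the penalty is in m/s, so an
  absolute λ² is meaningful only within one fixed scaling.  The package
  applies λ²_eff = λ² · mean(diag(SᵀS)) (`regularization="scaled"`;
  `"absolute"` is available), making the damping relative to the
  operator's energy and independent of grid spacing and unit system.
* **Calibration.**  The default λ² = 1e-2 is fixed, once, at the interior
  minimum of the cycle-error-versus-λ² curve on the reference phantom —
  the same sweep-and-pick procedure that originally set the method's
  operating point.  The sweep (`lvflow sweep`) is U-shaped: under-damped
  runs amplify the momentum-row inconsistency (errors grow by orders of
  magnitude at λ² ≤ 1e-5), over-damped runs freeze the iterate at the
  initial guess.
* **Pressure update.**  Re-solving the pressure from every new iterate
  (`pressure_update="every_iteration"`) is the textbook alternation, but
  the pressure feedback is quadratic in v and the loop gain exceeds one
  whenever the data carry percent-level momentum inconsistency — the
  alternation then diverges at every λ².  The default
  (`pressure_update="frozen"`) solves the pressure once from the initial
  iterate and converges unconditionally; for discretely consistent data
  (e.g. the decaying Beltrami flow, whose momentum residual is at rounding
  level) the two strategies coincide to solver tolerance.
* **Time coupling.**  `reconstruct_cycle` runs
  `time_coupling_passes` (default 2) passes over the cycle: pass one
  reconstructs each frame with zero transverse acceleration; later passes
  re-estimate ∂v₂/∂t, ∂v₃/∂t by periodic central differences across the
  previous pass's reconstructions and repeat the frame solves with the
  completed pressure datum.
* **Stopping.**  ‖vⁿ⁺¹−vⁿ‖₂/‖vⁿ‖₂ < `stop_tol` (default 1e-2); the
  absolute update norm is used when the iterate is zero, so the zero-data
  problem converges in one iteration.  `max_iter` (default 50) caps the
  loop; non-convergence returns the fields with a flag rather than
  raising.
* **Inner solver.**  (SᵀS + λ²_eff I) is solved by sparse LU (cached per
  frame and λ²) up to `direct_threshold` unknowns, and by Jacobi-
  preconditioned CG above it; the two paths agree to solver tolerance and
  both match dense solves on small grids to 1e-6.

## Initial guess

Assuming the vorticity has no component along an in-plane direction
d = (d₁, d₂, 0) through both valves, cross-differentiating that constraint
with continuity yields a block-triangular elliptic system: first
(d₁Lyz − d₂DxDy)v₃ = −(d₂DyDz + d₁DzDx)𝒟, then
d₁Lyz v₂ = (d₂Lzz − d₁DxDy)𝒟 − d₂DzDx v₃, with the same wall/valve rows
substituted.  The system was re-derived from the constraint; with the
default d = (1, 0, 0) all d₂ terms vanish and the solves reduce to
per-x-slice Poisson problems.  d₁ = 0 is rejected (singular v₂ operator).
A least-squares heuristic (`estimate_d=True`) fits d to minimize the
in-plane vorticity of a provisional guess, but is off by default.  For a
vortex aligned with the beam axis the constraint is exact and the guess is
accurate to discretization (≈5% at 28³); the default phantom tilts the
vortex axis 25° so the constraint — like in any oblique inflow — is only
approximate, and the iteration measurably improves on the guess.

## Dual-beam closed form

With a second beam a₂ ≠ a, the 2×2 matrix of in-plane Doppler gradients
per node inverts the momentum projections directly, without boundary data.
Nodes whose determinant falls below `det_rel_threshold` (default 0.02)
relative to the 90th-percentile scale are solved with a Tikhonov 2×2
pseudo-inverse; if their fraction exceeds `max_singular_fraction` (0.25)
the inversion is rejected (constant fields fail this way, as they must).
On the Beltrami solution with exact pressure and analytic ∂t𝒟 the
root-mean-square recovery error falls ≈5× when the grid is halved.

## Contour tracking and lofting

Tracking minimizes, jointly over all 2n point displacements, the
Lucas-Kanade data term over a k×k neighbourhood per point plus
λ̃‖(I−P)(x+v)‖², where P is the hat matrix of the affine design
[x(0), y(0), 1] — i.e. deviation from the best-fit affine motion of the
initial configuration.  The quadratic is minimized exactly by one dense
2n×2n solve; by default 3 warp-and-resolve sweeps reduce linearization
error (`n_refine`).  Images are presmoothed with a Gaussian (σ = 1 px)
before central-difference gradients.  Neither the neighbourhood size nor
λ̃ is prescribed by the problem; defaults are k = 9 and λ̃ = 1.  Larger λ̃
interpolates toward pure affine motion (the λ̃→∞ limit reproduces an
affine fixture to <0.25 px); λ̃ = 0 fails on textureless patches with an
explicit error.  Sub-quarter-pixel accuracy on speckle fixtures holds for
λ̃ within a few orders of magnitude of the default; k mainly trades noise
robustness against locality.

Closed contours are periodic cubic splines through the tracked points
(chord-length parameterization), exact at the knots.  Two orthogonal
contour stacks sharing the long (x) axis are lofted by elliptic azimuthal
blending: at each height the cross-section is the ellipse whose y- and
z-extents match the two planes' contours.  Pipe-type valve openings are
appended at the basal cap; their end caps are valve-labelled, their side
walls wall-labelled.  Voxelization reproduces analytic volumes and areas
to a few percent at ≈50³ and re-extracting the mid-plane contour returns
the input within one voxel.

## The phantom: what it emulates, and what it does not

The phantom replaces a fluid-structure-interaction forward simulation as
the source of ground-truth data.  It emulates: a chamber-filling vortex
(interior Hill spherical vortex, radius equal to the long semi-axis so
speeds stay within the physiologic ≈1.2 m/s), oblique to the beam (axis
tilted 25°, as transmitral inflow is); cardiac-cycle dynamics through a
periodic drift of the vortex along its axis (amplitude 8 mm — the
apically propagating inflow ring) and through an ellipsoidal mask whose
volume follows a C¹ periodic curve with 70 mL stroke volume, 120 mL
end-diastolic volume, 60 min⁻¹ heart rate and diastole fraction 0.6,
sampled at 10 frames; valve openings with realistic mitral/aortic
dimensions and short pipe extensions; beam projection with optional
Gaussian noise.

Two design points matter for interpreting results:

* **The flow is an exact Navier-Stokes solution.**  The drifting Hill
  vortex is a Galilean/accelerating-frame boost of a steady exact
  solution, with a known polynomial pressure (plus the −ρẍ_c·x inertial
  term).  An amplitude-*modulated* vortex is *not* a solution — the
  rotational part of ∂v/∂t has no absorbing pressure — and feeding such
  non-physical data into the inverse model injects an irreducible
  momentum-row error that no real measurement of a real flow would
  contain.  Modulation is therefore an off-by-default stress option
  (`amplitude_modulation`), not part of the reference conditions.
* **Wall kinematics are not coupled to the flow.**  The mask moves with
  the volume curve while the analytic flow does not follow the wall; the
  Dirichlet data used by default are the true velocities sampled at the
  wall (`wall_bc="exact"`), with the average-speed alternative
  v̄ = (dV/dt)/A available (`wall_bc="average_normal"`).  Consequently the
  phantom validates the solver's recovery of an exact flow from exact
  data; it does not test robustness to segmentation error, Doppler
  aliasing/noise (unless enabled), or genuine flow-wall interaction.

Other analytic fields: a 3-D trigonometric Taylor-Green-type flow and the
Hill polynomial are *discretely* divergence-free to rounding (polynomial
exactness; equal-wavenumber cancellation), so divergence convergence is
checked on the generic Gaussian jet-with-ring field instead.  The decaying
Beltrami (ABC) flow is the exact *unsteady* solution used wherever full
Navier-Stokes consistency is needed (pressure validation, dual-beam
refinement).

## Error metrics

Relative L2 errors are computed over inside-mask nodes, unweighted by cell
volume (uniform h makes the weight a constant), per frame and aggregated
over the cycle as √(Σ_t‖Δv‖²)/√(Σ_t‖v f‖²).  Vorticity is the discrete
curl via the masked operators.  Global energy discrepancies are
|‖v f‖−‖v r‖|/‖v f‖ and the analogue for vorticity; by the reverse
triangle inequality each is bounded by the corresponding pointwise error,
which is asserted on every reported frame.  Per-frame rows are keyed by
t/T.  A vanishing reference norm raises by default; report generation maps
an exactly-zero pair to zero error so the zero-amplitude phantom yields an
all-zero report.

## Problem sizes and runtime

The reference experiment runs on a 32³ grid (≈1000–2500 inside nodes per
frame depending on cycle phase) with 10 frames and two time-coupling
passes, in a few seconds on one CPU; convergence studies use grid pairs
(16³, 32³) and (20³, 40³).  The full test suite runs in well under a
minute.

## Known limitations

* Staircase (voxel) boundary: boundary closures are locally first order;
  wall-adjacent accuracy, not interior accuracy, limits the pressure and
  the reconstruction at coarse h.
* The momentum row informs (v₂, v₃) only where ∇𝒟 is appreciable;
  elsewhere recovery relies on continuity, boundary data and the damping —
  small-scale vortical detail is smoothed accordingly (vorticity errors
  ≈3× velocity errors).
* Ten frames per cycle make ∂t𝒟 a coarse central difference; its sampling
  error is a visible but subdominant part of the budget.
* The paper-style alternating pressure update is provided but diverges for
  inconsistent data (see above); the frozen/two-pass strategy is the
  supported default.
* No turbulence, non-Newtonian rheology, valve leaflets, or real
  ultrasound physics (speckle decorrelation, aliasing, beam geometry).
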