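# Methods

This note records the model, the numerical choices, and what the synthetic
study conditions do and do not establish.

## Model overview

The tissue is represented twice. A closed triangle mesh bounds it and is
the object cut operations act on; the volume behind it is a set of
independent point elements with positions, masses, volumes, displacements
and velocities, produced by equal-distance interpolation: an axis-aligned
lattice with the requested spacing, anchored at the model's minimum corner
(boxes) or centre (ellipsoids) and clipped to the solid. Each lattice point
carries volume spacing³ and mass density·volume. Density defaults to
1 g/mm³ and is configurable; nothing downstream depends on its absolute
scale except the time-step stability margin.

### Surface incision

The scalpel is two points (tip P, handle P′) plus a vertical unit
direction; the blade plane contains both points and is perpendicular to
the tissue surface, normal n̂_b ∝ (P′−P) × v̂. Collision detection is
replaced by analytic intersection: mesh edges crossing the blade plane are
snapped to their nearest endpoint, filtered to the region above the
cut-bottom plane and to the swept extent of the trajectory, ordered along
the in-plane sweep direction, and stitched into an edge-connected chain
(shortest-path splices fill gaps; a revisited vertex aborts with an
unsupported-path error).

The incision is two quadratic Bezier curves through the chord endpoints
A, B and, per side of the chord, the affected vertex farthest from the
chord line. Side membership and distances are evaluated in the tangent
plane of the affected region (projection along its area-weighted average
normal); on-chord points count as positive, distance ties resolve to the
lowest vertex index, and an empty or collinear side degenerates its control
point to the chord midpoint (that curve collapses onto the chord). Curves
are evaluated in Bernstein form so the endpoints interpolate exactly.

Retriangulation opens the wound by (a) duplicating interior path vertices
and rebinding the triangles on the negative side of the chord to the
duplicates, which separates the surface along the path, and (b) inserting
the sampled curve points and bridging each separated path chain to its
polyline with a monotone "zip" strip, which makes the polylines the free
boundary. For a two-vertex path the shared chord edge ends up inside the
wound with four incident triangles; this local non-manifoldness is
confined to the wound interior, and all boundary bookkeeping (loop count,
ordered polyline boundary, positive triangle areas, untouched non-incision
boundary) remains exact. A zero-width two-vertex cut returns the mesh
unchanged.

### Level-set classification

φ is the signed distance to the blade plane and ψ the signed distance
above the plane through the blade's lowest cut point (the stored plane
normal is −v̂, the outward normal of the unaffected half-space; ψ is
measured along +v̂ so affected points have ψ > 0). Points with ψ ≤ 0 are
unaffected and skipped entirely; ψ > 0 splits by the sign of φ into the
"+" and "−" regions. Exactly-on-plane ties: φ = 0 goes to "+", ψ = 0 is
unaffected. Because the blade moves rigidly, the advection equation
φ_t + v·∇φ = 0 is solved exactly by recomputing plane distances from the
current pose each step; a first-order upwind grid solver exists only as a
test oracle and confirms the recomputation to O(grid) under rotating
poses.

### Meshless elasticity

The offset convention is x_ij = x_i − x_j in the stored neighborhoods, but
the exposed displacement gradient is the sign-corrected physical one (it
reproduces any affine field with gradient exactly A), and the pair-force
term uses the neighbor-pointing offset x_j − x_i. With the literal
stored-offset signs the gradient of an affine field comes out negated,
stretching produces anti-restoring forces, and rigid rotations generate
spurious strain; the corrected convention restores all three properties
and is the one the acceptance suite pins down. The quadratic Green-strain
term is ∇Uᵀ∇U — the only reading that annihilates rigid rotations.

The kernel is the compactly supported C² polynomial (1 − (r/h)²)³ with
h = 2.2× the lattice spacing by default (~10–20 interior neighbors). The
moment matrix is Tikhonov-regularized with ε = 1e-9·tr(M)/3 when its
condition number exceeds 1e8 or a point has fewer than 4 neighbors; such
points are flagged and behave rigidly in degenerate directions.

**Support severing.** When a region is cut, kernel supports must not span
the wound: neighbor pairs whose side labels ("+" vs "−", for real and
virtual points alike) have negative product are dropped before moment
matrices are assembled. Without this the two halves remain elastically
glued and the wound cannot open; with it both halves stay connected to
the neutral (unaffected) tissue around the cut bottom, which is what
anchors them.

Integration is semi-implicit (symplectic) Euler: v ← (1−c)(v + Δt f/m),
U ← U + Δt v, x ← rest + U. The damping factor c is an artifact extension
(default 0); positions never accumulate drift because they are always
rebuilt from rest positions.

### Coupling

Virtual points are generated per incision-boundary polyline edge at
uniform interpolation weights, tagged by side, and prescribed the
displacement ±opening_scale·s(t)·n̂_b where s(t) is half the local
separation of the two polylines at matched curve parameter — so the
prescribed openings are exactly equal and opposite across the blade plane
and vanish for degenerate (chordal) cuts. They enter the solve as ordinary
neighbors with held displacements and zero velocity, are excluded from
momentum bookkeeping, never render, and are regenerated at every scalpel
pose. The mapping from incision width to opening displacement is a modelling
choice (the geometry itself fixes only the curve shapes); the
polyline-separation rule makes the interior deformation track the surface
incision by construction.

### Haptics

Γ(t, d) = e^(−at) sin(bt)·k·d with defaults a = 1 s⁻¹, b = 2π rad/s,
k = 1 (Υ(d) = k·d is the simplest linear depth law with zero feedback at
zero depth; a and b would come from experiment data and are
config-exposed). The recorded feedback series is the summed reaction force
on the virtual points scaled by Γ; the per-point form f_i·Γ is also
exposed. The empirical double-Gaussian force–displacement fit uses the
printed coefficients; RMSE is √(Σ(f−f*)²/N).

## Study conditions and their rationale

The defaults were chosen once, on physical grounds, and define the test
and acceptance conditions:

- **E = 3000 Pa** — soft-tissue (liver) order of magnitude.
- **dt = 1e-3 s, c = 0** — the paper-faithful undamped integrator; stable
  for the default box models (verified by a 300-step stretched-box sweep).
- **Quasi-static cutting runs: dt = 0.02 s, c = 0.35, opening ramp 0.1 s** —
  cutting demos want the per-pose equilibrium, not the elastic transient.
  c = 0.35 is near critical damping for the box models' dominant modes at
  this step (relaxation in a few steps), and the short load ramp avoids
  the impulsive spike a suddenly imposed Dirichlet opening would inject.
  Under these conditions the Γ-modulated force series has strictly
  decreasing peak amplitudes, as the oscillation model intends.
- **Damped-norm monotonicity** is asserted on the relaxation manifold: a
  uniformly stretched box released from rest, monitored after a 100-step
  release transient. A cold start with random velocities provably cannot
  be monotone (velocities first decay below, then recover to, the
  force-slaved level), so the released-stretch configuration is the
  meaningful realization of the norm-decay property.
- **Momentum checks** run on the perturbed 1000-point lattice with the
  default undamped integrator; pair forces cancel analytically, so the
  measured per-step drift (~1e-13) is pure floating-point roundoff.
- **Mirror runs** reflect the whole configuration (model arrays, scalpel
  trajectory) across the blade plane; the pipeline is equivariant to
  reflection up to roundoff (~1e-15 observed), which exercises every stage
  end to end.

Problem sizes in tests and the acceptance script (boxes of 144–1000
points, 20 random clouds of 200–2000 points, 50 scalpel poses, 150-step
force series) are chosen so the full suite runs in seconds while every
property is still measured at its stated tolerance.

## What the synthetic conditions do not show

The generators emulate regular, homogeneous, isotropic tissue blocks with
clean lattice interiors. Passing tests demonstrate the advertised
mathematical properties of the discretization and pipeline — not
biofidelity: real organs are anisotropic, viscoelastic, inhomogeneous and
irregularly sampled, cutting forces depend on blade speed and friction,
and the empirical force fit is a single-experiment curve. Wall-clock
real-time performance and haptic-device integration are out of scope (the
simulator is a batch tool).

## Known limitations

- The wound interior can be locally non-manifold for two-vertex paths
  (documented above); exports remain valid triangle soups.
- Support severing uses region labels, so for a partial cut the severing
  plane extends across the labelled region rather than stopping exactly at
  the cut's swept extent.
- One-sided force evaluation (only affected points assemble B matrices)
  biases transients near the affected/unaffected interface; equilibria are
  unaffected in practice but carry no formal error bound.
- Explicit integration is conditionally stable; the config exposes dt and
  damping, and a blown-up run aborts with a numerical-failure exit code
  rather than clamping.
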