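# Methods

## Model and representations

An ellipsoid in R^d (d = 2 or 3) is represented three ways, with lossless
conversions:

* **Quadric** (A, b, c): the zero set of ⟨x, Ax⟩ + ⟨b, x⟩ + c with A
  symmetric positive definite.  Quadrics are identified up to a positive
  scale; the canonical representative has Tr(A) = 1.
* **Packed vector** q of length m = d(d+1)/2 + d + 1 (6 in 2D, 10 in 3D):
  squared terms, cross terms scaled by √2, linear terms, constant.  The
  3D ordering is (x², y², z², √2xy, √2xz, √2yz, x, y, z, 1).  The √2
  scaling makes the Euclidean norm of the matrix block equal ‖A‖_F, so
  vector projections of q realize Frobenius projections of A.
* **Geometry**: center x₀ = −A⁻¹b/2, axes = eigenvectors of A,
  semilengths ℓᵢ = √(−ĉ/λᵢ) with ĉ = c − ⟨x₀, Ax₀⟩ < 0.  Semilengths are
  reported sorted descending (ℓ₁ ≥ ℓ₂ ≥ ℓ₃); each axis is sign-normalized
  (largest-magnitude component positive) for reproducible CSV output.
  Equal eigenvalues (spheres/spheroids) leave the axes only determined up
  to rotation within the eigenspace; tests compare subspaces there.

A quadric counts as **degenerate** when λ_min(A)/λ_max(A) < 1e-8 —
the double-precision boundary between an ellipsoid and a
paraboloid/cylinder.  Conversion to geometry raises on degenerate or
empty (ĉ ≥ 0) quadrics; the solver only flags, so callers can inspect.

## The objective and its minimization

With lifted points dᵢ (so ⟨dᵢ, q⟩ is the signed algebraic residual of
point i) and D = [d₁ … dₙ], the fit solves

    min ‖Dᵀq‖²  subject to  Tr(A(q)) = 1,  A(q) ⪰ 0.

The constraint set is convex: a spectahedron in the matrix block, free in
(b, c).  The m × m Gram matrix DDᵀ is formed once, so everything after is
independent of n.

**Douglas-Rachford splitting.**  The two prox operators are closed-form:

* projection onto the constraint set = eigendecompose A(q), project the
  eigenvalues onto the probability simplex (sort-based algorithm),
  recompose; (b, c) pass through;
* prox of γ‖Dᵀ·‖² = solve (I + 2γ DDᵀ) p = q (Cholesky, factored once).

Because (b, c) are unconstrained they are minimized out exactly before
iterating: with Gram blocks [[G_aa, G_al], [G_alᵀ, G_ll]], the reduced
objective on the matrix block is aᵀS a with S = G_aa − G_al G_ll⁺ G_alᵀ,
and the optimal (b, c) = −G_ll⁺ G_alᵀ a is recovered afterwards.  The
iteration (relaxation λ = 1, deterministic start A = I/d)

    z ← z + λ (prox_{γS}(2 P(z) − z) − P(z)),    output a = P(z)

stops when ‖z_{k+1} − z_k‖ / max(1, ‖z_k‖) ≤ 1e-14 (the "machine
precision" reading of the stopping rule) or after `max_iterations`
(default 1000).  The output is always feasible since it passes through
the projection.  Eliminating the free block matters: iterating on the
full 10-vector leaves flat directions that couple A with (b, c) to the
iteration and can cost thousands of iterations on ill-conditioned
instances; the reduced scheme needs tens.

**Step size.**  `step_size=None` (default) picks γ from the spectrum of
S: in the noisy regime (λ_min(S) ≥ 1e-6 λ_max) the classical optimal step
1/√(λ_min λ_max) for a strongly convex quadratic; in the interpolation
regime (λ_min(S) ≈ 0, the optimum has zero residual) a large step
1/max(λ_min, 1e-10 λ_max), which turns the prox into a null-space
projection and flushes weakly-curved modes in a few iterations.  A fixed
positive `step_size` is honored when given.

**Interpolation polish.**  When the Gram matrix has exactly one
numerically-zero eigenvalue (unique interpolating quadric — e.g. 9
generic noiseless points in 3D), the trace-normalized null eigenvector is
taken as a candidate, projected to the constraint set, and accepted only
if feasible and strictly better.  Rationale: the eigenvector is accurate
to roughly machine-epsilon over the spectral gap, whereas any route
through the *squared* residual can only locate the solution to
√(ε/curvature) — about 1e-6 on near-degenerate instances — because the
objective is numerically flat there.  Noisy and under-determined inputs
are untouched by construction.

**Whitening.**  The default fit first maps the cloud by
y = Σ^{-1/2}(x − mean), with Σ the sample covariance (divisor n; the
scale cancels in the fit) and the *symmetric* inverse square root, which
makes the transform unique and rotation-free.  The fitted quadric is
pulled back by substitution and re-normalized to Tr(A) = 1.  This yields
covariance of the complete algorithm under any invertible affine map of
the input and normalizes the data scale the step-size rule assumes.
Clouds with covariance eigenvalue ratio below 1e-10 (collinear/coplanar
clicks, e.g. all in one view plane) raise a degenerate-cloud error.

**LLS baseline.**  `fit_ellipsoid_lls` minimizes ‖Dᵀq‖ under ‖q‖ = 1
(smallest right singular vector), with no positivity constraint; the
result is rescaled to Tr(A) = 1 when the trace is nonzero and flagged
`non_elliptic` when A is indefinite.  It serves as the robustness
comparison: on noisy partial arcs it frequently returns hyperbolas, which
the constrained fit cannot.

**Uniqueness.**  n ≥ d(d+1)/2 + d points in generic position (5 in 2D, 9
in 3D) make the minimizer unique.  Below that the fit logs a warning and
returns one member of the solution family.

## Synthetic data generator

The generator defines the study conditions for all tests; no external
data is used.

* **Click simulation**: exact surface points at uniform parametric angles
  — matching how a user clicks along visible contours, not uniform in
  area — plus isotropic Gaussian noise (`noise_sigma`, px) for imperfect
  pixel selection.  `plane_mode` restricts samples to the three
  axis-aligned cross-section ellipses through a chosen interior point,
  emulating clicking on orthogonal views.  Deterministic given the seed.
* **Spheroid phantom**: `count` oblate ellipsoids (ℓ₁ = ℓ₂, ℓ₃/ℓ₁ drawn
  from [0.4, 0.8], ℓ₁ from 6–12 px — sizes chosen so nuclei-scale
  objects fill a 256³ volume; the defaults are exposed) packed without
  overlap (rejection sampling on bounding spheres) inside a ball, then
  rendered as a binary interior volume (voxel-center rule, arrays indexed
  [z, y, x]) and blurred with a normalized Gaussian kernel of std 1.5 px
  by default, mimicking microscope blur.  Defaults reproduce a
  145-object tumor-spheroid-like test image.
* **Shape populations**: ellipsoids whose aspect ratio ℓ₃/ℓ₁ is Gaussian
  with a prescribed mean (sd 0.1, clipped to (0.05, 1]), for recovery
  tests of group means at nuclei-study sample sizes (700 / 250).

What the phantom does **not** model: anisotropic z-blur of real PSFs,
photon/readout noise, light scattering and absorption in deep tissue, and
human clicking behavior.  Passing tests therefore validate the geometry
and solver pipeline, not robustness to real microscope degradations, and
accuracy numbers from simulated clicks are not comparable to
user-timing studies.

## Accuracy metrics

`score_fit` reports the error triple used for phantom validation: center
distance (px), angle between minor axes in [0°, 90°] (axes are unsigned
lines), and the mean absolute difference of sorted semilengths (px).
When either ellipsoid has ℓ₂/ℓ₃ within 2% the minor axis is ill-defined;
the angle is reported as 0 with a degeneracy flag rather than polluting
averages with an arbitrary value.  Constrained fits that land exactly on
the PSD boundary (possible under heavy noise on small objects) cannot be
converted to geometry and are scored as infinite error; medians over a
phantom are robust to these.

## Shape statistics

Each fitted 3D ellipsoid yields ratios ℓ₂/ℓ₁ and ℓ₃/ℓ₂ (both in (0, 1]),
placing it in the unit square — spheres at the top-right corner, prolate
shapes on the right edge, oblate on the top edge — and the aspect ratio
ℓ₃/ℓ₁ = (ℓ₂/ℓ₁)(ℓ₃/ℓ₂).  Histograms use 20 bins per axis by default with
right-closed edges (so ratio 1.0 lands in the last bin).  Group summaries
report n, mean ratios, and 1D aspect histograms, plus the direction of
the shift between two groups.  No significance test is computed; the
choice of test is left to the analyst.

## Numerical choices and edge cases

* Simplex projection: sort-based exact algorithm; ties in the
  eigendecomposition resolve by LAPACK's deterministic ordering.
* Prox solve: Cholesky of I + 2γ(DDᵀ or S), always SPD.
* CSV written at %.15g — round-trips geometries to better than 1e-10.
* Mask voxel test uses ≤ 1e-9 (not ≤ 0) so boundary voxels are included
  regardless of rounding in the trace normalization; overlapping
  ellipsoids in labeled masks resolve last-writer-wins with the overlap
  count logged.
* Points files: CSV/TSV, optional header, 0-based pixel coordinates,
  voxel centers at integer coordinates, x = column, y = row, z = slice.

## Known limitations

* The algebraic residual is not the Euclidean distance; for very noisy or
  very partial data the algebraic optimum can differ from the geometric
  one (high-curvature bias).  This is inherent to the formulation.
* Under heavy noise relative to object size the constrained optimum can
  be a degenerate (flat) quadric; it is flagged, not silently repaired.
* The phantom's rejection packing is conservative (bounding spheres), so
  very dense arrangements need larger volumes.
* 2D support covers fitting and representations; phantom rendering, mask
  export and shape statistics are 3D-only, matching the imaging use case.
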