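# ellipsoidfit

Affine-invariant fitting of ellipses (2D) and ellipsoids (3D) to boundary
point clouds, for supervised segmentation of roughly ellipsoidal objects in
biological images — cell nuclei in tumor spheroids being the motivating
case.  A user (or a simulation of one) marks a handful of points on the
boundary of an object; the library returns the ellipsoid that best fits
them, exports the parameters as CSV and the interiors as TIFF masks, and
provides shape morphometry (axis-ratio histograms) over collections of
fitted nuclei.  A synthetic phantom generator produces blurred
multi-ellipsoid "spheroid" volumes with ground truth, so the whole pipeline
can be exercised and validated without any microscope data.

## The fitting problem

An ellipsoid is the zero set {x : ⟨x, Ax⟩ + ⟨b, x⟩ + c = 0} with A symmetric
positive definite.  Given boundary points x₁…xₙ, the fit minimizes the
squared *algebraic* residual

    G(A, b, c) = Σᵢ (⟨xᵢ, A xᵢ⟩ + ⟨b, xᵢ⟩ + c)²

subject to Tr(A) = 1 and A ⪰ 0.  The trace normalization rules out the
trivial zero solution while keeping the feasible set convex (a spectahedron
in A, free in (b, c)); the PSD constraint guarantees the result is an
ellipsoid and never a hyperbola — the property that distinguishes this fit
from plain linear least squares (LLS), which under noise happily returns
non-elliptic quadrics.

Writing q for the packed coefficient vector (squared terms, √2-scaled cross
terms, linear terms, constant; m = 10 in 3D) and D for the matrix of lifted
points, G(q) = ‖Dᵀq‖².  The program is solved by Douglas-Rachford
splitting: the spectahedron projection is an eigenvalue projection onto the
probability simplex, and the prox of the quadratic is one small
(≤ 10 × 10) SPD solve.  The unconstrained (b, c) block is eliminated
exactly through a Schur complement before iterating, and the step size is
chosen from the reduced Hessian spectrum; on a mixed battery of random
instances the solver reaches a fixed-point residual of 1e-14 in well under
200 iterations, each of cost independent of n.

Before fitting, the cloud is *whitened* — translated to zero mean and
mapped by the inverse symmetric square root of its covariance — and the
fitted quadric is mapped back.  This makes the complete algorithm covariant
under any invertible affine transform of the input (rigid motions
included) and keeps the solver well-conditioned regardless of the data
scale.  Nine generic surface points determine a 3D ellipsoid exactly (five
points for an ellipse in 2D); with fewer points the fit still runs but the
solution is not unique.

## Worked example

Simulate 15 exact clicks on the boundary of a known ellipsoid (center
(24, 30, 18), semi-axes 9, 6, 4 px), fit, and analyze:

```python
import numpy as np
from ellipsoidfit import EllipsoidGeometry, ClickSimulation, sample_surface_points

geom = EllipsoidGeometry(center=[24.0, 30.0, 18.0],
                         axes=np.eye(3), semilengths=[9.0, 6.0, 4.0])
sim = ClickSimulation(ellipsoid=geom, n_points=15, noise_sigma=0.0,
                      plane_mode=True, seed=5)
np.savetxt("nucleus.csv", sample_surface_points(sim).points,
           delimiter=",", header="x,y,z", comments="")
```

```text
$ ellipsoidfit fit nucleus.csv --out fit.csv
nucleus.csv: 25 iterations, objective 8.518e-26
wrote 1 ellipsoid(s) to fit.csv

$ cat fit.csv
id,center_x,center_y,center_z,a1_x,...,length_1,length_2,length_3
nucleus,24,30,18,1,...,9.00000000000003,5.99999999999999,4.00000000000003

$ ellipsoidfit analyze fit.csv --out-dir analysis
all: n=1 mean_ratio_21=0.6667 mean_ratio_32=0.6667 mean_aspect=0.4444
```

The fit converged in 25 iterations to an essentially zero residual and
recovered center and semi-axis lengths to 13 significant digits.  The
analyze step reports the axis ratios ℓ₂/ℓ₁ = 6/9 and ℓ₃/ℓ₂ = 4/6 and the
aspect ratio ℓ₃/ℓ₁ = 4/9 ≈ 0.444 used for shape comparisons between
conditions.  Other subcommands: `ellipsoidfit phantom` renders a blurred
145-ellipsoid spheroid volume with ground-truth CSV and label mask;
`ellipsoidfit fit --mask` writes binary/labeled TIFF masks of the fitted
interiors.

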