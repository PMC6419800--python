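"""Synthetic test inputs: simulated boundary clicks and a spheroid phantom.

Two generators emulate the data the fitting tool is used on:

* :func:`sample_surface_points` mimics a user clicking boundary points of
  a nucleus — exact surface samples (uniform in parametric angle, either
  free on the surface or restricted to three orthogonal planar
  cross-sections, matching an orthogonal-views workflow) perturbed by
  isotropic Gaussian "click" noise.

* :func:`generate_spheroid_phantom` builds a 3D grayscale image of many
  non-overlapping oblate ellipsoids packed inside a ball — a synthetic
  tumor spheroid — blurred with a Gaussian kernel to mimic microscope
  optics, together with a label mask and the ground-truth geometries.

:func:`score_fit` computes the standard accuracy triple for a fitted
ellipsoid against ground truth: center distance (px), minor-axis angle
(degrees, unsigned lines), and mean absolute semi-axis length error (px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .design import PointCloud
from .quadrics import (
    EllipsoidGeometry,
    QuadricCoefficients,
    evaluate_quadric,
    geometry_to_quadric,
    quadric_to_geometry,
)

__all__ = [
    "ClickSimulation",
    "SpheroidPhantom",
    "FitScore",
    "sample_surface_points",
    "generate_spheroid_phantom",
    "sample_shape_population",
    "score_fit",
    "random_ellipsoid",
]

#: l2/l3 ratio within which the minor axis is considered ill-defined
_MINOR_AXIS_TIE = 0.02


@dataclass(frozen=True)
class ClickSimulation:
    """Configuration for simulated boundary clicks on one ellipsoid.

    ``plane_mode`` restricts samples to the three axis-aligned planes
    through ``plane_point`` (default: the ellipsoid center), emulating
    clicks on orthogonal views; otherwise points are sampled freely on
    the surface.  ``noise_sigma`` is the std (pixels) of isotropic
    Gaussian click noise.
    """

    ellipsoid: EllipsoidGeometry
    n_points: int
    noise_sigma: float = 0.0
    plane_mode: bool = False
    plane_point: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.plane_point is not None:
            object.__setattr__(
                self, "plane_point", np.asarray(self.plane_point, dtype=float)
            )


@dataclass(frozen=True)
class SpheroidPhantom:
    """Rendered spheroid phantom: blurred image, label mask, ground truth."""

    image: np.ndarray = field(repr=False)
    label_mask: np.ndarray = field(repr=False)
    ellipsoids: list[EllipsoidGeometry]
    blur_sigma: float
    seed: int


@dataclass(frozen=True)
class FitScore:
    """Accuracy of a fitted ellipsoid vs ground truth (Table-style metrics)."""

    center_px: float
    angle_deg: float
    length_px: float
    angle_degenerate: bool = False


def _surface_point(geom: EllipsoidGeometry, theta, phi=None) -> np.ndarray:
    """Parametric surface point(s); 2D uses theta only."""
    s, R, c = geom.semilengths, geom.axes, geom.center
    if geom.dim == 2:
        local = np.stack([s[0] * np.cos(theta), s[1] * np.sin(theta)], axis=-1)
    else:
        st, ct = np.sin(theta), np.cos(theta)
        local = np.stack(
            [s[0] * st * np.cos(phi), s[1] * st * np.sin(phi), s[2] * ct],
            axis=-1,
        )
    return local @ R.T + c


def _plane_cross_section(
    quad: QuadricCoefficients, axis: int, value: float
) -> tuple[EllipsoidGeometry, np.ndarray]:
    """Ellipse cut by the plane {x[axis] = value}; returns 2D geometry and
    the index map of the two in-plane coordinates."""
    A, b, c = quad.matrix_part, quad.linear_part, quad.scalar_part
    keep = np.array([i for i in range(3) if i != axis])
    A2 = A[np.ix_(keep, keep)]
    b2 = b[keep] + 2.0 * A[keep, axis] * value
    c2 = c + A[axis, axis] * value**2 + b[axis] * value
    tr = np.trace(A2)
    quad2 = QuadricCoefficients(
        matrix_part=A2 / tr, linear_part=b2 / tr, scalar_part=c2 / tr
    )
    return quadric_to_geometry(quad2), keep


def sample_surface_points(sim: ClickSimulation) -> PointCloud:
    """Simulate clicked boundary points; deterministic given the seed.

    With ``noise_sigma = 0`` every point lies exactly on the surface.
    In ``plane_mode`` the points are spread round-robin over the three
    axis-aligned cross-section ellipses through ``plane_point``.

    Raises
    ------
    ValueError
        if a requested cutting plane misses the ellipsoid.
    """
    rng = np.random.default_rng(sim.seed)
    geom = sim.ellipsoid
    d = geom.dim
    if sim.plane_mode:
        if d != 3:
            raise ValueError("plane_mode requires a 3D ellipsoid")
        p = sim.plane_point if sim.plane_point is not None else geom.center
        quad = geometry_to_quadric(geom)
        if evaluate_quadric(quad, p) >= 0:
            raise ValueError("plane point lies outside the ellipsoid")
        pts = []
        counts = [(sim.n_points + 2 - k) // 3 for k in range(3)]
        for axis, n_k in enumerate(counts):
            if n_k == 0:
                continue
            try:
                ell2d, keep = _plane_cross_section(quad, axis, p[axis])
            except Exception as exc:
                raise ValueError(
                    f"plane x[{axis}]={p[axis]} does not cut the ellipsoid"
                ) from exc
            theta = rng.uniform(0.0, 2.0 * np.pi, n_k)
            xy = _surface_point(ell2d, theta)
            block = np.empty((n_k, 3))
            block[:, keep] = xy
            block[:, axis] = p[axis]
            pts.append(block)
        X = np.vstack(pts)
    elif d == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi, sim.n_points)
        X = _surface_point(geom, theta)
    else:
        theta = rng.uniform(0.0, np.pi, sim.n_points)
        phi = rng.uniform(0.0, 2.0 * np.pi, sim.n_points)
        X = _surface_point(geom, theta, phi)
    if sim.noise_sigma > 0:
        X = X + rng.normal(0.0, sim.noise_sigma, X.shape)
    return PointCloud(points=X)


def random_ellipsoid(
    rng: np.random.Generator,
    dim: int = 3,
    center_range: float = 50.0,
    semilength_range: tuple[float, float] = (2.0, 20.0),
    max_anisotropy: float = 10.0,
) -> EllipsoidGeometry:
    """Random ellipsoid: uniform center, random rotation, semilengths with
    anisotropy ratio at most ``max_anisotropy``."""
    center = rng.uniform(-center_range, center_range, dim)
    M = rng.normal(size=(dim, dim))
    Q, Rm = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(Rm))
    lo, hi = semilength_range
    s1 = rng.uniform(lo, hi)
    others = s1 * rng.uniform(1.0 / max_anisotropy, 1.0, dim - 1)
    s = np.sort(np.concatenate([[s1], others]))[::-1]
    return EllipsoidGeometry(center=center, axes=Q, semilengths=s)


def _random_rotation(rng: np.random.Generator, dim: int = 3) -> np.ndarray:
    M = rng.normal(size=(dim, dim))
    Q, R = np.linalg.qr(M)
    return Q * np.sign(np.diag(R))


def generate_spheroid_phantom(
    count: int = 145,
    image_shape: tuple[int, int, int] = (256, 256, 256),
    oblateness_range: tuple[float, float] = (0.4, 0.8),
    semilength_range: tuple[float, float] = (6.0, 12.0),
    blur_sigma: float = 1.5,
    seed: int = 0,
    max_attempts: int = 200_000,
) -> SpheroidPhantom:
    """Generate a spheroid phantom of ``count`` oblate ellipsoids.

    Oblate nuclei (l1 = l2 > l3, with l3/l1 drawn from
    ``oblateness_range``) are packed without overlap inside a ball
    centered in the volume, by rejection sampling on bounding spheres.
    The image is the binary union of interiors convolved with a Gaussian
    of std ``blur_sigma`` (pixels); the mask holds labels 1..count.

    Raises
    ------
    RuntimeError
        if packing fails within the attempt budget (volume too small or
        count too large).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in image_shape)  # (nz, ny, nx)
    center_vol = np.array(shape[::-1], dtype=float) / 2.0  # in (x, y, z)
    lo, hi = semilength_range
    ball_radius = min(shape) / 2.0 - hi - 4.0 * blur_sigma
    if ball_radius <= hi:
        raise ValueError("image_shape too small for the semilength range")

    geoms: list[EllipsoidGeometry] = []
    centers = np.empty((0, 3))
    radii = np.empty(0)
    attempts = 0
    while len(geoms) < count:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not pack {count} ellipsoids after {max_attempts} "
                "attempts; reduce count or enlarge image_shape"
            )
        l1 = rng.uniform(lo, hi)
        l3 = l1 * rng.uniform(*oblateness_range)
        # random position uniform in the allowed ball
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = (ball_radius - l1) * rng.uniform() ** (1.0 / 3.0)
        pos = center_vol + r * u
        if radii.size and np.any(
            np.linalg.norm(centers - pos, axis=1) < radii + l1
        ):
            continue
        R = _random_rotation(rng)
        geom = EllipsoidGeometry(
            center=pos, axes=R, semilengths=np.array([l1, l1, l3])
        )
        geoms.append(geom)
        centers = np.vstack([centers, pos])
        radii = np.append(radii, l1)

    from .io import rasterize_labels

    mask = rasterize_labels(geoms, shape)
    image = (mask > 0).astype(np.float64)
    if blur_sigma > 0:
        image = gaussian_filter(image, sigma=blur_sigma, mode="constant")
    return SpheroidPhantom(
        image=image,
        label_mask=mask,
        ellipsoids=geoms,
        blur_sigma=blur_sigma,
        seed=seed,
    )


def sample_shape_population(
    n: int,
    mean_aspect: float,
    sd_aspect: float = 0.1,
    semilength_range: tuple[float, float] = (4.0, 8.0),
    seed: int = 0,
) -> list[EllipsoidGeometry]:
    """Random 3D ellipsoids whose aspect ratio l3/l1 has a given mean.

    Aspect ratios are drawn Gaussian (clipped to (0.05, 1]); l2 is
    uniform between l3 and l1.  Used to emulate nuclei populations with
    a prescribed mean aspect ratio.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        a = float(np.clip(rng.normal(mean_aspect, sd_aspect), 0.05, 1.0))
        l1 = rng.uniform(*semilength_range)
        l3 = a * l1
        l2 = rng.uniform(l3, l1)
        out.append(
            EllipsoidGeometry(
                center=rng.uniform(-20, 20, 3),
                axes=_random_rotation(rng),
                semilengths=np.array([l1, l2, l3]),
            )
        )
    return out


def score_fit(truth: EllipsoidGeometry, fitted: EllipsoidGeometry) -> FitScore:
    """Accuracy triple of a 3D fit against ground truth.

    center: Euclidean distance (px).  angle: angle between the minor
    axes in [0, 90] degrees (axes are unsigned lines); reported as 0
    with ``angle_degenerate=True`` when either minor axis is ill-defined
    (l2/l3 within 2%).  length: mean absolute difference of the sorted
    semilengths (px).
    """
    if truth.dim != 3 or fitted.dim != 3:
        raise ValueError("score_fit requires 3D geometries")
    center = float(np.linalg.norm(truth.center - fitted.center))
    length = float(np.mean(np.abs(truth.semilengths - fitted.semilengths)))

    def _minor_ok(g: EllipsoidGeometry) -> bool:
        return g.semilengths[1] / g.semilengths[2] > 1.0 + _MINOR_AXIS_TIE

    if _minor_ok(truth) and _minor_ok(fitted):
        cosang = abs(truth.axes[:, 2] @ fitted.axes[:, 2])
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return FitScore(center_px=center, angle_deg=angle, length_px=length)
    return FitScore(
        center_px=center, angle_deg=0.0, length_px=length, angle_degenerate=True
    )
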