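"""Quadric representations of ellipses and ellipsoids.

An ellipsoid is the zero set ``{x : <x, A x> + <b, x> + c = 0}`` with ``A``
symmetric positive definite.  Three interchangeable representations are
provided:

``QuadricCoefficients``
    the triplet ``(A, b, c)``;
``PackedQuadric``
    a flat vector ``q`` of length ``m = d(d+1)/2 + d + 1`` (6 in 2D, 10 in
    3D) holding the squared terms, the cross terms scaled by ``sqrt(2)``,
    the linear terms and the constant — the scaling makes the Euclidean
    norm of the matrix block equal the Frobenius norm of ``A``;
``EllipsoidGeometry``
    center, orthonormal axes and semi-axis lengths, the human-readable
    form used for CSV export.

Conversions between the three are lossless (quadrics are identified up to
a positive scale factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuadricCoefficients",
    "PackedQuadric",
    "EllipsoidGeometry",
    "packed_length",
    "pack",
    "unpack",
    "quadric_to_geometry",
    "geometry_to_quadric",
    "evaluate_quadric",
    "DegenerateQuadricError",
]

_SQRT2 = np.sqrt(2.0)

#: (row, col) order of the off-diagonal entries in the packed vector.
_CROSS_INDICES = {2: [(0, 1)], 3: [(0, 1), (0, 2), (1, 2)]}

#: eigenvalue-ratio threshold below which a matrix part is "degenerate"
#: (paraboloid/cylinder rather than an ellipsoid, at double precision)
DEGENERACY_RATIO = 1e-8


class DegenerateQuadricError(ValueError):
    """Raised when a quadric does not describe a non-empty ellipsoid."""


def packed_length(dim: int) -> int:
    """Number of packed coefficients, ``m = d(d+1)/2 + d + 1``."""
    if dim not in (2, 3):
        raise ValueError(f"dim must be 2 or 3, got {dim}")
    return dim * (dim + 1) // 2 + dim + 1


@dataclass(frozen=True)
class QuadricCoefficients:
    """The triplet ``(A, b, c)`` of a quadric ``<x,Ax> + <b,x> + c = 0``."""

    matrix_part: np.ndarray
    linear_part: np.ndarray
    scalar_part: float

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix_part, dtype=float)
        b = np.asarray(self.linear_part, dtype=float)
        object.__setattr__(self, "matrix_part", A)
        object.__setattr__(self, "linear_part", b)
        object.__setattr__(self, "scalar_part", float(self.scalar_part))
        d = A.shape[0]
        if A.shape != (d, d) or d not in (2, 3):
            raise ValueError(f"matrix_part must be 2x2 or 3x3, got {A.shape}")
        if b.shape != (d,):
            raise ValueError(f"linear_part must have length {d}, got {b.shape}")
        scale = max(np.abs(A).max(), 1.0)
        asym = np.abs(A - A.T).max()
        if asym > 1e-12 * scale:
            raise ValueError(
                f"matrix_part is not symmetric: |A - A.T|_max = {asym:.3e}"
            )

    @property
    def dim(self) -> int:
        return self.matrix_part.shape[0]


@dataclass(frozen=True)
class PackedQuadric:
    """Flat coefficient vector ``q`` with sqrt(2)-scaled cross terms.

    Ordering (fixed contract): squared terms ``x1^2 .. xd^2``, then cross
    terms ``sqrt(2) x1 x2 [, sqrt(2) x1 x3, sqrt(2) x2 x3]``, then linear
    terms, then the constant.
    """

    dim: int
    coeffs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", v)
        m = packed_length(self.dim)
        if v.shape != (m,):
            raise ValueError(
                f"packed vector for dim={self.dim} must have length {m} "
                f"(6 for d=2, 10 for d=3), got shape {v.shape}"
            )


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Center, orthonormal axes and semi-axis lengths (pixels).

    ``axes`` stores one unit axis per column; ``semilengths`` are sorted
    descending (l1 >= l2 >= l3) with the columns of ``axes`` permuted to
    match.
    """

    center: np.ndarray
    axes: np.ndarray
    semilengths: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        R = np.asarray(self.axes, dtype=float)
        s = np.asarray(self.semilengths, dtype=float)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "axes", R)
        object.__setattr__(self, "semilengths", s)
        d = c.shape[0]
        if d not in (2, 3):
            raise ValueError(f"center must have length 2 or 3, got {d}")
        if R.shape != (d, d):
            raise ValueError(f"axes must be {d}x{d}, got {R.shape}")
        if s.shape != (d,):
            raise ValueError(f"need {d} semilengths, got {s.shape}")
        if np.abs(R.T @ R - np.eye(d)).max() > 1e-10:
            raise ValueError("axes columns are not orthonormal")
        if not np.all(s > 0):
            raise ValueError(f"semilengths must be strictly positive, got {s}")
        if np.any(np.diff(s) > 0):
            raise ValueError(f"semilengths must be sorted descending, got {s}")

    @property
    def dim(self) -> int:
        return self.center.shape[0]


def pack(quadric: QuadricCoefficients) -> PackedQuadric:
    """Vectorize ``(A, b, c)`` into the packed vector ``q``.

    Cross terms carry a factor sqrt(2), so the 2-norm of the matrix block
    equals ``||A||_F``.
    """
    d = quadric.dim
    A, b, c = quadric.matrix_part, quadric.linear_part, quadric.scalar_part
    parts = [np.diag(A)]
    parts.append(np.array([_SQRT2 * A[i, j] for i, j in _CROSS_INDICES[d]]))
    parts.append(b)
    parts.append(np.array([c]))
    return PackedQuadric(dim=d, coeffs=np.concatenate(parts))


def unpack(packed: PackedQuadric) -> QuadricCoefficients:
    """Inverse of :func:`pack`; exact round trip."""
    d = packed.dim
    v = packed.coeffs
    A = np.diag(v[:d]).copy()
    for k, (i, j) in enumerate(_CROSS_INDICES[d]):
        A[i, j] = A[j, i] = v[d + k] / _SQRT2
    n_cross = len(_CROSS_INDICES[d])
    b = v[d + n_cross : d + n_cross + d]
    c = v[-1]
    return QuadricCoefficients(matrix_part=A, linear_part=b, scalar_part=c)


def matrix_block(dim: int) -> slice:
    """Slice of the packed vector holding the matrix part (diag + cross)."""
    return slice(0, dim * (dim + 1) // 2)


def _fix_axis_signs(R: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (reproducible CSV)."""
    R = R.copy()
    for j in range(R.shape[1]):
        k = np.argmax(np.abs(R[:, j]))
        if R[k, j] < 0:
            R[:, j] = -R[:, j]
    return R


def quadric_to_geometry(quadric: QuadricCoefficients) -> EllipsoidGeometry:
    """Convert ``(A, b, c)`` to center / axes / semilengths.

    Completes the square: the center is ``x0 = -A^{-1} b / 2``; with
    ``c_hat = c - <x0, A x0>`` (which must be negative for a non-empty
    ellipsoid) the semilength along eigenvector ``v_i`` of ``A`` is
    ``sqrt(-c_hat / lambda_i)``.

    Raises
    ------
    DegenerateQuadricError
        if ``A`` is (near-)singular or the quadric is empty/a point.
    """
    A, b, c = quadric.matrix_part, quadric.linear_part, quadric.scalar_part
    lam, V = np.linalg.eigh(A)
    if lam[-1] <= 0 or lam[0] / lam[-1] < DEGENERACY_RATIO:
        raise DegenerateQuadricError(
            f"degenerate quadric: min eigenvalue {lam[0]:.3e} "
            f"(max {lam[-1]:.3e})"
        )
    x0 = np.linalg.solve(A, -b / 2.0)
    c_hat = c - x0 @ A @ x0
    if c_hat >= 0:
        raise DegenerateQuadricError(
            f"empty or point ellipsoid: centered constant {c_hat:.3e} >= 0"
        )
    semilengths = np.sqrt(-c_hat / lam)
    order = np.argsort(semilengths)[::-1]  # descending; eigh ties stay stable
    return EllipsoidGeometry(
        center=x0,
        axes=_fix_axis_signs(V[:, order]),
        semilengths=semilengths[order],
    )


def geometry_to_quadric(geom: EllipsoidGeometry) -> QuadricCoefficients:
    """Convert geometry back to a trace-normalized quadric (Tr(A) = 1)."""
    R, s, x0 = geom.axes, geom.semilengths, geom.center
    A0 = (R / s**2) @ R.T  # R diag(1/s^2) R^T
    tr = np.trace(A0)
    A = A0 / tr
    b = -2.0 * A @ x0
    c = (x0 @ A0 @ x0 - 1.0) / tr
    return QuadricCoefficients(matrix_part=A, linear_part=b, scalar_part=c)


def evaluate_quadric(
    quadric: QuadricCoefficients, points: np.ndarray
) -> np.ndarray:
    """Signed algebraic residual ``<x,Ax> + <b,x> + c`` per point.

    Negative inside the ellipsoid, positive outside, zero on the surface.
    ``points`` is an ``(n, d)`` array (a single point of shape ``(d,)`` is
    accepted and returns a scalar).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.shape[1] != quadric.dim:
        raise ValueError(
            f"points have dim {X.shape[1]}, quadric has dim {quadric.dim}"
        )
    A, b, c = quadric.matrix_part, quadric.linear_part, quadric.scalar_part
    vals = np.einsum("ij,jk,ik->i", X, A, X) + X @ b + c
    if np.asarray(points).ndim == 1:
        return vals[0]
    return vals
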