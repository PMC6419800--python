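"""Affine registration of point clouds (whitening) and quadric transport.

Fitting in whitened coordinates (zero mean, identity covariance) and
mapping the result back makes the whole fitting algorithm invariant to
invertible affine transforms of the input cloud, and keeps the solver
well-conditioned regardless of the data scale.

The forward map is the symmetric inverse square root of the sample
covariance, ``y = Sigma^{-1/2} (x - mean)`` — symmetric so the transform
is rotation-free and unique.  The sample covariance uses divisor ``n``
(the overall scale cancels in the fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import PointCloud
from .quadrics import QuadricCoefficients

__all__ = [
    "WhitenTransform",
    "DegenerateCloudError",
    "compute_whitening",
    "apply_transform",
    "invert_transform",
    "pullback_quadric",
]

#: covariance eigenvalue ratio below which the cloud is affinely degenerate
_DEGENERATE_RATIO = 1e-10


class DegenerateCloudError(ValueError):
    """Points are (nearly) collinear/coplanar; no whitening exists."""


@dataclass(frozen=True)
class WhitenTransform:
    """Affine map ``y = T (x - mean)`` with stored inverse of ``T``."""

    mean: np.ndarray
    forward_map: np.ndarray
    inverse_map: np.ndarray

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @classmethod
    def identity(cls, dim: int) -> "WhitenTransform":
        eye = np.eye(dim)
        return cls(mean=np.zeros(dim), forward_map=eye, inverse_map=eye)


def compute_whitening(points: PointCloud) -> WhitenTransform:
    """Whitening transform taking the cloud to mean 0, covariance I.

    Requires ``n >= d + 1`` non-degenerate points.
    """
    X = points.points
    n, d = X.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points to whiten, got {n}")
    mean = X.mean(axis=0)
    Y = X - mean
    cov = Y.T @ Y / n
    lam, V = np.linalg.eigh(cov)
    if lam[-1] <= 0 or lam[0] / lam[-1] < _DEGENERATE_RATIO:
        cond = np.inf if lam[0] <= 0 else lam[-1] / lam[0]
        raise DegenerateCloudError(
            "affinely degenerate point cloud (points collinear or coplanar); "
            f"covariance condition number {cond:.3e}"
        )
    T = (V / np.sqrt(lam)) @ V.T  # symmetric Sigma^{-1/2}
    T_inv = (V * np.sqrt(lam)) @ V.T
    return WhitenTransform(mean=mean, forward_map=T, inverse_map=T_inv)


def apply_transform(transform: WhitenTransform, points: PointCloud) -> PointCloud:
    """Apply ``y = T (x - mean)`` to every point."""
    if transform.dim != points.dim:
        raise ValueError(
            f"dim mismatch: transform {transform.dim}, points {points.dim}"
        )
    Y = (points.points - transform.mean) @ transform.forward_map.T
    return PointCloud(points=Y)


def invert_transform(transform: WhitenTransform, points: PointCloud) -> PointCloud:
    """Map whitened points back: ``x = T^{-1} y + mean``."""
    if transform.dim != points.dim:
        raise ValueError(
            f"dim mismatch: transform {transform.dim}, points {points.dim}"
        )
    X = points.points @ transform.inverse_map.T + transform.mean
    return PointCloud(points=X)


def pullback_quadric(
    transform: WhitenTransform, quadric_whitened: QuadricCoefficients
) -> QuadricCoefficients:
    """Transport a quadric from whitened to original coordinates.

    Substituting ``y = T (x - mean)`` into ``<y, A y> + <b, y> + c`` gives
    a quadric in ``x`` whose zero set is the preimage of the whitened
    ellipsoid.  The result is renormalized to ``Tr(A) = 1``.
    """
    if transform.dim != quadric_whitened.dim:
        raise ValueError("transform and quadric dims differ")
    T, mu = transform.forward_map, transform.mean
    if abs(np.linalg.det(T)) < 1e-300:
        raise ValueError("singular whitening transform")
    A, b, c = (
        quadric_whitened.matrix_part,
        quadric_whitened.linear_part,
        quadric_whitened.scalar_part,
    )
    A_x = T.T @ A @ T
    A_x = (A_x + A_x.T) / 2.0
    b_x = T.T @ b - 2.0 * A_x @ mu
    c_x = mu @ A_x @ mu - (T.T @ b) @ mu + c
    tr = np.trace(A_x)
    if tr <= 0:
        # zero/indefinite matrix part cannot be trace-normalized; return as-is
        return QuadricCoefficients(matrix_part=A_x, linear_part=b_x, scalar_part=c_x)
    return QuadricCoefficients(
        matrix_part=A_x / tr, linear_part=b_x / tr, scalar_part=c_x / tr
    )
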