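"""Data matrix construction and the algebraic objective.

For a point ``x`` the lifted vector in 2D is
``d_i = (x1^2, x2^2, sqrt(2) x1 x2, x1, x2, 1)`` so that the signed
algebraic residual of a quadric with packed vector ``q`` is the inner
product ``<d_i, q>``.  In 3D the ordering is
``(x^2, y^2, z^2, sqrt(2) xy, sqrt(2) xz, sqrt(2) yz, x, y, z, 1)``.

Stacking the ``d_i`` as columns of ``D`` (``m x n``), the objective is
``G(X, q) = ||D^T q||^2``.  The Gram matrix ``D D^T`` is at most 10x10,
so solver iterations cost O(m^2) regardless of the number of points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quadrics import PackedQuadric, packed_length, _CROSS_INDICES, _SQRT2

__all__ = ["PointCloud", "DesignMatrix", "build_design", "objective", "read_points"]


@dataclass(frozen=True)
class PointCloud:
    """``n`` points in R^d (d = 2 or 3), coordinates in pixels."""

    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", X)
        if X.ndim != 2 or X.shape[1] not in (2, 3):
            raise ValueError(f"points must be (n, 2) or (n, 3), got {X.shape}")
        if X.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
        if bad.size:
            raise ValueError(f"non-finite coordinates at row(s) {bad.tolist()}")

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class DesignMatrix:
    """``m x n`` matrix whose columns are the lifted point vectors."""

    dim: int
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", M)
        m = packed_length(self.dim)
        if M.ndim != 2 or M.shape[0] != m:
            raise ValueError(f"design matrix for dim={self.dim} must have {m} rows")

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def gram(self) -> np.ndarray:
        """The m x m Gram matrix ``D D^T``."""
        return self.matrix @ self.matrix.T


def build_design(points: PointCloud) -> DesignMatrix:
    """Lift a point cloud into the design matrix ``D = [d_1 ... d_n]``."""
    X = points.points
    d = points.dim
    cols = [X[:, i] ** 2 for i in range(d)]
    cols += [_SQRT2 * X[:, i] * X[:, j] for i, j in _CROSS_INDICES[d]]
    cols += [X[:, i] for i in range(d)]
    cols.append(np.ones(points.n))
    return DesignMatrix(dim=d, matrix=np.vstack(cols))


def objective(design: DesignMatrix, q: PackedQuadric) -> float:
    """The algebraic objective ``G = ||D^T q||^2 = sum_i <d_i, q>^2``."""
    if q.dim != design.dim:
        raise ValueError(f"dim mismatch: design {design.dim}, quadric {q.dim}")
    r = design.matrix.T @ q.coeffs
    return float(r @ r)


def read_points(path: str | Path) -> PointCloud:
    """Read a point cloud from delimited text (CSV/TSV).

    One point per row, columns x,y[,z]; a header row is detected and
    skipped; 0-based pixel coordinates.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty points file")
    lines = text.splitlines()
    delim = "\t" if "\t" in lines[0] else ","
    start = 0
    try:
        [float(t) for t in lines[0].split(delim)]
    except ValueError:
        start = 1  # header row
    rows = [[float(t) for t in ln.split(delim)] for ln in lines[start:] if ln.strip()]
    return PointCloud(points=np.array(rows))
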