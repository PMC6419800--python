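"""Ellipsoid fitting by Douglas-Rachford splitting.

The fit solves the convex program

    min_q ||D^T q||^2   subject to   Tr(A(q)) = 1,  A(q) >= 0,

where ``q`` is the packed quadric vector and ``A(q)`` its matrix part.
The constraint set (a spectahedron in the matrix block, free in the
linear/constant block) has an exact Euclidean projection — eigendecompose
``A(q)`` and project the eigenvalues onto the probability simplex — and
the smooth term has a closed-form proximal operator (one small SPD
solve), so Douglas-Rachford splitting applies directly.

The user-facing :func:`fit_ellipsoid` whitens the cloud first (zero
mean, identity covariance), fits in whitened coordinates, and maps the
quadric back, which makes the result affine-invariant and keeps the
iteration count low (at most a couple of hundred iterations to machine
precision on well-posed instances).

A linear least squares (LLS) baseline — the smallest right singular
vector of ``D^T`` under ``||q|| = 1``, with no positivity constraint —
is provided for robustness comparisons; unlike the constrained fit it
can return hyperbolas on noisy partial data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .design import DesignMatrix, PointCloud, build_design, objective
from .quadrics import (
    PackedQuadric,
    QuadricCoefficients,
    DEGENERACY_RATIO,
    pack,
    unpack,
    packed_length,
)
from .whitening import apply_transform, compute_whitening, pullback_quadric

__all__ = [
    "SolverConfig",
    "FitResult",
    "project_constraint",
    "prox_objective",
    "fit_ellipsoid_dr",
    "fit_ellipsoid_lls",
    "fit_ellipsoid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Douglas-Rachford parameters.

    step_size : float or None
        gamma of the quadratic prox.  ``None`` (default) adapts to the
        spectrum of the reduced Hessian S: ``1 / sqrt(mu L)`` (classical
        optimal step for a strongly convex quadratic) when ``mu =
        lambda_min(S)`` is genuinely positive, or a large
        ``1 / max(mu, 1e-10 L)`` in the interpolation regime where the
        optimum has (near-)zero residual.
    relaxation : float
        over/under-relaxation in (0, 2); 1.0 is the plain iteration.
    max_iterations, tolerance :
        stop when the relative fixed-point residual
        ``||z_{k+1} - z_k|| / max(1, ||z_k||)`` drops below ``tolerance``
        or the iteration budget is exhausted.
    """

    step_size: float | None = None
    relaxation: float = 1.0
    max_iterations: int = 1000
    tolerance: float = 1e-14

    def __post_init__(self) -> None:
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0 < self.relaxation < 2:
            raise ValueError("relaxation must lie in (0, 2)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fit: the quadric plus solver diagnostics."""

    quadric: QuadricCoefficients
    packed: PackedQuadric = field(repr=False)
    iterations_used: int
    final_objective: float
    converged: bool
    fixed_point_residual: float
    degenerate: bool = False      # matrix part nearly singular
    non_elliptic: bool = False    # matrix part indefinite (LLS only)

    def geometry(self):
        """Geometric parameters of the fitted ellipsoid (may raise on
        degenerate quadrics)."""
        from .quadrics import quadric_to_geometry

        return quadric_to_geometry(self.quadric)


_SQRT2 = np.sqrt(2.0)


def _A_from_block(a: np.ndarray, d: int) -> np.ndarray:
    """Symmetric matrix from the packed matrix block (sqrt(2) cross terms)."""
    if d == 2:
        return np.array([[a[0], a[2] / _SQRT2], [a[2] / _SQRT2, a[1]]])
    return np.array(
        [
            [a[0], a[3] / _SQRT2, a[4] / _SQRT2],
            [a[3] / _SQRT2, a[1], a[5] / _SQRT2],
            [a[4] / _SQRT2, a[5] / _SQRT2, a[2]],
        ]
    )


def _block_from_A(A: np.ndarray, d: int) -> np.ndarray:
    if d == 2:
        return np.array([A[0, 0], A[1, 1], _SQRT2 * A[0, 1]])
    return np.array(
        [A[0, 0], A[1, 1], A[2, 2],
         _SQRT2 * A[0, 1], _SQRT2 * A[0, 2], _SQRT2 * A[1, 2]]
    )


def _project_A_block(a: np.ndarray, d: int) -> np.ndarray:
    """Projection of the matrix block onto the spectahedron (Tr=1, PSD)."""
    lam, V = np.linalg.eigh(_A_from_block(a, d))
    Ap = (V * _project_simplex(lam)) @ V.T
    return _block_from_A((Ap + Ap.T) / 2.0, d)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of ``v`` onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ks = np.arange(1, v.size + 1)
    valid = u - css / ks > 0
    k = ks[valid][-1]
    tau = css[k - 1] / k
    return np.maximum(v - tau, 0.0)


def project_constraint(q: PackedQuadric) -> PackedQuadric:
    """Euclidean projection onto {Tr(A) = 1, A >= 0}.

    Only the matrix block is constrained: eigendecompose ``A(q)``,
    project the eigenvalues onto the probability simplex, recompose.
    Because of the sqrt(2) packing this is exactly the Frobenius-nearest
    feasible matrix.  The linear and constant entries pass through.
    """
    quad = unpack(q)
    lam, V = np.linalg.eigh(quad.matrix_part)
    lam_proj = _project_simplex(lam)
    A_proj = (V * lam_proj) @ V.T
    A_proj = (A_proj + A_proj.T) / 2.0
    return pack(
        QuadricCoefficients(
            matrix_part=A_proj,
            linear_part=quad.linear_part,
            scalar_part=quad.scalar_part,
        )
    )


def prox_objective(
    q: PackedQuadric, design: DesignMatrix, step_size: float
) -> PackedQuadric:
    """Prox of ``G(q) = ||D^T q||^2``: solve ``(I + 2 gamma D D^T) p = q``."""
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    m = packed_length(design.dim)
    M = np.eye(m) + 2.0 * step_size * design.gram()
    p = np.linalg.solve(M, q.coeffs)
    return PackedQuadric(dim=q.dim, coeffs=p)


def _matrix_eig_ratio(quad: QuadricCoefficients) -> float:
    lam = np.linalg.eigvalsh(quad.matrix_part)
    if lam[-1] <= 0:
        return 0.0
    return lam[0] / lam[-1]


def _polish_interpolation(
    q: PackedQuadric,
    design: DesignMatrix,
    G: np.ndarray,
    back_map: np.ndarray,
    na: int,
) -> PackedQuadric:
    """Refine an exact-interpolation solution via the design null vector.

    When the points interpolate a unique quadric (the Gram matrix has a
    single numerically-zero eigenvalue), that quadric is the normalized
    null eigenvector, computed by eigendecomposition to an accuracy set by
    the spectral gap — far better than what minimizing the squared
    residual can resolve on ill-conditioned instances.  The candidate is
    projected to the constraint set and accepted only if feasible and
    strictly better, so behavior on noisy or under-determined problems is
    unchanged.
    """
    d = q.dim
    lam, V = np.linalg.eigh(G)
    if not (lam[0] < 1e-16 * lam[-1] and lam[1] > 1e6 * max(lam[0], 0.0)):
        return q
    v = V[:, 0]
    tr = v[:d].sum()  # trace of the matrix part in packed form
    if abs(tr) < 1e-12 * np.linalg.norm(v):
        return q
    a_cand = _project_A_block(v[:na] / tr, d)
    cand = PackedQuadric(
        dim=d, coeffs=np.concatenate([a_cand, back_map @ a_cand])
    )
    if objective(design, cand) < objective(design, q):
        return cand
    return q


def fit_ellipsoid_dr(
    points: PointCloud, config: SolverConfig | None = None
) -> FitResult:
    """Douglas-Rachford fit in the given coordinates (no whitening).

    The linear/constant block ``(b, c)`` of the quadric is unconstrained,
    so it is minimized out exactly first: with the Gram matrix
    ``[[Gaa, Gal], [Gal^T, Gll]]`` of the design, the objective restricted
    to optimal ``(b, c)`` is ``a^T S a`` with the Schur complement
    ``S = Gaa - Gal Gll^+ Gal^T`` acting on the matrix block alone.
    Douglas-Rachford then alternates the prox of this reduced quadratic
    with the spectahedron projection,

        z <- z + relaxation * (prox_S(2 P(z) - z) - P(z)),

    returns ``a = P(z)`` (always feasible: Tr(A)=1, A PSD) and recovers
    ``(b, c) = -Gll^+ Gal^T a``.  Eliminating the free block this way
    converges in far fewer iterations than iterating on the full
    coefficient vector, because the flat directions that couple ``A``
    with ``(b, c)`` are solved exactly instead of iterated.

    With fewer than ``d(d+1)/2 + d`` points the minimizer need not be
    unique; a warning is logged but the fit proceeds.
    """
    config = config or SolverConfig()
    d = points.dim
    n_unique = d * (d + 1) // 2 + d
    if points.n < n_unique:
        logger.warning(
            "only %d points for d=%d; at least %d are needed for a unique fit",
            points.n, d, n_unique,
        )
    design = build_design(points)
    na = d * (d + 1) // 2
    G = design.gram()
    Gaa, Gal, Gll = G[:na, :na], G[:na, na:], G[na:, na:]
    Gll_pinv = np.linalg.pinv(Gll, rcond=1e-13)
    back_map = -Gll_pinv @ Gal.T  # optimal (b, c) = back_map @ a
    S = Gaa + Gal @ back_map
    S = (S + S.T) / 2.0

    gamma = config.step_size
    if gamma is None:
        lam_S = np.linalg.eigvalsh(S)
        L = lam_S[-1]
        if L <= 0:
            gamma = 1.0
        elif lam_S[0] < 1e-6 * L:
            # interpolation regime: the optimum has (near-)zero residual, so
            # a large step turns the prox into a null-space projection and
            # flushes the weakly curved modes in a few iterations
            gamma = 1.0 / max(lam_S[0], 1e-10 * L)
        else:
            # noisy regime: classical optimal step for a strongly convex
            # quadratic under Douglas-Rachford
            gamma = 1.0 / np.sqrt(lam_S[0] * L)

    M = np.eye(na) + 2.0 * gamma * S
    chol = cho_factor(M)

    z = np.zeros(na)
    z[:d] = 1.0 / d  # A = I/d, deterministic start
    residual = np.inf
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        x = _project_A_block(z, d)
        y = cho_solve(chol, 2.0 * x - z)
        z_new = z + config.relaxation * (y - x)
        residual = np.linalg.norm(z_new - z) / max(1.0, np.linalg.norm(z))
        z = z_new
        if residual <= config.tolerance:
            break
    a_out = _project_A_block(z, d)
    q_out = PackedQuadric(dim=d, coeffs=np.concatenate([a_out, back_map @ a_out]))
    q_out = _polish_interpolation(q_out, design, G, back_map, na)
    quad = unpack(q_out)
    degenerate = _matrix_eig_ratio(quad) < DEGENERACY_RATIO
    if degenerate:
        logger.warning("fit produced a degenerate quadric (near-singular A)")
    return FitResult(
        quadric=quad,
        packed=q_out,
        iterations_used=iterations,
        final_objective=objective(design, q_out),
        converged=residual <= config.tolerance,
        fixed_point_residual=float(residual),
        degenerate=degenerate,
    )


def fit_ellipsoid_lls(points: PointCloud) -> FitResult:
    """Linear least squares baseline: ``min ||D^T q||`` s.t. ``||q|| = 1``.

    The solution is the right singular vector of ``D^T`` for the smallest
    singular value.  No positive-semidefiniteness is imposed: under noise
    the returned quadric can be non-elliptic (indefinite matrix part),
    which is flagged.  The result is rescaled to ``Tr(A) = 1`` whenever
    the trace is nonzero, so elliptic results are comparable with the
    constrained fit.
    """
    design = build_design(points)
    m = packed_length(points.dim)
    if points.n < m - 1:
        logger.warning(
            "LLS with %d points (< %d); null space is multi-dimensional",
            points.n, m - 1,
        )
    _, s, Vt = np.linalg.svd(design.matrix.T, full_matrices=True)
    if points.n >= m and s[0] > 0 and s[-1] / s[0] < 1e-14:
        logger.warning("rank-deficient design; tie broken by SVD ordering")
    q = Vt[-1]
    quad = unpack(PackedQuadric(dim=points.dim, coeffs=q))
    tr = np.trace(quad.matrix_part)
    if abs(tr) > 1e-12:
        q = q / tr
        quad = unpack(PackedQuadric(dim=points.dim, coeffs=q))
    lam = np.linalg.eigvalsh(quad.matrix_part)
    non_elliptic = lam[0] < -1e-10
    packed = PackedQuadric(dim=points.dim, coeffs=q)
    return FitResult(
        quadric=quad,
        packed=packed,
        iterations_used=0,
        final_objective=objective(design, packed),
        converged=True,
        fixed_point_residual=0.0,
        degenerate=_matrix_eig_ratio(quad) < DEGENERACY_RATIO,
        non_elliptic=non_elliptic,
    )


def fit_ellipsoid(
    points: PointCloud, config: SolverConfig | None = None
) -> FitResult:
    """Default fit: whiten, run Douglas-Rachford, map the quadric back.

    Equivalent to :func:`fit_ellipsoid_dr` in whitened coordinates with
    the quadric transported to the original frame and renormalized to
    ``Tr(A) = 1``.  Affine-invariant: transforming the input cloud by any
    invertible affine map transforms the fitted ellipsoid the same way.
    """
    transform = compute_whitening(points)
    whitened = apply_transform(transform, points)
    result = fit_ellipsoid_dr(whitened, config)
    quad = pullback_quadric(transform, result.quadric)
    packed = pack(quad)
    design = build_design(points)
    degenerate = _matrix_eig_ratio(quad) < DEGENERACY_RATIO
    return FitResult(
        quadric=quad,
        packed=packed,
        iterations_used=result.iterations_used,
        final_objective=objective(design, packed),
        converged=result.converged,
        fixed_point_residual=result.fixed_point_residual,
        degenerate=degenerate or result.degenerate,
    )
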