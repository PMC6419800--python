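"""Independent oracles used by the tests.

These deliberately avoid the package's solver code paths: the simplex
projection enumerates KKT active sets by brute force, and the
constrained-fit oracle is an accelerated projected-gradient method on
the full coefficient vector (no proximal solve, no block elimination),
so agreement with the Douglas-Rachford solver is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

SQRT2 = np.sqrt(2.0)


def simplex_projection_bruteforce(v: np.ndarray) -> np.ndarray:
    """Projection onto the probability simplex by active-set enumeration.

    The optimum zeroes some subset of coordinates and shifts the rest by
    a common multiplier; trying every nonempty subset and keeping the
    nearest feasible candidate is exact for the small sizes used here.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    best, best_dist = None, np.inf
    for r in range(1, n + 1):
        for active in itertools.combinations(range(n), r):
            idx = list(active)
            tau = (v[idx].sum() - 1.0) / r
            x = np.zeros(n)
            x[idx] = v[idx] - tau
            if np.all(x[idx] >= -1e-12):
                dist = np.sum((x - v) ** 2)
                if dist < best_dist:
                    best, best_dist = np.clip(x, 0.0, None), dist
    return best


def _mat_from_packed(q: np.ndarray, d: int) -> np.ndarray:
    if d == 2:
        return np.array([[q[0], q[2] / SQRT2], [q[2] / SQRT2, q[1]]])
    return np.array(
        [
            [q[0], q[3] / SQRT2, q[4] / SQRT2],
            [q[3] / SQRT2, q[1], q[5] / SQRT2],
            [q[4] / SQRT2, q[5] / SQRT2, q[2]],
        ]
    )


def _packed_from_mat(A: np.ndarray, d: int) -> np.ndarray:
    if d == 2:
        return np.array([A[0, 0], A[1, 1], SQRT2 * A[0, 1]])
    return np.array(
        [A[0, 0], A[1, 1], A[2, 2],
         SQRT2 * A[0, 1], SQRT2 * A[0, 2], SQRT2 * A[1, 2]]
    )


def project_feasible(q: np.ndarray, d: int) -> np.ndarray:
    """Projection of a full packed vector onto {Tr(A)=1, A PSD}."""
    na = d * (d + 1) // 2
    lam, V = np.linalg.eigh(_mat_from_packed(q[:na], d))
    Ap = (V * simplex_projection_bruteforce(lam)) @ V.T
    out = q.copy()
    out[:na] = _packed_from_mat((Ap + Ap.T) / 2.0, d)
    return out


def constrained_fit_pg(
    D: np.ndarray, d: int, max_iter: int = 60_000, tol: float = 1e-16
) -> tuple[np.ndarray, float]:
    """Minimize ||D^T q||^2 over the constraint set by projected gradient.

    Nesterov acceleration with function-value restart; step 1/L with
    L = 2 lambda_max(D D^T).  Returns (q, objective).
    """
    m = D.shape[0]
    G = D @ D.T
    L = 2.0 * np.linalg.eigvalsh(G)[-1]
    if L <= 0:
        q = np.zeros(m)
        q[:d] = 1.0 / d
        return q, 0.0
    step = 1.0 / L
    q = np.zeros(m)
    q[:d] = 1.0 / d
    y = q.copy()
    t = 1.0
    f_prev = np.inf
    for _ in range(max_iter):
        grad = 2.0 * (G @ y)
        q_new = project_feasible(y - step * grad, d)
        f_new = q_new @ G @ q_new
        if f_new > f_prev:  # restart momentum
            y = q.copy()
            t = 1.0
            f_prev = np.inf
            continue
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = q_new + ((t - 1.0) / t_new) * (q_new - q)
        if np.linalg.norm(q_new - q) <= tol * max(1.0, np.linalg.norm(q)):
            q = q_new
            break
        q, t, f_prev = q_new, t_new, f_new
    q = project_feasible(q, d)
    return q, float(q @ G @ q)
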