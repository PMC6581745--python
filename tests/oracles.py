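"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the QP oracle
enumerates active sets and solves KKT systems directly, and the WLS
oracle minimizes the weighted objective with a generic numeric
optimizer.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import minimize


def qp_active_set_oracle(
    Q: np.ndarray, y: np.ndarray, G: np.ndarray, h: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Exact solution of min ||Qa - y||^2 s.t. Ga >= h by enumeration.

    Tries every subset of constraints as the active set, solves the
    equality-constrained KKT system, and keeps the best candidate that
    is primal feasible with non-negative multipliers.
    """
    n = Q.shape[1]
    # row-normalize constraints: equivalent problem, well-conditioned KKT
    scale = np.linalg.norm(G, axis=1)
    scale[scale == 0] = 1.0
    G = G / scale[:, None]
    h = h / scale
    H = 2.0 * Q.T @ Q
    f = 2.0 * Q.T @ y
    best = None
    best_obj = np.inf
    m = G.shape[0]
    for k in range(0, n + 1):
        for S in combinations(range(m), k):
            S = list(S)
            GS = G[S]
            KKT = np.zeros((n + k, n + k))
            KKT[:n, :n] = H
            KKT[:n, n:] = -GS.T
            KKT[n:, :n] = GS
            rhs = np.concatenate([f, h[S]])
            try:
                sol = np.linalg.solve(KKT, rhs)
            except np.linalg.LinAlgError:
                continue
            a, lam = sol[:n], sol[n:]
            if np.any(lam < -tol):
                continue
            if np.any(G @ a - h < -1e-8):
                continue
            obj = float(np.sum((Q @ a - y) ** 2))
            if obj < best_obj - 1e-12:
                best_obj = obj
                best = a
    assert best is not None, "oracle found no feasible KKT point"
    return best


def wls_numeric_oracle(X: np.ndarray, logy: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Minimize sum w_i (logy_i - x_i^T beta)^2 with a generic optimizer."""

    def obj(beta):
        r = logy - X @ beta
        return float(np.sum(weights * r**2))

    def grad(beta):
        r = logy - X @ beta
        return -2.0 * X.T @ (weights * r)

    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.mean(logy)
    res = minimize(
        obj, beta0, jac=grad, method="BFGS", options={"gtol": 1e-14, "maxiter": 20000}
    )
    return res.x


def random_qp_instance(seed: int, t: int = 10, n_max: int = 2):
    """A small random constrained MAP fit problem built from real parts.

    Returns (Q, y, G, h) with Q a genuine design matrix for a random
    frame and 10-measurement scheme, and G the positivity rows plus
    the integral bound of a tiny 3x3x1 constraint grid.
    """
    from mapboot.dti_init import TensorFrame
    from mapboot.map_basis import constraint_matrix, design_matrix, enumerate_indices
    from mapboot.scheme_io import AcquisitionScheme

    rng = np.random.default_rng(seed)
    bvals = np.concatenate([[0.0], rng.uniform(500, 4000, t - 1)])
    bvecs = rng.standard_normal((t, 3))
    bvecs[0] = 0
    bvecs[1:] /= np.linalg.norm(bvecs[1:], axis=1, keepdims=True)
    scheme = AcquisitionScheme(bvals, bvecs, 0.062, 0.062)
    lam = np.sort(rng.uniform(0.2e-3, 2.0e-3, 3))[::-1]
    qr, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(qr) < 0:
        qr[:, 0] = -qr[:, 0]
    frame = TensorFrame(R=qr, u=np.sqrt(2 * lam * scheme.t_d))
    indices = enumerate_indices(n_max)
    Q = design_matrix(frame, scheme, n_max, indices=indices)
    K, grid = constraint_matrix(frame, n_max, grid_shape=(3, 3, 1), indices=indices)
    integral_row = grid.weights @ K
    G = np.vstack([K, -integral_row[None, :]])
    h = np.zeros(G.shape[0])
    h[-1] = -0.5
    # signal: noisy attenuation around a feasible Gaussian-ish voxel
    y = np.exp(-scheme.bvals * rng.uniform(0.3e-3, 1.5e-3)) + rng.normal(0, 0.08, t)
    return Q, y, G, h
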