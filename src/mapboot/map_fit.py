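"""Positivity-constrained least-squares fit of the MAP coefficients.

The coefficients solve

    min_a || y - Q a ||^2   s.t.   K a >= 0,   w^T K a <= 0.5,

where the rows of K are propagator basis values on a half-space grid
and w are the grid quadrature volumes, so the second constraint bounds
the discretized propagator integral over the half space by 1/2 (the
full-space integral, by antipodal symmetry, by 1).

The quadratic program is solved exactly by the Lawson-Hanson reduction
chain: least squares with inequalities (LSI) -> least distance
programming (LDP) -> non-negative least squares (NNLS), with scipy's
NNLS as the core solver.  The method is deterministic and active-set
based, so noise-free feasible problems are recovered to machine
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from mapboot.dti_init import fit_dti_wls, frame_from_tensor, TensorFrame
from mapboot.map_basis import ConstraintGrid, constraint_matrix, design_matrix, enumerate_indices
from mapboot.scheme_io import AcquisitionScheme, VolumeStack

logger = logging.getLogger(__name__)

#: Feasibility tolerance on the linear constraints.
FEASIBILITY_TOL = 1e-8

#: Half-space propagator integral bound.
INTEGRAL_BOUND = 0.5


class FitError(RuntimeError):
    """Raised when the constrained solve fails for a voxel."""


@dataclass
class MapModel:
    """Fitted MAP coefficients for one voxel."""

    indices: list[tuple[int, int, int]]
    a: np.ndarray
    frame: TensorFrame
    fitted: np.ndarray
    residuals: np.ndarray
    objective: float
    n_active: int = 0
    scheme: AcquisitionScheme | None = field(default=None, repr=False)

    @property
    def n_coef(self) -> int:
        return self.a.size


def _solve_ldp(E: np.ndarray, f: np.ndarray) -> np.ndarray:
    """min ||z|| s.t. E z >= f (Lawson & Hanson LDP via NNLS)."""
    m, n = E.shape
    A = np.vstack([E.T, f[None, :]])  # (n+1) x m
    b = np.zeros(n + 1)
    b[-1] = 1.0
    lam, _ = nnls(A, b, maxiter=10 * max(m, n))
    r = A @ lam - b
    denom = r[-1]
    if abs(denom) < 1e-12:
        raise FitError("infeasible constraint set in LDP subproblem")
    return -r[:n] / denom


def solve_lsi(
    Q: np.ndarray, y: np.ndarray, G: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """min ||Q a - y|| s.t. G a >= h, Q full column rank.

    Reduces to LDP through the SVD of Q.  If the unconstrained
    least-squares solution already satisfies the constraints it is
    returned directly.  Constraint rows are normalized to unit norm
    first (an equivalent problem) so the active-set arithmetic is
    well-conditioned despite the large dynamic range of propagator
    densities.
    """
    scale = np.linalg.norm(G, axis=1)
    scale[scale == 0] = 1.0
    G = G / scale[:, None]
    h = h / scale
    U, s, Vt = np.linalg.svd(Q, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        # rank-deficient design: ridge fallback keeps the solve defined
        logger.warning("rank-deficient design matrix; applying ridge fallback")
        s = s + 1e-8 * s[0]
    Uty = U.T @ y
    a_ls = Vt.T @ (Uty / s)
    slack = G @ a_ls - h
    if np.all(slack >= -FEASIBILITY_TOL):
        return a_ls
    E = (G @ Vt.T) / s[None, :]
    f = h - E @ Uty
    z = _solve_ldp(E, f)
    return Vt.T @ ((z + Uty) / s)


def fit_map(
    y: np.ndarray,
    Q: np.ndarray,
    K: np.ndarray,
    weights: np.ndarray | ConstraintGrid,
    frame: TensorFrame | None = None,
    indices: list[tuple[int, int, int]] | None = None,
    integral_bound: float = INTEGRAL_BOUND,
    literal_integral: bool = False,
    scheme: AcquisitionScheme | None = None,
) -> MapModel:
    """Solve the positivity-constrained MAP coefficient fit for one voxel.

    Parameters
    ----------
    y : (T,) array
        Signal normalized by the voxel's b0 estimate (E(0) ~ 1).
    Q, K : arrays
        Design and constraint matrices for the voxel's frame.
    weights : (M,) array or ConstraintGrid
        Quadrature volumes for the integral bound.  With
        ``literal_integral=True`` the bound is applied to the raw sum
        ``1^T K a <= 0.5`` instead of the volume-weighted integral.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(weights, ConstraintGrid):
        weights = weights.weights
    weights = np.asarray(weights, dtype=float)
    if literal_integral:
        integral_row = np.sum(K, axis=0)
    else:
        integral_row = weights @ K
    G = np.vstack([K, -integral_row[None, :]])
    h = np.zeros(G.shape[0])
    h[-1] = -integral_bound
    a = solve_lsi(Q, y, G, h)
    scale = np.linalg.norm(G, axis=1)
    scale[scale == 0] = 1.0
    slack = (G @ a - h) / scale  # violations measured on unit-norm rows
    if np.min(slack) < -1e-5:
        raise FitError(f"constraint violation {-np.min(slack):.2e} after solve")
    fitted = Q @ a
    residuals = y - fitted
    return MapModel(
        indices=indices if indices is not None else [],
        a=a,
        frame=frame,
        fitted=fitted,
        residuals=residuals,
        objective=float(residuals @ residuals),
        n_active=int(np.sum(slack < FEASIBILITY_TOL)),
        scheme=scheme,
    )


def fit_voxel(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    n_max: int,
    b_max_dti: float = 2000.0,
    grid_shape: tuple[int, int, int] = (21, 21, 11),
    extent_factor: float = 6.0,
) -> MapModel:
    """Full single-voxel pipeline: tensor fit, frame, design, QP solve.

    The signal is normalized by the S0 estimate of the initial tensor
    fit before the constrained solve, so the coefficients describe the
    attenuation E(q).  Pooling all low-b measurements into the S0
    estimate (rather than dividing by the raw b0 mean) matters for
    schemes with few b0 volumes: a noisy single-b0 divisor would
    introduce a fully correlated scale error that the residual-based
    bootstrap could not see.
    """
    signal = np.asarray(signal, dtype=float)
    b0 = signal[scheme.b0_mask]
    if b0.size == 0 or np.mean(b0) <= 0:
        raise FitError("voxel has no positive b0 signal")
    tensor = fit_dti_wls(signal, scheme, b_max=b_max_dti)
    if not np.isfinite(tensor.S0_est) or tensor.S0_est <= 0:
        raise FitError("non-positive S0 estimate")
    y = signal / tensor.S0_est
    frame = frame_from_tensor(tensor, scheme.t_d)
    indices = enumerate_indices(n_max)
    Q = design_matrix(frame, scheme, n_max, indices=indices)
    K, grid = constraint_matrix(
        frame, n_max, grid_shape=grid_shape, extent_factor=extent_factor, indices=indices
    )
    return fit_map(y, Q, K, grid, frame=frame, indices=indices, scheme=scheme)


def fit_voxelwise(
    stack: VolumeStack,
    scheme: AcquisitionScheme,
    n_max: int | None = None,
    **kwargs,
) -> list[MapModel | None]:
    """Fit every in-mask voxel independently.

    Failed voxels yield None (and a log record) without affecting the
    rest; results are a list in the C order of the mask.  Voxels are
    strictly independent, so any execution order gives identical output.
    """
    if stack.data.shape[3] != scheme.n_measurements:
        raise ValueError(
            f"volume has {stack.data.shape[3]} measurements, scheme has {scheme.n_measurements}"
        )
    if n_max is None:
        n_max = default_n_max(scheme)
    signals = stack.voxel_signals()
    models: list[MapModel | None] = []
    for i, sig in enumerate(signals):
        try:
            models.append(fit_voxel(sig, scheme, n_max, **kwargs))
        except (FitError, ValueError) as exc:
            logger.warning("voxel %d failed: %s", i, exc)
            models.append(None)
    return models


def default_n_max(scheme: AcquisitionScheme) -> int:
    """Order 4 for schemes with <= 3 shells, 6 for richer schemes."""
    return 4 if len(scheme.shells()) <= 3 else 6
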