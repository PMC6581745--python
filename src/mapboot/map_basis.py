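"""Hermite-function basis for the mean apparent propagator.

The q-space signal attenuation is expanded as E(q) = sum a_n Phi_n(A, q)
where each 3-D basis function is a separable product of 1-D Hermite
functions evaluated in the eigenframe of the displacement covariance
tensor A = 2 R^T D R t_d.  The r-space counterparts Psi_n reconstruct
the propagator P(r) with the same coefficients, which is what makes the
positivity constraint a simple linear inequality on the coefficients.

Basis indices (n1, n2, n3) with even total order N = n1+n2+n3 <= N_max
are enumerated N ascending, then lexicographically, so coefficient
vectors are comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_hermite, gammaln

from mapboot.dti_init import TensorFrame
from mapboot.scheme_io import AcquisitionScheme, q_vectors


def n_coef(n_max: int) -> int:
    """Number of basis coefficients up to even order ``n_max``.

    Closed form (1/6)(N/2+1)(N/2+2)(2N+3) for N = n_max.
    """
    if n_max % 2 != 0 or n_max < 0:
        raise ValueError(f"n_max must be even and non-negative, got {n_max}")
    half = n_max // 2
    return (half + 1) * (half + 2) * (2 * n_max + 3) // 6


def enumerate_indices(n_max: int) -> list[tuple[int, int, int]]:
    """Ordered list of (n1, n2, n3) with n1+n2+n3 even and <= n_max."""
    if n_max % 2 != 0 or n_max < 0:
        raise ValueError(f"n_max must be even and non-negative, got {n_max}")
    indices = [
        (n1, n2, total - n1 - n2)
        for total in range(0, n_max + 1, 2)
        for n1 in range(total + 1)
        for n2 in range(total - n1 + 1)
    ]
    # lexicographic within each total order
    indices.sort(key=lambda t: (sum(t), t))
    assert len(indices) == n_coef(n_max)
    return indices


def _hermite_norm(n: np.ndarray | int) -> np.ndarray:
    """(2^n n!)^(-1/2) via log-gamma, stable for large n."""
    n = np.asarray(n, dtype=float)
    return np.exp(-0.5 * (n * np.log(2.0) + gammaln(n + 1.0)))


def phi_1d(n: int, u: float, q) -> complex | np.ndarray:
    """1-D q-space Hermite basis function.

    phi_n(u, q) = i^(-n) (2^n n!)^(-1/2) exp(-2 pi^2 q^2 u^2) H_n(2 pi u q)

    Purely real for even n, purely imaginary for odd n.
    """
    if n < 0:
        raise ValueError("order must be non-negative")
    if u <= 0:
        raise ValueError("scale u must be positive")
    q = np.asarray(q, dtype=float)
    x = 2.0 * np.pi * u * q
    real_part = _hermite_norm(n) * np.exp(-(x**2) / 2.0) * eval_hermite(n, x)
    out = np.asarray((-1j) ** n * real_part)  # i^(-n) = (-i)^n
    if out.ndim == 0:
        return complex(out)
    return out


def psi_1d(n: int, u: float, x) -> float | np.ndarray:
    """1-D displacement-space Hermite basis function.

    psi_n(u, x) = (2^(n+1) pi n!)^(-1/2) u^(-1) exp(-x^2 / 2u^2) H_n(x/u)

    For n = 0 this is the N(0, u^2) probability density.
    """
    if n < 0:
        raise ValueError("order must be non-negative")
    if u <= 0:
        raise ValueError("scale u must be positive")
    x = np.asarray(x, dtype=float)
    t = x / u
    norm = np.exp(-0.5 * (n * np.log(2.0) + gammaln(n + 1.0))) / np.sqrt(2.0 * np.pi) / u
    out = norm * np.exp(-(t**2) / 2.0) * eval_hermite(n, t)
    if out.ndim == 0:
        return float(out)
    return out


def _phi_factors(n_max: int, u: float, q: np.ndarray) -> np.ndarray:
    """(n_max+1, len(q)) matrix of |phi_n| factors (without the i^(-n))."""
    x = 2.0 * np.pi * u * np.asarray(q, dtype=float)
    env = np.exp(-(x**2) / 2.0)
    return np.stack(
        [_hermite_norm(n) * env * eval_hermite(n, x) for n in range(n_max + 1)]
    )


def _psi_factors(n_max: int, u: float, x: np.ndarray) -> np.ndarray:
    """(n_max+1, len(x)) matrix of psi_n values."""
    return np.stack([psi_1d(n, u, x) for n in range(n_max + 1)])


def design_matrix(
    frame: TensorFrame,
    scheme: AcquisitionScheme,
    n_max: int,
    indices: list[tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """T x N_coef design matrix Q of 3-D basis functions Phi.

    q-vectors are rotated into the tensor eigenframe (q' = R^T q) before
    the separable 1-D factors are taken.  The complex prefactor
    i^(-N) equals (-1)^(N/2) because the total order N is always even,
    so Q is real.
    """
    if indices is None:
        indices = enumerate_indices(n_max)
    q = q_vectors(scheme) @ frame.R  # rows are R^T q
    fx = _phi_factors(n_max, frame.u[0], q[:, 0])
    fy = _phi_factors(n_max, frame.u[1], q[:, 1])
    fz = _phi_factors(n_max, frame.u[2], q[:, 2])
    cols = [
        (-1.0) ** ((n1 + n2 + n3) // 2) * fx[n1] * fy[n2] * fz[n3]
        for n1, n2, n3 in indices
    ]
    return np.column_stack(cols)


@dataclass(frozen=True)
class ConstraintGrid:
    """Cartesian r-space grid on which the propagator is constrained.

    ``points`` are the M grid locations in mm (eigenframe coordinates),
    ``weights`` the per-point quadrature volumes in mm^3 used for the
    half-space integral bound.  Points on the z = 0 plane carry half a
    cell volume because their cell extends only into z > 0.
    """

    points: np.ndarray
    weights: np.ndarray
    shape: tuple[int, int, int]
    cell_volume: float


def constraint_matrix(
    frame: TensorFrame,
    n_max: int,
    grid_shape: tuple[int, int, int] = (21, 21, 11),
    extent_factor: float = 6.0,
    indices: list[tuple[int, int, int]] | None = None,
) -> tuple[np.ndarray, ConstraintGrid]:
    """M x N_coef matrix K of Psi values on a half-space grid.

    The grid spans +/- extent_factor * u_i along each eigenframe axis
    and [0, extent_factor * u_z] in z (the propagator is antipodally
    symmetric, so the positive-z half suffices).  Scaling the extent
    per axis keeps the grid spacing proportional to the propagator
    width in every direction, so the discretized half-space integral
    of a Gaussian propagator is accurate to ~1e-9 even for strongly
    anisotropic frames.  The default 21x21x11 grid has 4851 points.
    """
    if indices is None:
        indices = enumerate_indices(n_max)
    nx, ny, nz = grid_shape
    ex, ey, ez = extent_factor * frame.u
    xs = np.linspace(-ex, ex, nx)
    ys = np.linspace(-ey, ey, ny)
    zs = np.linspace(0.0, ez, nz)
    if nx % 2:
        xs[nx // 2] = 0.0  # exact origin despite linspace rounding
    if ny % 2:
        ys[ny // 2] = 0.0
    dx = xs[1] - xs[0] if nx > 1 else 2 * ex
    dy = ys[1] - ys[0] if ny > 1 else 2 * ey
    dz = zs[1] - zs[0] if nz > 1 else ez
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    fx = _psi_factors(n_max, frame.u[0], points[:, 0])
    fy = _psi_factors(n_max, frame.u[1], points[:, 1])
    fz = _psi_factors(n_max, frame.u[2], points[:, 2])
    K = np.column_stack(
        [fx[n1] * fy[n2] * fz[n3] for n1, n2, n3 in indices]
    )

    cell = dx * dy * dz
    weights = np.full(points.shape[0], cell)
    weights[points[:, 2] == 0.0] *= 0.5  # boundary plane: half cell in z
    grid = ConstraintGrid(points=points, weights=weights, shape=grid_shape, cell_volume=cell)
    return K, grid
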