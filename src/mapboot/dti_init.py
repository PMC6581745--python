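"""Initial diffusion-tensor fit and the MAP anatomical frame.

The Hermite basis is anchored to a voxel-specific frame derived from a
single diffusion tensor: its eigenvectors give the rotation R and its
eigenvalues the displacement scale lengths u_i = sqrt(2 lambda_i t_d),
the standard deviations of Gaussian displacement over the diffusion
time.  The tensor is fitted on the low-b subset of the data by two-pass
weighted least squares on the log signal (ordinary LS first, then
weights equal to the squared predicted signals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mapboot.scheme_io import AcquisitionScheme

logger = logging.getLogger(__name__)

#: Eigenvalue clamp floor (mm^2/s) keeping u_i > 0 for degenerate voxels.
EIGENVALUE_FLOOR = 1e-5

#: Default exclusive b-value cutoff (s/mm^2) for the tensor subset.
DEFAULT_B_MAX = 2000.0

# schemes for which the single-shell extension was already logged
_extended_schemes: set = set()


@dataclass(frozen=True)
class TensorFit:
    """A fitted diffusion tensor with its eigensystem."""

    D: np.ndarray
    S0_est: float
    eigenvalues: np.ndarray  # sorted descending, mm^2/s
    R: np.ndarray  # columns are eigenvectors, det +1

    @property
    def md(self) -> float:
        """Mean diffusivity (mm^2/s)."""
        return float(np.mean(self.eigenvalues))

    @property
    def fa(self) -> float:
        """Fractional anisotropy."""
        lam = self.eigenvalues
        md = lam.mean()
        num = np.sum((lam - md) ** 2)
        den = np.sum(lam**2)
        if den == 0:
            return 0.0
        return float(np.sqrt(1.5 * num / den))


@dataclass(frozen=True)
class TensorFrame:
    """Rotation R and scale lengths u (mm) of the MAP basis."""

    R: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        if np.any(self.u <= 0):
            raise ValueError("scale lengths must be positive")

    @property
    def det_A(self) -> float:
        """|A| = (u_x u_y u_z)^2."""
        return float(np.prod(self.u) ** 2)


def _design_rows(scheme: AcquisitionScheme, idx: np.ndarray) -> np.ndarray:
    """Log-linear tensor design: columns [1, -b gx^2, ..., -2b gy gz]."""
    b = scheme.bvals[idx]
    g = scheme.bvecs[idx]
    return np.column_stack(
        [
            np.ones(idx.size),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _beta_to_tensor(beta: np.ndarray) -> tuple[np.ndarray, float]:
    D = np.array(
        [
            [beta[1], beta[4], beta[5]],
            [beta[4], beta[2], beta[6]],
            [beta[5], beta[6], beta[3]],
        ]
    )
    return D, float(np.exp(beta[0]))


def _canonical_eigensystem(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and a right-handed, sign-fixed rotation."""
    lam, V = np.linalg.eigh(D)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    # deterministic signs: largest-|component| of each eigenvector positive
    for j in range(3):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return lam, V


def fit_dti_wls(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    b_max: float = DEFAULT_B_MAX,
) -> TensorFit:
    """Weighted least-squares tensor fit on measurements with b < b_max.

    Two passes: an ordinary LS fit of ln(y) on the tensor design gives
    predicted signals, whose squares are then the WLS weights (the
    delta-method variance of ln(y) under additive noise is sigma^2/y^2).
    Non-positive signals in the subset are excluded with a warning.

    Degeneracy guard: on a single shell the intercept is exactly
    collinear with the tensor columns (sum g_i^2 = 1), so a b < b_max
    subset containing only one nonzero shell would make S0 pivot
    entirely on the b0 measurements.  In that case the subset is
    extended to the next-lowest shell (logged) so S0 and the
    eigenvalues are jointly identified from more than one shell.
    """
    signal = np.asarray(signal, dtype=float)
    subset = np.flatnonzero(scheme.bvals < b_max)
    nonzero_shells = {b for b, _ in scheme.subset(subset).shells()}
    if len(nonzero_shells) < 2:
        higher = np.unique(scheme.bvals[scheme.bvals >= b_max])
        if higher.size:
            next_shell = higher[0]
            key = (b_max, round(next_shell))
            if key not in _extended_schemes:
                _extended_schemes.add(key)
                logger.warning(
                    "tensor subset has %d nonzero shell(s); extending to b <= %.0f",
                    len(nonzero_shells),
                    next_shell,
                )
            subset = np.flatnonzero(scheme.bvals <= next_shell + 50.0)
    usable = subset[signal[subset] > 0]
    if usable.size < subset.size:
        logger.warning(
            "excluding %d non-positive signals from tensor fit", subset.size - usable.size
        )
    if usable.size < 7:
        raise ValueError(
            f"need >= 7 usable measurements with b < {b_max}, have {usable.size}"
        )
    if not np.any(scheme.bvals[usable] == 0):
        raise ValueError("tensor fit requires at least one b=0 measurement")
    X = _design_rows(scheme, usable)
    logy = np.log(signal[usable])
    beta_ols, *_ = np.linalg.lstsq(X, logy, rcond=None)
    yhat = np.exp(X @ beta_ols)
    w = yhat  # sqrt of weights w_i = yhat_i^2
    beta, *_ = np.linalg.lstsq(X * w[:, None], logy * w, rcond=None)
    D, s0 = _beta_to_tensor(beta)
    lam, R = _canonical_eigensystem(D)
    return TensorFit(D=D, S0_est=s0, eigenvalues=lam, R=R)


def frame_from_tensor(fit: TensorFit, t_d: float) -> TensorFrame:
    """Scale lengths u_i = sqrt(2 lambda_i t_d) with eigenvalue clamping."""
    if t_d <= 0:
        raise ValueError("t_d must be positive")
    lam = np.asarray(fit.eigenvalues, dtype=float)
    clamped = np.maximum(lam, EIGENVALUE_FLOOR)
    if np.any(lam < EIGENVALUE_FLOOR):
        logger.warning(
            "clamping %d eigenvalues below %.1e mm^2/s", int(np.sum(lam < EIGENVALUE_FLOOR)), EIGENVALUE_FLOOR
        )
    u = np.sqrt(2.0 * clamped * t_d)
    return TensorFrame(R=fit.R, u=u)


def isotropic_frame(frame: TensorFrame) -> TensorFrame:
    """Frame with equalized scales u0 = geometric mean of u.

    The rotation is kept so the isotropic projection is evaluated in
    the voxel's own anatomical frame, making the construction
    covariant under joint rotation of gradients and tissue.  (With
    equal scales the basis span itself is rotation-invariant.)
    """
    u0 = float(np.prod(frame.u) ** (1.0 / 3.0))
    return TensorFrame(R=frame.R, u=np.full(3, u0))
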