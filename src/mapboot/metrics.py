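"""Scalar indices derived from MAP coefficients: RTOP, NG, PA.

RTOP, the return-to-origin probability P(0), is a linear functional of
the coefficients; its reciprocal estimates the mean pore volume.  NG
and PA are sines of angles between coefficient vectors: NG measures how
far the propagator is from its best Gaussian part (the (0,0,0) term),
PA how far it is from its isotropic part.  Both therefore live in
[0, 1] by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import factorial, factorial2

from mapboot.dti_init import isotropic_frame
from mapboot.map_basis import design_matrix
from mapboot.map_fit import MapModel
from mapboot.scheme_io import AcquisitionScheme

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricSet:
    """The four per-voxel scalars."""

    rtop: float  # mm^-3
    mean_volume: float  # mm^3
    ng: float
    pa: float


def b_coeff(n1: int, n2: int, n3: int) -> float:
    """RTOP weight for index (n1, n2, n3).

    Zero unless all indices are even, otherwise
    sqrt(n1! n2! n3!) / (n1!! n2!! n3!!).
    """
    if any(n < 0 for n in (n1, n2, n3)):
        raise ValueError("indices must be non-negative")
    if any(n % 2 for n in (n1, n2, n3)):
        return 0.0
    num = np.sqrt(factorial(n1) * factorial(n2) * factorial(n3))
    den = factorial2(n1) * factorial2(n2) * factorial2(n3)
    return float(num / den)


def rtop(model: MapModel) -> float:
    """Return-to-origin probability in mm^-3.

    RTOP = (8 pi^3 |A|)^(-1/2) sum (-1)^(N/2) a_n B_n with
    |A| = (u_x u_y u_z)^2.  A non-positive value indicates a
    pathological fit and is returned as NaN.
    """
    det_a = model.frame.det_A
    total = sum(
        (-1.0) ** (sum(idx) // 2) * a * b_coeff(*idx)
        for idx, a in zip(model.indices, model.a)
    )
    value = total / np.sqrt(8.0 * np.pi**3 * det_a)
    if value <= 0:
        logger.warning("non-positive RTOP (%.3e); flagging voxel as NaN", value)
        return float("nan")
    return float(value)


def mean_volume(model: MapModel) -> float:
    """Mean pore volume <V> = 1/RTOP (mm^3)."""
    r = rtop(model)
    return float(1.0 / r)


def ng(a: np.ndarray, sqrt_form: bool = True) -> float:
    """Non-Gaussianity of a coefficient vector.

    sqrt(1 - a_000^2 / ||a||^2): the sine of the angle between the
    coefficient vector and its Gaussian ((0,0,0)) component.  With
    ``sqrt_form=False`` the outer square root is omitted.
    """
    a = np.asarray(a, dtype=float)
    ss = a @ a
    if ss == 0 or not np.isfinite(ss):
        logger.warning("zero or non-finite coefficient norm in NG")
        return float("nan")
    val = 1.0 - a[0] ** 2 / ss
    val = min(max(val, 0.0), 1.0)
    return float(np.sqrt(val)) if sqrt_form else float(val)


def pa(a: np.ndarray, o: np.ndarray, sqrt_form: bool = True) -> float:
    """Propagator anisotropy between a vector and its isotropic part.

    sqrt(1 - <a,o>^2 / (||a||^2 ||o||^2)): the sine of the angle
    between the full coefficient vector a and the isotropic-basis
    coefficients o.
    """
    a = np.asarray(a, dtype=float)
    o = np.asarray(o, dtype=float)
    na, no = a @ a, o @ o
    if na == 0 or no == 0 or not (np.isfinite(na) and np.isfinite(no)):
        logger.warning("zero or non-finite coefficient norm in PA")
        return float("nan")
    cos2 = (a @ o) ** 2 / (na * no)
    val = min(max(1.0 - cos2, 0.0), 1.0)
    return float(np.sqrt(val)) if sqrt_form else float(val)


def isotropic_coeffs(
    model: MapModel, scheme: AcquisitionScheme | None = None
) -> np.ndarray:
    """Coefficients of the propagator's isotropic part.

    The fitted signal Q a is projected by least squares onto the design
    matrix built with the isotropic frame (same rotation, equal scales
    u0 = geometric mean of u) at the same order.
    """
    if scheme is None:
        scheme = model.scheme
    if scheme is None:
        raise ValueError("scheme required to build the isotropic design")
    iso = isotropic_frame(model.frame)
    n_max = max(sum(idx) for idx in model.indices)
    Q_iso = design_matrix(iso, scheme, n_max, indices=model.indices)
    target = model.fitted
    o, res, rank, sv = np.linalg.lstsq(Q_iso, target, rcond=None)
    if rank < Q_iso.shape[1]:
        logger.warning("rank-deficient isotropic projection; ridge fallback")
        A = Q_iso.T @ Q_iso + 1e-10 * np.eye(Q_iso.shape[1])
        o = np.linalg.solve(A, Q_iso.T @ target)
    return o


def metric_set(model: MapModel, scheme: AcquisitionScheme | None = None) -> MetricSet:
    """All four scalars for a fitted voxel."""
    r = rtop(model)
    o = isotropic_coeffs(model, scheme)
    return MetricSet(
        rtop=r,
        mean_volume=float(1.0 / r) if np.isfinite(r) else float("nan"),
        ng=ng(model.a),
        pa=pa(model.a, o),
    )


def rtpp(model: MapModel) -> float:
    """Return-to-plane probability (mm^-1), 1-D analogue of RTOP.

    The marginal density of displacement along the principal (x) axis
    at zero: psi_n(u, 0) contributes (-1)^(n/2) B_n / sqrt(2 pi u^2)
    and each transverse marginal integral contributes B_n, so

    RTPP = (2 pi u_x^2)^(-1/2) sum (-1)^(n1/2) a_n B_n1 B_n2 B_n3

    over all-even indices.  Optional extra alongside the headline
    metrics.
    """
    u_x = model.frame.u[0]
    total = sum(
        (-1.0) ** (idx[0] // 2) * a * b_coeff(*idx)
        for idx, a in zip(model.indices, model.a)
    )
    return float(total / np.sqrt(2.0 * np.pi * u_x**2))


def rtap(model: MapModel) -> float:
    """Return-to-axis probability (mm^-2), 2-D analogue of RTOP.

    Density of transverse displacement at zero, integrated along the
    principal axis: (2 pi u_y u_z)^(-1) sum (-1)^((n2+n3)/2) a B B B.
    """
    u_y, u_z = model.frame.u[1], model.frame.u[2]
    total = sum(
        (-1.0) ** ((idx[1] + idx[2]) // 2) * a * b_coeff(*idx)
        for idx, a in zip(model.indices, model.a)
    )
    return float(total / (2.0 * np.pi * u_y * u_z))
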