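"""Acquisition schemes, diffusion volumes and metric-map I/O.

Gradient tables follow the FSL dialect: a ``.bval`` file with one
b-value (s/mm^2) per measurement and a ``.bvec`` file with three rows
(x, y, z components of the unit gradient directions).  Transposed bvec
files (three columns) are detected automatically.  Volumes are NIfTI-1,
read and written through nibabel with the affine carried unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: b-values closer than this (s/mm^2) are treated as one shell.
SHELL_TOLERANCE = 50.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """A multi-shell acquisition: b-values, directions and pulse timing.

    Parameters
    ----------
    bvals : (T,) array
        Diffusion weightings in s/mm^2, non-negative.
    bvecs : (T, 3) array
        Unit gradient directions; rows for b = 0 may be zero.
    delta_small : float
        Gradient pulse duration delta in seconds.
    delta_big : float
        Pulse separation Delta in seconds.
    t_d : float
        Effective diffusion time in seconds.  By default the
        Stejskal-Tanner value ``Delta - delta/3``.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    delta_small: float
    delta_big: float
    t_d: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-values")
        t_d = self.t_d
        if t_d is None:
            t_d = self.delta_big - self.delta_small / 3.0
        if t_d <= 0:
            raise ValueError(f"effective diffusion time must be positive, got {t_d}")
        dwi = bvals > 0
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(norms == 0):
            raise ValueError("zero gradient direction at b > 0")
        if np.any(np.abs(norms - 1.0) > 1e-6):
            logger.warning(
                "renormalizing %d non-unit gradient directions",
                int(np.sum(np.abs(norms - 1.0) > 1e-6)),
            )
        bvecs = bvecs.copy()
        bvecs[dwi] /= norms[:, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "t_d", float(t_d))

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_measurements(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_dwi(self) -> int:
        """Number of diffusion-weighted (b > 0) measurements."""
        return int(np.sum(self.bvals > 0))

    def shells(self) -> list[tuple[float, int]]:
        """Group b > 0 measurements into shells within +/-50 s/mm^2.

        Returns a list of (mean b-value, count) sorted by b.
        """
        bs = np.sort(self.bvals[self.bvals > 0])
        out: list[list[float]] = []
        for b in bs:
            if out and b - out[-1][0] <= SHELL_TOLERANCE:
                out[-1].append(b)
            else:
                out.append([b])
        return [(float(np.mean(g)), len(g)) for g in out]

    def subset(self, idx: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted to measurement indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return AcquisitionScheme(
            self.bvals[idx], self.bvecs[idx], self.delta_small, self.delta_big, self.t_d
        )


@dataclass
class VolumeStack:
    """A 4-D diffusion volume with its mask and voxel geometry.

    Scanner magnitude data is non-negative and validation enforces
    that; synthetic volumes with additive Gaussian noise may carry
    negative samples and can opt out via ``allow_negative``.
    """

    data: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    voxel_size: np.ndarray = None  # type: ignore[assignment]
    affine: np.ndarray = None  # type: ignore[assignment]
    allow_negative: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got {self.data.ndim}-D")
        if not self.allow_negative and np.any(self.data < 0):
            raise ValueError("negative signal intensities")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"data spatial shape {self.data.shape[:3]}"
                )
        if self.voxel_size is None:
            self.voxel_size = np.ones(3)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_signals(self) -> np.ndarray:
        """(n_voxels, T) signal array over in-mask voxels (C order)."""
        return self.data[self.mask]


def _load_table(path) -> np.ndarray:
    try:
        return np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric token in gradient table {path}: {exc}") from exc


def read_scheme(
    bval_path,
    bvec_path,
    delta_small: float,
    delta_big: float,
    t_d: float | None = None,
) -> AcquisitionScheme:
    """Read an FSL-style .bval/.bvec pair into an AcquisitionScheme.

    The bvec orientation (3 rows vs 3 columns) is auto-detected; when
    ``t_d`` is omitted it defaults to ``Delta - delta/3``.
    """
    bvals = _load_table(bval_path).ravel()
    bvecs = _load_table(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        if bvecs.shape[0] == 3:  # ambiguous 3x3: FSL convention, rows are x/y/z
            bvecs = bvecs.T
        else:
            raise ValueError(f"bvec table must have 3 rows or columns, got {bvecs.shape}")
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"{bvals.size} b-values but {bvecs.shape[0]} gradient directions"
        )
    return AcquisitionScheme(bvals, bvecs, delta_small, delta_big, t_d)


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write .bval/.bvec in FSL layout (one row of b-values, 3 rows of vecs)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10g")


def q_from_scheme(scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """q-space magnitudes (1/mm) and unit directions for each measurement.

    Uses the short-pulse relation b = 4 pi^2 |q|^2 t_d, so
    ``|q| = sqrt(b / (4 pi^2 t_d))``.
    """
    if scheme.t_d <= 0:
        raise ValueError("invalid scheme: t_d must be positive")
    qmag = np.sqrt(scheme.bvals / (4.0 * np.pi**2 * scheme.t_d))
    return qmag, scheme.bvecs


def q_vectors(scheme: AcquisitionScheme) -> np.ndarray:
    """(T, 3) array of q-vectors in 1/mm."""
    qmag, dirs = q_from_scheme(scheme)
    return qmag[:, None] * dirs


def read_volumes(nifti_path, mask_path=None, allow_negative: bool = False) -> VolumeStack:
    """Load a 4-D NIfTI (and optional 3-D mask) into a VolumeStack.

    CSF or empty-voxel exclusion is the caller's responsibility via the
    mask; without one, every voxel is in-mask.  Scanner magnitude data
    is non-negative and validated as such; ``allow_negative=True``
    admits synthetic volumes with additive Gaussian noise.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got {data.ndim}-D")
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return VolumeStack(
        data,
        mask=mask,
        voxel_size=voxel_size,
        affine=img.affine,
        allow_negative=allow_negative,
    )


def write_metric_map(
    values: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    out_path,
    fill: float = 0.0,
) -> None:
    """Write per-voxel scalars into a 3-D NIfTI; out-of-mask voxels get ``fill``.

    ``values`` is indexed by the in-mask voxels in C order (the order of
    ``VolumeStack.voxel_signals``).  NaNs (failed voxels) are written as
    NaN and counted in a log message.
    """
    values = np.asarray(values, dtype=np.float32)
    mask = np.asarray(mask).astype(bool)
    if values.size != mask.sum():
        raise ValueError(
            f"{values.size} values for {int(mask.sum())} in-mask voxels"
        )
    vol = np.full(mask.shape, fill, dtype=np.float32)
    vol[mask] = values
    n_nan = int(np.sum(np.isnan(values)))
    if n_nan:
        logger.warning("writing %d NaN voxels (failed fits) to %s", n_nan, out_path)
    nib.save(nib.Nifti1Image(vol, affine), str(out_path))


def write_volume_stack(stack: VolumeStack, out_path) -> None:
    """Write the 4-D data of a VolumeStack to NIfTI."""
    nib.save(nib.Nifti1Image(stack.data.astype(np.float32), stack.affine), str(out_path))
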