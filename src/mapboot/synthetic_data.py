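"""Synthetic multi-shell phantom with known ground truth.

Emulates a physical crossing-fiber phantom: single-fiber voxels contain
one anisotropic Gaussian compartment, two-fiber voxels an equal mixture
of two identical tensors whose principal axes cross at 45 degrees, and
background voxels are isotropic (free-water-like).  Scheme presets
mirror the SPARC challenge acquisitions (three shells at b = 1000-3000
s/mm^2 with 20/30/60 directions per shell, and a five-shell
gold-standard with 81 directions per shell) plus the HCP-MGH shell
listing; all presets include b = 0 measurements.

The compartments are Gaussian, so the generated signals have no
restricted-diffusion (truly non-Gaussian) component; crossing-fiber
mixtures are still non-Gaussian as mixtures of Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mapboot.scheme_io import AcquisitionScheme, VolumeStack

#: Typical white-matter single-fiber eigenvalues (mm^2/s).
DEFAULT_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)

#: Free-water-like isotropic diffusivity (mm^2/s).
DEFAULT_ISO_DIFFUSIVITY = 2.0e-3

DEFAULT_S0 = 100.0
DEFAULT_CROSSING_ANGLE = 45.0

#: SPARC phantom pulse timing (s): delta = Delta = 62 ms.
SPARC_DELTA_SMALL = 0.062
SPARC_DELTA_BIG = 0.062

#: HCP-MGH pulse timing (s).
HCP_DELTA_SMALL = 0.0129
HCP_DELTA_BIG = 0.0218


@dataclass
class PhantomTruth:
    """Ground truth for every voxel of a synthetic phantom."""

    fiber_count: np.ndarray  # (X, Y, Z) ints in {0, 1, 2}
    tensors: dict  # voxel index -> list of 3x3 tensors
    fractions: dict  # voxel index -> mixing fractions
    clean_signal: np.ndarray  # (X, Y, Z, T) noise-free
    snr: float
    s0: float


def generate_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Approximately uniform unit vectors via electrostatic repulsion.

    Starts from seeded random points on the sphere and runs a fixed
    number of antipodally symmetric repulsion steps (charges interact
    with both the other points and their antipodes, the relevant
    symmetry for diffusion gradients).  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if n == 1:
        return v
    step = 0.1
    for it in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]  # i - (+/-)j
            d2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if sign < 0:
                d2[d2 < 1e-12] = np.inf  # own antipode for near-degenerate pairs
            force += np.sum(diff / (d2[..., None] ** 1.5 + 1e-12), axis=1)
        # project onto the tangent plane and take a small step
        force -= np.sum(force * v, axis=1, keepdims=True) * v
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        v = v + step * force / norm
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.97
    return v


def tensor_signal(D: np.ndarray, scheme: AcquisitionScheme, S0: float = DEFAULT_S0) -> np.ndarray:
    """Gaussian (single-tensor) signal S(b, g) = S0 exp(-b g^T D g)."""
    D = np.asarray(D, dtype=float)
    eigs = np.linalg.eigvalsh(D)
    if np.any(eigs <= 0):
        raise ValueError("diffusion tensor must be positive-definite")
    g = scheme.bvecs
    adc = np.einsum("ti,ij,tj->t", g, D, g)
    return S0 * np.exp(-scheme.bvals * adc)


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def fiber_tensor(eigenvalues=DEFAULT_EIGENVALUES, axis_angle_deg: float = 0.0) -> np.ndarray:
    """Axially symmetric tensor with principal axis in the x-y plane."""
    R = _rotation_z(axis_angle_deg)
    return R @ np.diag(eigenvalues) @ R.T


def voxel_compartments(
    fiber_count: int,
    eigenvalues=DEFAULT_EIGENVALUES,
    iso_diffusivity: float = DEFAULT_ISO_DIFFUSIVITY,
    crossing_angle: float = DEFAULT_CROSSING_ANGLE,
    fraction: float = 0.5,
) -> tuple[list[np.ndarray], list[float]]:
    """Compartment tensors and mixing fractions for one voxel."""
    if fiber_count == 0:
        return [np.eye(3) * iso_diffusivity], [1.0]
    if fiber_count == 1:
        return [fiber_tensor(eigenvalues, 0.0)], [1.0]
    if fiber_count == 2:
        half = crossing_angle / 2.0
        return (
            [fiber_tensor(eigenvalues, -half), fiber_tensor(eigenvalues, half)],
            [fraction, 1.0 - fraction],
        )
    raise ValueError(f"unknown fiber count {fiber_count}")


def build_phantom(
    layout: np.ndarray,
    scheme: AcquisitionScheme,
    S0: float = DEFAULT_S0,
    eigenvalues=DEFAULT_EIGENVALUES,
    iso_diffusivity: float = DEFAULT_ISO_DIFFUSIVITY,
    crossing_angle: float = DEFAULT_CROSSING_ANGLE,
    fraction: float = 0.5,
    snr: float = np.inf,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> tuple[VolumeStack, PhantomTruth]:
    """Build a phantom volume from a fiber-count layout.

    ``layout`` is a 3-D integer array: 0 = isotropic background,
    1 = single fiber, 2 = two fibers crossing at ``crossing_angle``.
    Two-fiber signals are the fraction-weighted mixture of the two
    rotated single-fiber signals.  Noise (if snr is finite) is added
    independently per voxel and measurement.
    """
    layout = np.atleast_3d(np.asarray(layout, dtype=int))
    T = scheme.n_measurements
    clean = np.zeros(layout.shape + (T,))
    tensors: dict = {}
    fractions: dict = {}
    signal_cache: dict[int, np.ndarray] = {}
    for count in np.unique(layout):
        comps, fracs = voxel_compartments(
            int(count), eigenvalues, iso_diffusivity, crossing_angle, fraction
        )
        signal_cache[int(count)] = sum(
            f * tensor_signal(D, scheme, S0) for D, f in zip(comps, fracs)
        )
        for idx in zip(*np.nonzero(layout == count)):
            tensors[idx] = comps
            fractions[idx] = fracs
    for count, sig in signal_cache.items():
        clean[layout == count] = sig
    noisy = add_noise(clean, snr, model=noise_model, S0_reference=S0, seed=seed)
    stack = VolumeStack(noisy, mask=np.ones(layout.shape, bool), allow_negative=True)
    truth = PhantomTruth(
        fiber_count=layout,
        tensors=tensors,
        fractions=fractions,
        clean_signal=clean,
        snr=snr,
        s0=S0,
    )
    return stack, truth


def add_noise(
    signal: np.ndarray,
    snr: float,
    model: str = "gaussian",
    S0_reference: float = DEFAULT_S0,
    seed: int = 0,
) -> np.ndarray:
    """Add noise at a given SNR (mean b0 signal over noise std).

    gaussian: y = s + e, e ~ N(0, sigma^2) with sigma = S0/snr.
    rician:   y = sqrt((s + e1)^2 + e2^2), magnitude of a complex
              signal with independent N(0, sigma^2) channel noise.
    ``snr = inf`` returns the signal unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if not snr > 0:
        raise ValueError(f"snr must be positive, got {snr}")
    if np.isinf(snr):
        return signal.copy()
    sigma = S0_reference / snr
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    if model == "rician":
        e1 = rng.normal(0.0, sigma, signal.shape)
        e2 = rng.normal(0.0, sigma, signal.shape)
        return np.sqrt((signal + e1) ** 2 + e2**2)
    raise ValueError(f"unknown noise model {model!r}")


def estimate_snr(stack: VolumeStack, scheme: AcquisitionScheme, clean: np.ndarray) -> float:
    """Empirical SNR: mean in-mask b0 signal over the noise std."""
    b0 = stack.data[..., scheme.b0_mask][stack.mask]
    noise = (stack.data - clean)[stack.mask]
    return float(np.mean(b0) / np.std(noise))


def _shell_scheme(
    shells: list[tuple[float, int]],
    n_b0: int,
    delta_small: float,
    delta_big: float,
    seed: int = 0,
) -> AcquisitionScheme:
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for k, (b, n_dir) in enumerate(shells):
        dirs = generate_directions(n_dir, seed=seed + k)
        bvals.extend([b] * n_dir)
        bvecs.extend(dirs)
    return AcquisitionScheme(np.array(bvals), np.array(bvecs), delta_small, delta_big)


def preset_scheme(name: str, seed: int = 0) -> AcquisitionScheme:
    """Named acquisition presets.

    sparc20/sparc30/sparc60: three shells (b = 1000, 2000, 3000 s/mm^2)
    with 20/30/60 directions per shell plus one b0.  sparcgold: five
    shells (b = 1000..5000) with 81 directions per shell plus one b0
    (406 measurements).  hcp_mgh: 40 b0 volumes plus the four-shell
    listing 64/64/128/256 at b = 1000/3000/5000/10000 (552 volumes).
    """
    name = name.lower().replace("-", "").replace("_", "")
    if name in ("sparc20", "sparc30", "sparc60"):
        n = int(name[5:])
        return _shell_scheme(
            [(1000.0, n), (2000.0, n), (3000.0, n)],
            1,
            SPARC_DELTA_SMALL,
            SPARC_DELTA_BIG,
            seed=seed,
        )
    if name == "sparcgold":
        return _shell_scheme(
            [(b, 81) for b in (1000.0, 2000.0, 3000.0, 4000.0, 5000.0)],
            1,
            SPARC_DELTA_SMALL,
            SPARC_DELTA_BIG,
            seed=seed,
        )
    if name == "hcpmgh":
        return _shell_scheme(
            [(1000.0, 64), (3000.0, 64), (5000.0, 128), (10000.0, 256)],
            40,
            HCP_DELTA_SMALL,
            HCP_DELTA_BIG,
            seed=seed,
        )
    raise ValueError(f"unknown scheme preset {name!r}")


def default_layout(shape: tuple[int, int, int] = (6, 6, 1)) -> np.ndarray:
    """A small layout with background, single-fiber and crossing bands."""
    layout = np.zeros(shape, dtype=int)
    third = max(shape[0] // 3, 1)
    layout[third : 2 * third] = 1
    layout[2 * third :] = 2
    return layout


def subsample_scheme(
    scheme: AcquisitionScheme, keep_fraction: float, seed: int = 0
) -> tuple[AcquisitionScheme, np.ndarray]:
    """Keep a fraction of DWI measurements per shell (b0s always kept).

    Returns the reduced scheme and the kept measurement indices,
    mirroring the reduced-scan-time experiments.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = list(np.flatnonzero(scheme.bvals == 0))
    for b, _ in scheme.shells():
        shell_idx = np.flatnonzero(np.abs(scheme.bvals - b) <= 50.0)
        n_keep = max(int(round(keep_fraction * shell_idx.size)), 1)
        keep.extend(rng.choice(shell_idx, size=n_keep, replace=False))
    keep = np.sort(np.array(keep))
    return scheme.subset(keep), keep
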