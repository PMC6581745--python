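"""Wild-bootstrap uncertainty for MAP-derived metrics.

The wild bootstrap resamples around the fitted regression: each
replicate signal is

    y_i* = (Q a_hat)_i + sqrt(T / (T - N_coef)) * u_i * eps_i

with u_i Rademacher (+/-1 with probability 1/2) and eps_i the original
residuals.  Re-solving the constrained fit for each replicate yields a
bootstrap distribution of coefficients, and of any metric computed
from them; the reported uncertainty is the sample standard deviation
(N_B - 1 denominator) of the replicates.  Because the sign flips
preserve each residual's own magnitude, the scheme is valid when the
noise variance differs across measurements (e.g., between shells).

The tensor frame, and with it Q and K, is held fixed across
replicates: resampling happens around the fitted design.  Re-deriving
the frame per replicate is available via ``refit_frame=True`` for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mapboot.map_fit import FitError, MapModel, fit_map, fit_voxel
from mapboot.map_basis import ConstraintGrid

logger = logging.getLogger(__name__)

DEFAULT_N_B = 500


@dataclass
class BootstrapResult:
    """Bootstrap replicates and summary spread for one metric."""

    metric: str
    replicates: np.ndarray
    std: float
    mean_replicate: float
    n_failed: int

    @property
    def n_usable(self) -> int:
        return self.replicates.size


def rademacher(t: int, seed) -> np.ndarray:
    """Length-t vector of +/-1 with equal probability, seeded."""
    if t < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    return rng.choice(np.array([-1.0, 1.0]), size=t)


def wild_resample(
    fitted: np.ndarray, residuals: np.ndarray, n_coef: int, u: np.ndarray
) -> np.ndarray:
    """One wild-bootstrap replicate signal.

    y* = fitted + sqrt(T / (T - n_coef)) * u * residuals, the global
    heteroscedasticity correction inflating the residuals for the
    degrees of freedom absorbed by the fit.
    """
    fitted = np.asarray(fitted, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    u = np.asarray(u, dtype=float)
    T = fitted.size
    if residuals.size != T or u.size != T:
        raise ValueError("fitted, residuals and u must have equal length")
    if T <= n_coef:
        raise ValueError(f"T={T} must exceed n_coef={n_coef}")
    return fitted + np.sqrt(T / (T - n_coef)) * u * residuals


def bootstrap_std(replicates: np.ndarray) -> float:
    """Sample standard deviation of the replicates (N_B - 1 denominator)."""
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size < 2:
        raise ValueError("need at least two replicates")
    return float(np.std(replicates, ddof=1))


def replicate_seed(seed: int, voxel: int, replicate: int):
    """Deterministic per-replicate seed from (master, voxel, replicate).

    The hierarchy makes serial and parallel execution, and any
    replicate ordering, produce identical draws.
    """
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(voxel), int(replicate)))


def bootstrap_voxel(
    model: MapModel,
    Q: np.ndarray,
    K: np.ndarray,
    weights: np.ndarray | ConstraintGrid,
    metric_fns: dict,
    n_b: int = DEFAULT_N_B,
    seed: int = 0,
    voxel_index: int = 0,
    u_vectors: np.ndarray | None = None,
    max_failed_fraction: float = 0.1,
) -> dict[str, BootstrapResult]:
    """Wild-bootstrap one fitted voxel.

    Parameters
    ----------
    model : MapModel
        The original constrained fit (supplies fitted values and
        residuals).
    metric_fns : dict
        ``{name: fn}`` where each ``fn(MapModel) -> float``.
    u_vectors : optional (n_b, T) array
        Explicit Rademacher vectors (testing hook); by default drawn
        from the (seed, voxel, replicate) hierarchy.
    """
    if n_b < 2:
        raise ValueError("need at least two bootstrap replicates")
    T = model.fitted.size
    values: dict[str, list[float]] = {name: [] for name in metric_fns}
    n_failed = 0
    for r in range(n_b):
        if u_vectors is not None:
            u = np.asarray(u_vectors[r], dtype=float)
        else:
            u = rademacher(T, replicate_seed(seed, voxel_index, r))
        y_star = wild_resample(model.fitted, model.residuals, model.n_coef, u)
        try:
            rep = fit_map(
                y_star,
                Q,
                K,
                weights,
                frame=model.frame,
                indices=model.indices,
                scheme=model.scheme,
            )
        except FitError as exc:
            logger.debug("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        for name, fn in metric_fns.items():
            values[name].append(fn(rep))
    if n_failed > max_failed_fraction * n_b:
        logger.warning(
            "voxel %d: %d/%d bootstrap replicates failed", voxel_index, n_failed, n_b
        )
    out: dict[str, BootstrapResult] = {}
    for name, reps in values.items():
        reps = np.asarray(reps, dtype=float)
        finite = reps[np.isfinite(reps)]
        out[name] = BootstrapResult(
            metric=name,
            replicates=finite,
            std=bootstrap_std(finite) if finite.size >= 2 else float("nan"),
            mean_replicate=float(np.mean(finite)) if finite.size else float("nan"),
            n_failed=n_failed + (reps.size - finite.size),
        )
    return out


def bootstrap_signal(
    signal: np.ndarray,
    scheme,
    n_max: int,
    metric_fns: dict,
    n_b: int = DEFAULT_N_B,
    seed: int = 0,
    voxel_index: int = 0,
    refit_frame: bool = True,
    **fit_kwargs,
) -> tuple[MapModel, dict[str, BootstrapResult]]:
    """Fit a raw voxel signal, then wild-bootstrap the whole estimator.

    With ``refit_frame=True`` (default) each replicate signal is mapped
    back to raw units and the full pipeline -- S0 estimate, tensor
    frame, design and constrained solve -- is re-run, so the bootstrap
    STD reflects the sampling variability of the estimator as actually
    applied, including normalization and frame uncertainty.  With
    ``refit_frame=False`` the design is held fixed (pure regression
    resampling): cheaper, but it measures only the coefficient
    variability conditional on the frame and so understates the total
    uncertainty.
    """
    from mapboot.dti_init import fit_dti_wls
    from mapboot.map_basis import constraint_matrix, design_matrix

    model = fit_voxel(signal, scheme, n_max, **fit_kwargs)
    if not refit_frame:
        Q = design_matrix(model.frame, scheme, n_max, indices=model.indices)
        K, grid = constraint_matrix(model.frame, n_max, indices=model.indices)
        results = bootstrap_voxel(
            model, Q, K, grid, metric_fns, n_b=n_b, seed=seed, voxel_index=voxel_index
        )
        return model, results

    s0 = fit_dti_wls(np.asarray(signal, float), scheme).S0_est
    T = model.fitted.size
    values: dict[str, list[float]] = {name: [] for name in metric_fns}
    n_failed = 0
    for r in range(n_b):
        u = rademacher(T, replicate_seed(seed, voxel_index, r))
        y_star = wild_resample(model.fitted, model.residuals, model.n_coef, u)
        try:
            rep = fit_voxel(s0 * y_star, scheme, n_max, **fit_kwargs)
        except (FitError, ValueError) as exc:
            logger.debug("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        for name, fn in metric_fns.items():
            values[name].append(fn(rep))
    results = {}
    for name, reps in values.items():
        reps = np.asarray(reps, dtype=float)
        finite = reps[np.isfinite(reps)]
        results[name] = BootstrapResult(
            metric=name,
            replicates=finite,
            std=bootstrap_std(finite) if finite.size >= 2 else float("nan"),
            mean_replicate=float(np.mean(finite)) if finite.size else float("nan"),
            n_failed=n_failed + (reps.size - finite.size),
        )
    return model, results
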