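"""Heteroscedasticity screening and uncertainty-weighted group maps.

Before choosing the wild bootstrap, the residuals of each voxel can be
screened with a White-type test.  The default is the reduced form
(Breusch-Pagan auxiliary regression of squared residuals on the fitted
values and their squares): the full White regression needs all
regressor cross-products, which exceeds the number of measurements for
realistic coefficient counts.  Group maps combine subjects with
inverse-variance weights w_n = 1 / sigma_n^2 from the per-subject
bootstrap standard deviations, so noisier subjects contribute less.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan, het_white

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WhiteTestResult:
    statistic: float
    dof: int
    p_value: float
    reject_at_005: bool


def white_test(
    residuals: np.ndarray,
    fitted: np.ndarray,
    alpha: float = 0.05,
    exog: np.ndarray | None = None,
) -> WhiteTestResult:
    """Heteroscedasticity test on one voxel's regression residuals.

    Default (reduced) form: regress eps^2 on {1, yhat, yhat^2}; the LM
    statistic T R^2 is chi-square with 2 degrees of freedom under the
    homoscedastic null.  Passing ``exog`` (a design matrix including a
    constant) runs the full White test with cross-product terms
    instead, when T is large enough to afford it.
    """
    residuals = np.asarray(residuals, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    T = residuals.size
    if T < 10:
        raise ValueError(f"need at least 10 residuals, got {T}")
    if np.var(residuals) <= 1e-20 * (np.mean(residuals**2) + 1e-300):
        logger.warning("zero-variance residuals; returning non-rejection")
        return WhiteTestResult(0.0, 2, 1.0, False)
    if exog is not None:
        lm, lm_p, _, _ = het_white(residuals, exog)
        dof = _white_dof(exog)
        return WhiteTestResult(float(lm), dof, float(lm_p), bool(lm_p < alpha))
    aux = np.column_stack([np.ones(T), fitted, fitted**2])
    if np.linalg.matrix_rank(aux) < 3:
        # constant fitted values: fall back to a degenerate non-rejection
        logger.warning("degenerate auxiliary regressors; returning non-rejection")
        return WhiteTestResult(0.0, 2, 1.0, False)
    lm, lm_p, _, _ = het_breuschpagan(residuals, aux)
    return WhiteTestResult(float(lm), 2, float(lm_p), bool(lm_p < alpha))


def _white_dof(exog: np.ndarray) -> int:
    k = exog.shape[1] - 1  # non-constant columns
    return k + k * (k + 1) // 2


@dataclass
class GroupMap:
    """Voxelwise group summaries across subjects."""

    weighted_mean: np.ndarray
    unweighted_mean: np.ndarray
    normalized_difference: np.ndarray
    weights: np.ndarray  # (n_subjects, ...) per-voxel weights


def weighted_mean(values, stds) -> float:
    """Inverse-variance weighted mean of per-subject scalars.

    x_bar = sum(w_n x_n) / sum(w_n) with w_n = 1 / sigma_n^2.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    stds = np.atleast_1d(np.asarray(stds, dtype=float))
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != stds.shape:
        raise ValueError("values and stds must have the same shape")
    if np.any(stds <= 0):
        raise ValueError("standard deviations must be positive")
    w = 1.0 / stds**2
    return float(np.sum(w * values) / np.sum(w))


def _cap_zero_stds(stds: np.ndarray) -> np.ndarray:
    """Replace zero stds by each subject's 1st percentile of nonzero stds."""
    stds = np.array(stds, dtype=float)
    for n in range(stds.shape[0]):
        zero = stds[n] == 0
        if np.any(zero):
            nonzero = stds[n][stds[n] > 0]
            if nonzero.size == 0:
                raise ValueError(f"subject {n} has all-zero stds")
            cap = np.percentile(nonzero, 1)
            logger.warning(
                "subject %d: capping %d zero stds at %.3e", n, int(zero.sum()), cap
            )
            stds[n][zero] = cap
    return stds


def group_maps(subject_metric_maps, subject_std_maps) -> GroupMap:
    """Weighted and unweighted group means plus normalized difference.

    Inputs are stacked per-subject arrays of identical (co-registered)
    shape.  The normalized difference is
    (unweighted mean - weighted mean) / weighted mean.
    """
    x = np.stack([np.asarray(m, dtype=float) for m in subject_metric_maps])
    s = np.stack([np.asarray(m, dtype=float) for m in subject_std_maps])
    if x.shape != s.shape:
        raise ValueError(f"metric maps {x.shape} and std maps {s.shape} differ in shape")
    s = _cap_zero_stds(s)
    w = 1.0 / s**2
    wmean = np.sum(w * x, axis=0) / np.sum(w, axis=0)
    mean = np.mean(x, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndiff = (mean - wmean) / wmean
    return GroupMap(
        weighted_mean=wmean,
        unweighted_mean=mean,
        normalized_difference=ndiff,
        weights=w,
    )


def region_density(values: np.ndarray, weights: np.ndarray | None = None, n_grid: int = 256):
    """Gaussian kernel density of metric values over a region.

    Silverman-bandwidth KDE, optionally inverse-variance weighted, for
    region-level summaries (e.g., a white-matter structure across
    subjects).  Returns (grid, density).
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least two finite values")
    kde = sps.gaussian_kde(values, bw_method="silverman", weights=weights)
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo if hi > lo else abs(hi) + 1.0)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    return grid, kde(grid)
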