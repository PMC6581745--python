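"""Self-contained synthetic experiments for validating the pipeline.

Each function generates its own data from the phantom presets, runs the
estimator and returns summary numbers.  They are deliberately sized for
a single CPU: bootstrap and Monte-Carlo loops use hundreds (not
thousands) of replicates, which is where the summary statistics have
visibly converged.
"""

from __future__ import annotations

import numpy as np

from mapboot import synthetic_data as sd
from mapboot.map_basis import constraint_matrix, design_matrix
from mapboot.map_fit import FitError, fit_voxel
from mapboot.metrics import isotropic_coeffs, ng, pa, rtop
from mapboot.wild_bootstrap import bootstrap_signal, bootstrap_voxel


def _metric_fns(scheme):
    return {
        "rtop": rtop,
        "ng": lambda m: ng(m.a),
        "pa": lambda m: pa(m.a, isotropic_coeffs(m, scheme)),
    }


def gaussian_limit(preset: str = "sparcgold", n_max: int = 4) -> dict:
    """Noise-free sanity suite against closed-form Gaussian values.

    Fits a matched single-tensor voxel and an isotropic voxel without
    noise and reports NG, PA and the relative RTOP error against the
    Gaussian propagator value ((4 pi t_d)^3 |D|)^(-1/2).
    """
    scheme = sd.preset_scheme(preset, seed=1)
    D = sd.fiber_tensor()
    model = fit_voxel(sd.tensor_signal(D, scheme, 100.0), scheme, n_max)
    expected = ((4 * np.pi * scheme.t_d) ** 3 * np.linalg.det(D)) ** -0.5
    r = rtop(model)
    iso = fit_voxel(
        sd.tensor_signal(sd.DEFAULT_ISO_DIFFUSIVITY * np.eye(3), scheme, 100.0),
        scheme,
        n_max,
    )
    return {
        "ng_gaussian": ng(model.a),
        "pa_isotropic": pa(iso.a, isotropic_coeffs(iso, scheme)),
        "rtop_relative_error": abs(r - expected) / expected,
        "rtop": r,
    }


def bootstrap_calibration(
    seed: int,
    snr: float = 30.0,
    n_b: int = 500,
    n_mc: int = 500,
    preset: str = "sparcgold",
    n_max: int = 4,
) -> dict:
    """Wild-bootstrap STD of RTOP vs the Monte-Carlo sampling STD.

    One synthetic single-fiber voxel with Gaussian noise: the
    Monte-Carlo truth is the empirical STD of RTOP over ``n_mc``
    independent noise realizations, each run through the full
    estimator; the bootstrap STD comes from ``n_b`` wild-bootstrap
    replicates of one realization (full re-estimation per replicate).
    """
    scheme = sd.preset_scheme(preset, seed=1)
    clean = sd.tensor_signal(sd.fiber_tensor(), scheme, 100.0)
    rng = np.random.default_rng([seed, 2_000_001])
    mc_vals = []
    for i in range(n_mc):
        s = sd.add_noise(clean, snr, S0_reference=100.0, seed=rng.integers(2**31))
        try:
            mc_vals.append(rtop(fit_voxel(s, scheme, n_max)))
        except (FitError, ValueError):
            continue
    mc_std = float(np.std(mc_vals, ddof=1))
    sig = sd.add_noise(clean, snr, S0_reference=100.0, seed=rng.integers(2**31))
    _, res = bootstrap_signal(
        sig, scheme, n_max, {"rtop": rtop}, n_b=n_b, seed=seed, refit_frame=True
    )
    boot_std = res["rtop"].std
    return {
        "bootstrap_std": boot_std,
        "mc_std": mc_std,
        "ratio": boot_std / mc_std,
        "n_mc_used": len(mc_vals),
    }


def _phantom_voxels(scheme, n_voxels: int, snr: float, seed: int):
    """Noisy single- and two-fiber voxel signals (half and half)."""
    rng = np.random.default_rng([seed, 77])
    signals = []
    for v in range(n_voxels):
        count = 1 if v % 2 == 0 else 2
        comps, fracs = sd.voxel_compartments(count)
        clean = sum(f * sd.tensor_signal(D, scheme, 100.0) for D, f in zip(comps, fracs))
        signals.append(
            sd.add_noise(clean, snr, S0_reference=100.0, seed=rng.integers(2**31))
        )
    return signals


def snr_monotonicity(
    seed: int,
    snrs=(10.0, 5.0, 2.0),
    n_voxels: int = 20,
    n_b: int = 200,
    preset: str = "sparc30",
    n_max: int = 4,
) -> dict:
    """Mean bootstrap STD of RTOP as noise added to fitted signals grows.

    Mirrors the added-noise verification: fit each voxel once, add
    Gaussian noise of decreasing SNR to the *fitted* signal, and
    bootstrap each noisy version.  Reports the mean STD per SNR level.
    """
    scheme = sd.preset_scheme(preset, seed=1)
    signals = _phantom_voxels(scheme, n_voxels, np.inf, seed)
    fitted = [fit_voxel(s, scheme, n_max) for s in signals]
    out = {}
    rng = np.random.default_rng([seed, 88])
    for snr in snrs:
        stds = []
        for v, m in enumerate(fitted):
            noisy = sd.add_noise(
                100.0 * m.fitted, snr, S0_reference=100.0, seed=rng.integers(2**31)
            )
            model = fit_voxel(noisy, scheme, n_max)
            Q = design_matrix(model.frame, scheme, n_max, indices=model.indices)
            K, grid = constraint_matrix(model.frame, n_max, indices=model.indices)
            res = bootstrap_voxel(
                model, Q, K, grid, {"rtop": rtop}, n_b=n_b, seed=seed, voxel_index=v
            )
            stds.append(res["rtop"].std)
        out[snr] = float(np.nanmean(stds))
    return out


def density_monotonicity(
    seed: int,
    fractions=(1.0, 0.5, 0.25),
    n_voxels: int = 20,
    n_b: int = 200,
    snr: float = 30.0,
    preset: str = "sparcgold",
    n_max: int = 4,
) -> dict:
    """Mean bootstrap STD of NG and PA as measurements are sub-sampled.

    Keeps 100%, 50% and 25% of the measurements per shell of the
    gold-standard scheme and bootstraps the same noisy voxels under
    each reduced scheme.  Reports {fraction: {"ng": ..., "pa": ...}}.
    """
    scheme = sd.preset_scheme(preset, seed=1)
    signals = _phantom_voxels(scheme, n_voxels, snr, seed)
    out = {}
    for frac in fractions:
        sub, idx = sd.subsample_scheme(scheme, frac, seed=seed)
        fns = _metric_fns(sub)
        ng_stds, pa_stds = [], []
        for v, s in enumerate(signals):
            model = fit_voxel(s[idx], sub, n_max)
            Q = design_matrix(model.frame, sub, n_max, indices=model.indices)
            K, grid = constraint_matrix(model.frame, n_max, indices=model.indices)
            res = bootstrap_voxel(
                model, Q, K, grid, fns, n_b=n_b, seed=seed, voxel_index=v
            )
            ng_stds.append(res["ng"].std)
            pa_stds.append(res["pa"].std)
        out[frac] = {"ng": float(np.nanmean(ng_stds)), "pa": float(np.nanmean(pa_stds))}
    return out


def nb_stability(
    seed: int,
    n_voxels: int = 10,
    snr: float = 30.0,
    preset: str = "sparc30",
    n_max: int = 4,
) -> dict:
    """Median relative gap between N_B = 500 and N_B = 1000 STDs of RTOP.

    The N_B = 500 estimate uses the first 500 of the same replicate
    stream, so the comparison isolates the effect of the sample size.
    """
    scheme = sd.preset_scheme(preset, seed=1)
    signals = _phantom_voxels(scheme, n_voxels, snr, seed)
    gaps = []
    for v, s in enumerate(signals):
        model = fit_voxel(s, scheme, n_max)
        Q = design_matrix(model.frame, scheme, n_max, indices=model.indices)
        K, grid = constraint_matrix(model.frame, n_max, indices=model.indices)
        res = bootstrap_voxel(
            model, Q, K, grid, {"rtop": rtop}, n_b=1000, seed=seed, voxel_index=v
        )
        reps = res["rtop"].replicates
        std_1000 = np.std(reps, ddof=1)
        std_500 = np.std(reps[:500], ddof=1)
        gaps.append(abs(std_500 - std_1000) / std_1000)
    return {"median_gap": float(np.median(gaps))}


def white_type1_rate(seed: int, n_sim: int = 2000, t: int = 200) -> float:
    """Rejection rate of the White test under a homoscedastic null."""
    from mapboot.stats import white_test

    rng = np.random.default_rng([seed, 99])
    fitted = np.exp(-np.linspace(0.0, 3.0, t))
    rejections = 0
    for _ in range(n_sim):
        resid = rng.normal(0.0, 1.0, t)
        rejections += white_test(resid, fitted).reject_at_005
    return rejections / n_sim
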