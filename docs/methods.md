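# Methods

This note documents the model, the estimator pipeline, the numerical
choices, and what the synthetic experiments do and do not establish.

## Signal model and basis

The attenuation E(q) = S(q)/S0 is expanded in separable Hermite
functions in the eigenframe of an initial diffusion tensor.  The 1-D
factors are

    φ_n(u, q) = i^(−n) (2ⁿ n!)^(−1/2) e^(−2π²q²u²) H_n(2πuq)      (q-space)
    ψ_n(u, x) = (2^(n+1) π n!)^(−1/2) u^(−1) e^(−x²/2u²) H_n(x/u)  (r-space)

with H_n the physicists' Hermite polynomials, evaluated through
`scipy.special.eval_hermite`; normalization constants go through
log-gamma so orders ≥ 8 do not overflow.  Only even total orders
N = n1+n2+n3 appear (the propagator is antipodally symmetric), so the
3-D prefactor i^(−N) is realized as (−1)^(N/2) and the design matrix is
real.  Indices are enumerated N ascending, then lexicographically; the
coefficient count for maximum order N_max is
(1/6)(N_max/2+1)(N_max/2+2)(2N_max+3): 22 at order 4, 50 at order 6.
The q-magnitude follows b = 4π²|q|²t_d with the Stejskal–Tanner
effective diffusion time t_d = Δ − δ/3 (the timing files give δ and Δ;
t_d can be overridden).

Default order: 4 for schemes with up to three shells, 6 otherwise —
low shell counts do not support the order-6 radial detail.

## Initial tensor and frame

The tensor is fitted on the low-b subset (default b < 2000 s/mm²) by
two-pass weighted least squares on the log signal: an ordinary LS pass
supplies predicted signals ŷ, whose squares are the WLS weights (the
delta-method variance of ln y under additive noise is σ²/y²).
Eigenvalues are clamped at 1e-5 mm²/s so the scale lengths
u_i = √(2λ_i t_d) stay positive in CSF-like or noise-dominated voxels.
Eigenvector signs follow a largest-component-positive convention and
det(R) = +1, making the frame deterministic.

**Single-shell degeneracy guard.**  Restricted to a single shell, the
log-linear tensor design is exactly rank-deficient: because
g_x²+g_y²+g_z² = 1 on the shell, the intercept column is a linear
combination of the tensor columns, and S0 is then identified solely by
the b = 0 measurement(s).  With one b0 volume that measurement has
leverage exactly 1 — every fit interpolates it, and its noise becomes
both a dominant and an invisible error source (a residual that is
identically zero cannot be resampled).  When the b < b_max subset
contains fewer than two nonzero shells, the subset is therefore
extended to the next shell (logged).  This keeps S0 and the
eigenvalues jointly identified from many measurements, which both
reduces the sampling variance of the metrics and puts the remaining
variance where residual-based resampling can see it.

**Normalization.**  The signal is divided by the WLS S0 estimate (not
the raw b0 mean) before the constrained solve.  For schemes with a
single b0 volume the raw mean is one noisy sample; the pooled estimate
is less variable and its error is spread over measurements with
resampleable residuals.

## Constrained fit

Coefficients solve

    min_a ‖y − Qa‖²   s.t.   Ka ≥ 0,   wᵀKa ≤ 1/2,

where K evaluates the propagator basis on a 21×21×11 Cartesian grid
covering the positive-z half space (4851 points) and w are per-point
quadrature volumes.  Two grid choices matter and are easy to get
wrong:

* **Extent per axis.**  The grid spans ±6·u_i along each eigenframe
  axis (and [0, 6·u_z] in z), covering > 99.999% of the Gaussian
  propagator mass.  Scaling all axes by max(u) instead would leave the
  narrow axes undersampled for anisotropic voxels: the quadrature of
  the matched Gaussian then overshoots the true half-integral by
  ~1e-4, the exact Gaussian becomes infeasible, and the fit acquires a
  spurious non-Gaussianity of the same order.  With per-axis extents
  the spacing is 0.6·u_i everywhere and the quadrature error is ~1e-9.

* **Half-weighted boundary plane.**  Grid points at z = 0 represent
  cells extending only into z > 0 and carry half a cell volume in w.
  A uniform-volume sum double-counts the symmetry plane (the discrete
  half-integral of a unit Gaussian comes out ≈ 0.62 instead of 0.50)
  and again rejects exact Gaussians.  A literal unweighted
  `1ᵀKa ≤ 0.5` mode is available (`literal_integral=True`) for
  comparison.

The QP is solved exactly by the Lawson–Hanson reduction chain: least
squares with linear inequalities (LSI) → least distance programming
(LDP) → non-negative least squares, with `scipy.optimize.nnls` as the
active-set core.  Constraint rows are normalized to unit norm first —
propagator densities span several orders of magnitude (mm⁻³ scale),
and without normalization the KKT arithmetic loses ~6 digits.  The
method is deterministic, warm-start-free, and solves a 406-measurement
order-4 voxel with all 4852 constraints in ~10 ms.  If the
unconstrained least-squares solution is already feasible it is
returned directly.  Voxels whose solve fails are flagged (NaN metrics)
without affecting neighbours.

## Scalar indices

RTOP, NG and PA are computed from the coefficient vector as summarized
in the README.  The isotropic part o is obtained by least-squares
projection of the fitted signal onto the design built with the same
rotation but equal scales u₀ = (u_x u_y u_z)^(1/3).  Keeping the
rotation makes the construction exactly covariant under joint rotation
of gradients and tissue; with equal scales the basis span is itself
rotation-invariant, so nothing else changes.  Note that for voxels
with a degenerate tensor (two equal eigenvalues) the eigenframe is
only defined up to a rotation in the degenerate plane; all reported
metrics are invariant under that rotation, but raw coefficient vectors
are not comparable across such frames.  NG and PA carry the outer
square root (they are sines of angles between coefficient vectors,
bounded in [0,1]); a `sqrt_form=False` flag reproduces the un-rooted
variant.  RTPP and RTAP are provided as extras via the exact marginal
reductions of the Hermite basis (∫ψ_n dx = B_n for even n, and
ψ_n(u,0) = (−1)^(n/2)(2πu²)^(−1/2)B_n).

## Wild bootstrap

Replicates are formed as y*ᵢ = (Qâ)ᵢ + √(T/(T−N_coef)) uᵢ ε̂ᵢ with
Rademacher uᵢ; the global degrees-of-freedom inflation is used rather
than per-observation leverage weights.  Two resampling modes exist:

* `bootstrap_signal(..., refit_frame=True)` (default): each replicate
  is mapped back to raw signal units and the full estimator — S0,
  tensor frame, design, constrained solve — is re-run.  This is the
  mode whose standard deviation tracks the sampling variability of
  the estimator as actually applied: on a synthetic single-fiber
  gold-standard voxel at SNR 30, its RTOP standard deviation lies
  within ~10% of the Monte-Carlo truth from 500 independent fully
  re-fitted noise realizations (the acceptance suite re-measures
  this).
* `refit_frame=False` / `bootstrap_voxel`: the frame, Q and K are held
  fixed and only the coefficients are re-solved.  This is ~3× faster
  and appropriate for producing STD maps over volumes, but it measures
  coefficient variability *conditional* on the frame and understates
  the total (by ~20% in the calibration setup).

Replicate seeds derive from (master seed, voxel index, replicate
index) via `numpy.random.SeedSequence` spawn keys, so serial and
parallel execution and any replicate ordering give identical results.
Failed replicate fits are excluded and counted; a voxel with more than
10% failures is flagged.  Default N_B = 500: the N_B-stability
experiment shows the median gap between N_B = 500 and N_B = 1000
standard deviations is well under 10%.

## Synthetic phantom

The generator emulates a crossing-fiber phantom: single-fiber voxels
are one axially symmetric tensor with eigenvalues (1.7, 0.3, 0.3)×10⁻³
mm²/s (typical coherent white matter), two-fiber voxels are 50/50
mixtures of two such tensors crossing at 45°, and background voxels
are isotropic with 2.0×10⁻³ mm²/s (free water).  S0 = 100.  Scheme
presets mirror the multi-shell designs the uncertainty experiments
need: three shells at b = 1000/2000/3000 s/mm² with 20, 30 or 60
directions per shell plus one b0 (δ = Δ = 62 ms), a five-shell
gold-standard at b = 1000–5000 with 81 directions per shell plus one
b0, and the four-shell human-connectome listing (40 b0 + 64 + 64 +
128 + 256 = 552 volumes, δ = 12.9 ms, Δ = 21.8 ms).  Directions come
from seeded electrostatic repulsion with antipodal symmetry.  Noise is
Gaussian (or Rician) with SNR defined as mean b0 signal over the noise
standard deviation, added independently per measurement and voxel.

What the phantom does *not* emulate: restricted (truly non-Gaussian)
intra-fiber diffusion — compartments are Gaussian, so single-fiber NG
is near zero by construction and absolute NG values are not comparable
to physical-phantom or in-vivo tissue; spatial noise correlation;
motion or eddy-current artifacts.  Passing tests therefore establish
the estimator's internal correctness and calibration under the stated
noise model, not the physiological realism of the metric values.

## Experiment sizes

The validation experiments are sized for a single CPU: bootstrap
calibration uses one voxel with N_B = 500 against 500 Monte-Carlo
realizations; the SNR and sampling-density trends use 20 voxels at
N_B = 200 (three-shell scheme for the SNR sweep, sub-sampled
gold-standard for the density sweep); the White-test null uses 2000
simulations at T = 200.  At these sizes the compared summaries are
stable to well within the margins they are tested against.

## Known limitations

* The bootstrap distribution near active positivity constraints can be
  inconsistent (boundary-of-parameter-space effect); the calibration
  experiment operates at moderate SNR where the constraint is not
  pinning the solution.  At very low SNR the STD maps remain useful as
  relative, not absolute, uncertainty.
* The White test's reduced auxiliary regression (ε² on ŷ, ŷ²) has 2
  degrees of freedom; the full cross-product form is available when T
  affords it, but for order-6 designs it would need more regressors
  than measurements.
* Group maps assume co-registered inputs; no registration is provided.
* Subjects with exactly zero STD at a voxel are capped at that
  subject's 1st percentile of nonzero STDs to avoid infinite weight.
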