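# mapboot

Mean-apparent-propagator (MAP) MRI fitting with a positivity-constrained
quadratic program, the scalar indices **RTOP**, **NG** and **PA**, and
**wild-bootstrap** uncertainty maps — plus a synthetic multi-shell
crossing-fiber phantom so the whole pipeline can be exercised and
validated without any scanner data.

## Who this is for

Diffusion-MRI researchers who compute MAP-MRI metrics and want a
per-voxel *uncertainty* next to each metric: a standard deviation that
can flag unreliable voxels, compare acquisition schemes or
preprocessing pipelines, and weight subjects in group analyses.

## The model

The q-space signal attenuation of a voxel is expanded in Hermite
functions anchored to the eigenframe of an initial diffusion tensor D:

    E(q) = Σ_{n1+n2+n3 ≤ N_max}  a_{n1n2n3} Φ_{n1n2n3}(A, q),
    A    = 2 RᵀD R t_d = diag(u_x², u_y², u_z²),

where R holds the tensor eigenvectors, u_i = √(2 λ_i t_d) are
displacement scale lengths over the diffusion time t_d, and the total
order N is even.  The propagator P(r) uses the same coefficients on the
conjugate basis Ψ, so non-negativity of P becomes a linear constraint
on a.  The coefficients solve the quadratic program

    min_a ‖y − Q a‖²   s.t.   K a ≥ 0,   wᵀK a ≤ 1/2,

with K the Ψ basis evaluated on a 21×21×11 half-space grid (4851
points) and w the grid quadrature volumes.  From â:

* **RTOP** = (8π³|A|)^(−1/2) Σ (−1)^(N/2) a_n B_n  — return-to-origin
  probability (mm⁻³); its reciprocal is the mean pore volume.
* **NG** = √(1 − a₀₀₀²/‖a‖²) — non-Gaussianity, the sine of the angle
  between the coefficient vector and its Gaussian part.
* **PA** = √(1 − ⟨a,o⟩²/(‖a‖²‖o‖²)) — propagator anisotropy, with o the
  coefficients of the propagator's isotropic part.

Uncertainty comes from the **wild bootstrap**: replicate signals
y*ᵢ = (Qâ)ᵢ + √(T/(T−N_coef)) uᵢ ε̂ᵢ with Rademacher signs uᵢ = ±1,
re-fitted N_B times; the reported uncertainty is the sample standard
deviation of each metric over the replicates.  Sign-flipping preserves
each residual's own magnitude, which is what makes the scheme valid for
the heteroscedastic noise of multi-shell data (variance differs between
shells).  A White test screens voxels for heteroscedasticity, and group
maps combine subjects with inverse-variance weights w_n = 1/σ_n².

## Worked example

```python
import numpy as np
from mapboot import synthetic_data as sd
from mapboot import fit_voxel, metric_set
from mapboot.wild_bootstrap import bootstrap_signal
from mapboot.metrics import rtop

scheme = sd.preset_scheme("sparcgold", seed=1)      # 5 shells x 81 dirs + 1 b0
clean  = sd.tensor_signal(sd.fiber_tensor(), scheme, S0=100.0)
noisy  = sd.add_noise(clean, snr=30.0, S0_reference=100.0, seed=7)

model = fit_voxel(noisy, scheme, n_max=4)
print(metric_set(model, scheme))

_, boot = bootstrap_signal(noisy, scheme, 4, {"rtop": rtop}, n_b=500, seed=7)
print("RTOP std:", boot["rtop"].std)
```

Output:

```
MetricSet(rtop=223766.4992742891, mean_volume=4.468944204083996e-06,
          ng=0.03620473045142434, pa=0.46167298651168404)
RTOP std: 5071.777905545327
```

The voxel is a single coherent fiber population: RTOP ≈ 2.24×10⁵ mm⁻³
(mean pore volume ≈ 4.5×10⁻⁶ mm³), NG near zero (the underlying signal
is a single Gaussian tensor, so almost all weight sits on the (0,0,0)
coefficient; the residual 0.036 is noise), and PA ≈ 0.46 (strongly
anisotropic propagator).  The bootstrap standard deviation of RTOP,
≈ 5.1×10³ mm⁻³, is ~2% of the estimate — the uncertainty attributable
to this noise level and scheme.

A CLI wraps the same stages:

```bash
mapboot simulate --preset sparcgold --snr 30 --seed 1 --out-dir phantom/
mapboot fit       --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
                  --bvec phantom/dwi.bvec --nmax 4 --out-dir maps/
mapboot bootstrap --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
                  --bvec phantom/dwi.bvec --nb 500 --seed 1 --out-dir maps/
mapboot group     --metric rtop --subjects s1/ s2/ s3/ --out-dir group/
```

## Documentation

`docs/methods.md` describes the model, the solver, the numerical
choices and the known limitations in detail.
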