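# t1rhomap

Direct ("embedded") reconstruction of quantitative T1ρ relaxation maps
from undersampled multi-contrast MRI k-space, with compressed-sensing
and zero-filled iFFT reference pipelines and a fully synthetic
golden-angle radial / cartesian phantom study.

## The problem

Quantitative T1ρ mapping repeats an acquisition at several spin-lock
times TSL_c; the pixel-wise signal follows

    S_c = S0 · exp(−TSL_c / T1ρ),

so 5–7 full acquisitions are needed per map — long enough that
undersampled acquisitions plus iterative reconstruction are the
practical route to clinically usable scan times.  The conventional
two-step route reconstructs one complex image per spin-lock time
(compressed sensing with total-variation regularization) and then fits
the exponential pixel by pixel.  The embedded route implemented here
estimates the three real maps x = (S0, T1ρ, θ) directly from all the
k-space data through the non-linear forward model K = A∘B∘D
(A: undersampled FFT or radial NUFFT, B: phase embedding, D: the decay),
solving

    min_x ‖K(x) − m‖² + α₁TV(S0) + α₂TV(T1ρ) + α₃‖∇θ‖²
          s.t. S0 ≥ a₁, T1ρ ≥ a₂

with a non-linear primal–dual proximal splitting (per-block primal steps
derived from the diagonal Jacobian structure of B∘D; details in
`docs/methods.md`).  This reduces the unknown count from 2NC (complex
image series) to 3N — 79% fewer at C = 7 contrasts, 70% at C = 5 — and
regularizes the map of interest directly.

The package is written for MRI reconstruction researchers: every piece
(phantom, sampling schedules, NUFFT, operators, solvers, fit, sweeps) is
a library function with an estimator-style interface, and a small CLI
drives end-to-end experiments.

## Worked example

Simulate an AF = 10 golden-angle radial acquisition of the 48×48
phantom (3 spin-lock times, 5% complex noise), reconstruct it with the
embedded model, and compare with a compressed-sensing reconstruction
followed by the mono-exponential fit:

```python
import numpy as np
from t1rhomap import (PhantomSpec, simulate_radial_phantom_kspace,
                      EmbeddedRecon, CSRecon, MonoExpFit, rmse)

spec = PhantomSpec(matrix_size=48, base_size=32)
truth, data, enc = simulate_radial_phantom_kspace(
    spec=spec, tsl=[0., 16., 64.], af=10, noise_fraction=0.05, seed=0)

emb = EmbeddedRecon(alpha1=1e-4, alpha2=1e-6, alpha3=1e-5,
                    phase_init="composite", max_iters=3000,
                    rel_tol=1e-8).fit(data, encoding=enc)

cs = CSRecon(model="s1c2", alpha=1e-3, max_iters=1500).fit(data,
                                                           encoding=enc)
fit = MonoExpFit().fit(cs.images_)

support = truth.s0 > 1e-3
for name, t1rho in (("embedded", emb.t1rho_map_),
                    ("CS s1c2 + fit", fit.t1rho_map_)):
    print(f"{name}: T1rho RMSE {rmse(t1rho, truth.t1rho, support):.2f} ms")
```

```
embedded: T1rho RMSE 6.25 ms
CS s1c2 + fit: T1rho RMSE 5.46 ms
```

The RMSE is taken over the phantom support against the known ground
truth (20–120 ms); `emb.history_` carries the convergence log (objective,
per-block step sizes, the step-size criterion estimate).  This snippet
deliberately runs small and fast — three spin-lock times and capped
iterations; the packaged comparison preset uses the full 7-spin-lock
protocol and longer embedded runs, where the direct reconstruction pulls
ahead of this CS model at undersampled acquisitions (see
`docs/methods.md` on how contrast count and intensity scale shift the
balance between the models).

The same experiment from the shell:

```bash
t1rhomap simulate --scheme radial --af 10 --matrix-size 48 \
    --base-size 32 --tsl 0,16,64 --noise 0.05 --seed 0 --out acq.h5
t1rhomap recon-embedded --data acq.h5 --alpha1 1e-4 --alpha2 1e-5 \
    --alpha3 1e-5 --max-iters 3000 --out maps.nii.gz --log conv.csv
t1rhomap report --contrasts 7 --matrix-size 192
```

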