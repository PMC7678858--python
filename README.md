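# lfholo — lens-free holographic reconstruction of cells in suspension

Lens-free (in-line holographic) microscopy records only the intensity of the
diffraction pattern of a sample; the image must be recovered computationally.
For cells in suspension the optical thickness routinely exceeds half the
illumination wavelength, so any variational reconstruction recovers the
optical path difference (OPD) only modulo λ — cells appear with phase-wrap
artefacts.  `lfholo` implements a three-step *alternation* pipeline that
resolves this:

1. **First reconstruction** — fast regularized inversion (20 conjugate-
   gradient iterations from a null object, coherence kernel set to a Dirac)
   that produces a *wrapped* estimate of the OPD map `L` and absorption map
   `A`;
2. **CNN unwrapping** — a fully-convolutional network, trained purely on
   synthetic sphere-cell phantoms and their first reconstructions, maps the
   wrapped `(L, A)` pair to an unwrapped prediction;
3. **Final reconstruction** — a longer inversion (70 iterations, full
   partial-coherence kernel `K`) initialized at the network prediction,
   which pulls the result back onto the measurements and corrects the
   deviations the network introduced.

## Model

The sample is a thin transmission plane `E(L, A) = exp(2iπL/λ + A)`.  The
hologram intensity at sample–sensor distance `Z` is

    I(L, A) = B · |E(L, A) * h_Z|² * K,     h_Z(r) = 1/(iλZ) · exp(iπr²/(λZ)),

with `B` the illumination background (grey levels) and `K` a normalized
kernel modelling the finite size and spectral width of the source.
Reconstruction minimizes the χ²-like criterion

    ε(L, A) = Σ |I(L, A) − I_meas|² / I_meas + α ζ(L, A)

by nonlinear conjugate gradients with exact analytic gradients.  The first
stage uses total variation on the complex field `E` (blind to λ-jumps of
`L`, hence wrap-tolerant); the final stage uses total variation on `L`
itself plus positivity of `L`, smoothness of `A` and `A ≤ 0` — which is
exactly what makes it keep the unwrapped branch the network found.

Synthetic scenes are homogeneous spheres with uniform random radius
(5–20 µm) and complex refractive-index contrast (Δn_r ∈ [0.01, 0.05],
Δn_i ∈ [0, 0.005]); a sphere of chord thickness `T` contributes
`L = T·Δn_r` and `A = −2πT·Δn_i/λ`, and holograms carry Poisson noise.
Per-cell recovery inverts this: `Δn_r = (1/V)∫_S L`,
`Δn_i = −λ/(2πV)∫_S A` over the cell's known disc `S`, `V = (4/3)πr³`.

## Worked example

```python
import numpy as np
from lfholo import (OpticsConfig, gaussian_kernel, sample_scene, render_maps,
                    simulate_hologram, run_alternation, PipelineConfig,
                    train_benchmark_unwrapper, benchmark_sim_params)

optics = OpticsConfig()                      # 450 nm, Z = 1270 µm, 1.67 µm pitch
unwrapper = train_benchmark_unwrapper(seed=1)    # ~6 min on one CPU

rng = np.random.default_rng(1)
scene = sample_scene(benchmark_sim_params(grid=256), rng)
truth = render_maps(scene, optics.wavelength)
K = gaussian_kernel((256, 256))
holo = simulate_hologram(truth, optics, K, rng)

result = run_alternation(holo, PipelineConfig(optics=optics,
                                              unwrapper=unwrapper, K=K))
print(f"true max OPD    {truth.L.max():.3f} µm")
print(f"stage-1 max OPD {result.first.maps.L.max():.3f} µm (wrapped)")
print(f"network max OPD {result.predicted.L.max():.3f} µm")
print(f"final max OPD   {result.final.maps.L.max():.3f} µm")
print(f"final/prediction fidelity {result.final.history[-1][0] / result.fidelity_at_prediction:.4f}")
```

Output of this exact run:

```
true max OPD    0.528 µm
stage-1 max OPD 0.171 µm (wrapped)
network max OPD 0.384 µm
final max OPD   0.532 µm
final/prediction fidelity 0.0166
```

The tallest phantom cell has an OPD of 0.53 µm ≈ 1.2λ (a phase shift of
2.3π): the first reconstruction wraps it down to 0.17 µm (< λ/2 =
0.225 µm), the network restores the super-λ/2 peak, and the final stage —
initialized at the prediction — lands within 1% of the true peak while
reducing the data-fidelity term sixty-fold relative to the raw prediction.

A command-line interface mirrors the library: `lfm simulate`,
`lfm reconstruct`, `lfm train`, `lfm predict`, `lfm run`, `lfm evaluate`
(all take `--seed`; see `lfm --help`).

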