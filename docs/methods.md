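# Methods

## Physical model

The object is a single 2D transmission plane characterized by two real
maps: the optical path difference `L` (µm, ≥ 0 for physical phantoms) and
the negative absorption coefficient `A` (dimensionless, ≤ 0).  The field
after the sample under unit plane-wave illumination is
`E = exp(2iπL/λ + A)`; the sensor-plane intensity is
`I = B·|E * h_Z|² * K` with `h_Z` the paraxial (Fresnel) free-space kernel
over the sample–sensor distance `Z`, `B` the background in grey levels and
`K` a normalized blur kernel for source partial coherence.  Because `E`
depends on `L` only through `exp(2iπL/λ)`, the measurement is *exactly*
invariant under per-pixel shifts `L → L + Nλ`: this is the wrapping
ambiguity the pipeline exists to resolve.  No multiple scattering,
vectorial diffraction or 3D (multi-plane) object model is attempted.

Reference configuration (all configurable): λ = 450 nm with 30 nm full
spectral width, source diameter 50 µm at 50 mm from the sample,
Z = 1270 µm, pixel pitch 1.67 µm, B = 105 grey levels.  Note on units: the
experimental setups behind these numbers quote λ = 457 nm (and 405 nm for
one phase-profile figure) and B is plausibly a much larger full-well count;
both are plain config values here, with the simulation defaults above.

### Propagation

Propagation is computed spectrally with the unit-modulus transfer function
`H(f) = exp(−iπλZ|f|²)` (the constant plane-wave phase is dropped; it
cancels in any intensity).  The default is the plain periodic FFT form:
it is exactly unitary, a uniform field is an exact fixed point, and
`propagate(−Z)` is simultaneously the exact inverse and the exact adjoint —
the last point is load-bearing, because the solver's analytic gradient
back-propagates residuals with `−Z`.  Zero-padding before the transform is
available (`pad_factor`) for aperiodic fields, but it is *not* the default:
cropping after padding discards edge-diffracted energy, which breaks
unitarity (and hence exact adjointness) at far above round-off level.
A sampling guard warns (or raises, per call) when `λ|Z|/(N·pitch²) > 1`,
i.e. when the chirp is undersampled on the grid in use; the 128² test grids
deliberately operate past this point since the properties tested (energy,
invertibility, wrap invariance) hold regardless.

### Partial-coherence kernel

`K` is derived from two point-object simulations: the hologram of a single
opaque pixel under (a) coherent monochromatic illumination and (b) the
configured extended polychromatic source — the source disc discretized
into ≤ 9 points (axial point + ring of 8 at the area-weighted mean radius
`D/2·√½`) whose geometric projection shifts the pattern by
`Z / source_sample_distance` times the source offset, and the spectrum into
`n_spectral_samples` (default 5) equally weighted wavelengths across the
full width.  `K` is the Wiener-regularized Fourier deconvolution of the two
*mean-removed* fringe patterns (floor `1e−3·max|spectrum|`), with the DC
gain pinned to 1 (a unit-mass kernel preserves the mean), negatives clipped,
then normalized.  Mean removal matters: without it the DC term dominates
the Wiener floor and the deconvolution collapses to a uniform kernel.
When the configured source is exactly coherent the deconvolution is
short-circuited to an exact discrete Dirac (the two simulations are
identical by construction).  At the reference configuration the derived
kernel's FWHM is ≈2–5 µm depending on grid — the same order as the 1.75 µm
Gaussian that is also provided (`gaussian_kernel`) as the conventional
summary dialect and used as `K` in the simulation pipelines.  Limitation:
for source diameters far beyond the realistic range (≳200 µm projected to
several pixels) the 9-point disc discretization degenerates into a ring.

## Inverse problem

Criterion: `ε(L,A) = Σ (I(L,A) − I_meas)²/max(I_meas, 1) + α·ζ(L,A)`.
The 1-grey-level floor guards against zero/negative measured pixels.  The
integral-vs-pixel-sum normalization question is absorbed into α.

Stage-1 regularizer (wrap-tolerant):
`ζ₁ = Σ √(|∂ₓE|² + |∂ᵧE|² + ε²) + √(L² + ε²) + 10·A²·1(A>0)`.
Stage-2 regularizer (wrap-hostile, run after unwrapping):
`ζ₂ = Σ √((∂ₓL)² + (∂ᵧL)² + ε²) + ⅕√(L² + ε²) + ⅕(ΔA)² + 10·A²·1(A>0) + L²·1(L<0)`.
The ⅕, 10 and 1 weights are part of the regularizer definitions; the global
α is not printed anywhere, so it was calibrated once so that `α·ζ` is about
10% of the data term early in stage 1 on a reference-density phantom
(measured ratio at α = 1: ≈1%, hence α = 10) and then frozen; the same
default serves stage 2 (recovery quality was checked to be insensitive
between α₂ = 10 and the value ≈65 the same rule would give at the stage-2
starting point).

Numerical choices: TV magnitudes and `√(L²)` are smoothed as `√(x² + ε²)`
with ε = 1e−3 (µm for L-terms, dimensionless for E-terms); the one-sided
penalties are exact C¹ piecewise quadratics and contribute zero gradient on
their inactive side.  Spatial derivatives are forward differences with
replicate (Neumann) boundaries; the Laplacian is the self-adjoint 5-point
stencil `−DᵀD` built from them, so every regularizer term has an exact
adjoint.  Gradients of the data term follow the adjoint chain
(residual → kernel correlation → `2·(·)·U` → back-propagation by `−Z` →
`exp` chain rule) and match central finite differences to ≲1e−7 relative in
the tests.

Minimization: Polak–Ribière+ nonlinear conjugate gradients over the
concatenated `(L, A)` vector, restart every 50 iterations or on a
non-descent direction, Armijo backtracking (factor 0.5, c₁ = 1e−4, ≤ 20
trials, warm-started step), steepest-descent fallback when the conjugate
direction fails to yield sufficient decrease.  Every iteration logs
(fidelity, regularization, total) with `total = fidelity + α·reg` exact by
construction; accepted steps make the history non-increasing.  The solver
is deterministic given its inputs.

First reconstruction: null init, Dirac `K`, ζ₁, 20 iterations.
Final reconstruction: init at the network prediction, full `K`, ζ₂, 70
iterations.  `B` for experimental data defaults to the median of the
measured hologram (configurable); no autofocus/Z-search is provided.

## Synthetic data

Scenes are homogeneous spheres: count uniform on an integer range (default
500–5000 per 1000×1000 px, i.e. 179–1792 cells/mm²), radii uniform on
5–20 µm, Δn_r on 0.01–0.05, Δn_i on 0–0.005, centers uniform over the
field (cells may straddle the border; only the in-field part is rendered).
Overlapping spheres simply add their chord thickness (projection
approximation, consistent with the 2D forward model).  Per-image jitter:
Z ± 5%, B ± 30%, one value each per image.  Holograms are Poisson draws
with the forward-model mean, grey levels read as counts; no read noise,
motion blur or non-spherical cells are modelled.  Surface density truncates
(floors) the cells-per-mm² ratio, reproducing the printed triplet
500 → 179, 1001 → 358, 5000 → 1792 (the printed 909 and 1627 for 2547 and
4569 cells are not reproducible by this arithmetic, which gives 913 and
1638; the arithmetic is followed).

What passing tests on this generator do *not* show: performance on real
acquisitions (aberrations, sensor nonlinearity, non-spherical and textured
cells, coherent speckle from debris) is outside what the phantom family
exercises; reconstruction here is an inverse-crime setting in which the
simulator and the solver share the forward model (only `K` differs between
simulation and the first stage, which uses a Dirac).

## Unwrapping network

Architecture: `n_blocks` repetitions of [5×5 conv (`n_features`) → batch
norm → ReLU] closed by a 5×5 conv with 2 outputs, zero same-padding, no
dimension changes — any input size works and output size equals input size.
Reference spec: 20 blocks × 32 features; reduced spec: 6 × 16 (receptive
field 29 px).  Inputs and targets are normalized per channel (L by λ, A by
1; constants stored with the model) — needed for stable batch-norm
training; loss is MSE equally weighted over both channels; optimizer Adam
(reference: lr 1e−4, 10 epochs × 12 800 random 121×121 vignettes, batch 32
— roughly a 10-hour GPU-scale job).  Batch-norm inference uses running
statistics frozen at training end.  One network is trained per distance Z;
the pipeline refuses holograms whose Z differs from the model's training Z
by more than 5% (the Z-jitter band).  Training, inference and
initialization are seeded; the whole pipeline is reproducible bit-for-bit.

The convolution/batch-norm/ReLU engine, its reverse-mode gradients and the
Adam optimizer live in `lfholo.nn` (numpy, NCHW, windows-view GEMM
convolutions) and are finite-difference-verified in the test suite.

## Scaled-down benchmark

The full protocol is far outside a CPU-minutes budget, so the package fixes
a smaller instance of the same physics (`lfholo.benchmark`): 128×128 scenes
with 2–5 cells, radii 5–8 µm, Δn_r 0.02–0.05 (max OPD 0.2–0.8 µm, up to
≈1.8λ — one to two wraps), Δn_i 0–0.002; 60 training scenes; the reduced
network trained 30 epochs × 320 vignettes of 32×32 at lr 1e−3, batch 16
(≈6 min on one CPU).  Because cells cover only ≈5% of a sparse scene, 70%
of training crops are centered (with jitter) on a randomly chosen cell.

Measured behavior at these conditions (recomputed by the tests and
`scripts/acceptance.py`, never asserted from this file): the first
reconstruction's per-cell Δn_r is uncorrelated with truth; the network
prediction and the final reconstruction recover it with near-unit slope on
isolated cells, the final stage slightly better than the raw prediction;
the final stage always lowers the data-fidelity term relative to the
prediction (a descent guarantee, logged per iteration).  Known failure
mode, shared with the full-scale method: for the tallest cells
(max OPD ≳ 0.7 µm) the prediction sometimes falls short of the true peak by
more than λ/2, the final stage then locks onto the wrong branch, and the
recovered Δn_r for that cell is far off (one wrong wrap shifts it by
≈3λ/(4r), the width of the whole parameter range); a single such cell can
dominate a small regression, so the acceptance script reports the
wrap-failure count and the regression over correctly unwrapped cells
alongside the all-cells regression.

## Evaluation conventions

PSNR uses `10·log10(range²/MSE)` with `range` = max of the ground-truth
map of the compared channel (headline figures use the L channel), capped
at 200 dB for identical maps.  Per-cell recovery integrates over pixels
whose centers lie inside the cell's disc (no partial-pixel weighting; the
resulting discretization error is within the 2% tolerance the tests
assert for r ≥ 5 µm at 1.67 µm pitch).  Regressions are ordinary least
squares with intercept (slope, R²), reconstructed against true values.
Unit conversions: phase in π units is `2L/λ`; surface density (cells/mm²)
over a chamber of thickness t µm converts to volumetric density as
`density/t` in 10⁶ cells/ml.

## Problem sizes

The test suite runs forward-model properties at 128², gradient checks at
32², solver behavior at 64–128², the alternation demonstration at 256²,
and trains the benchmark network once per session; `scripts/acceptance.py`
repeats the same computations from scratch at the given seed.  These sizes
are the package's scaled demonstration conditions; the full-scale protocol
is available in `scripts/full_scale.py`.
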