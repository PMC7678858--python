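"""Regularized variational reconstruction of (L, A) from a hologram.

The criterion is a χ²-like data-fidelity term weighted by the measurement,

    ε(L, A) = Σ_pixels |I(L, A) − I_meas|² / I_meas  +  α ζ(L, A),

minimized by nonlinear conjugate gradients with an exact analytic gradient
(adjoint back-propagation of the intensity residual through the coherence
kernel, the squared modulus, the Fresnel kernel and the exponential
transmission).

Two regularizers are used.  The first stage — run from a null initialization
with a Dirac coherence kernel and few iterations — applies total variation
to the complex field E itself, so it is insensitive to λ-jumps of L and
reconstructs the OPD wrapped modulo λ:

    ζ₁ = Σ √(|∂E/∂x|² + |∂E/∂y|² + ε²) + √(L² + ε²) + 10 A²·1(A>0)

The final stage — initialized at the network's unwrapped prediction, with
the full kernel K and more iterations — applies TV to L directly (which
penalizes wraps), smooths A, and enforces positive OPD:

    ζ₂ = Σ √((∂L/∂x)² + (∂L/∂y)² + ε²) + (1/5)√(L² + ε²)
           + (1/5)(ΔA)² + 10 A²·1(A>0) + L²·1(L<0)

Non-smooth magnitudes are smoothed as √(x² + ε²); one-sided penalties are
exact C¹ piecewise quadratics.  Derivatives use forward differences with
replicate boundaries; the Laplacian is the self-adjoint 5-point stencil
built from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import (CoherenceKernel, IntensityImage, OpticsConfig,
                     SampleMaps, _convolve_k, _correlate_k, _kernel_tf,
                     _propagate, _transmission)

__all__ = [
    "SolverConfig",
    "ReconResult",
    "data_fidelity",
    "reg_stage1",
    "reg_stage2",
    "criterion_and_gradient",
    "minimize",
    "first_reconstruction",
    "second_reconstruction",
    "DEFAULT_ALPHA_STAGE1",
    "DEFAULT_ALPHA_STAGE2",
]

# Global regularization weights, calibrated once on the reference phantom so
# that α·ζ is about a tenth of the data-fidelity term early in stage 1, then
# kept fixed (see docs/methods.md).
DEFAULT_ALPHA_STAGE1 = 10.0
DEFAULT_ALPHA_STAGE2 = 10.0


@dataclass
class SolverConfig:
    """Settings of one reconstruction stage."""

    n_iterations: int = 20
    alpha: float = DEFAULT_ALPHA_STAGE1
    tv_smoothing: float = 1e-3
    stage: str = "first"            # "first" (ζ₁ on E) or "second" (ζ₂ on L)
    use_kernel: bool = False
    ls_factor: float = 0.5          # backtracking contraction
    ls_c1: float = 1e-4             # Armijo sufficient-decrease constant
    ls_max_trials: int = 20
    restart_every: int = 50
    intensity_floor: float = 1.0    # grey levels, floor for the 1/I_meas weight

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.tv_smoothing <= 0:
            raise ValueError("tv_smoothing must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.stage not in ("first", "second"):
            raise ValueError("stage must be 'first' or 'second'")


@dataclass
class ReconResult:
    """Reconstruction output plus per-iteration convergence history.

    ``history`` rows are (fidelity, regularization, total) with
    total = fidelity + α·regularization at every logged iteration.
    """

    maps: SampleMaps
    history: list[tuple[float, float, float]]
    n_iterations_run: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Difference operators (forward differences, replicate boundary) and adjoints
# ---------------------------------------------------------------------------

def _dx(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    out[:, :-1] = u[:, 1:] - u[:, :-1]
    return out


def _dy(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    out[:-1, :] = u[1:, :] - u[:-1, :]
    return out


def _dxT(g: np.ndarray) -> np.ndarray:
    out = np.zeros_like(g)
    out[:, 1:] += g[:, :-1]
    out[:, :-1] -= g[:, :-1]
    return out


def _dyT(g: np.ndarray) -> np.ndarray:
    out = np.zeros_like(g)
    out[1:, :] += g[:-1, :]
    out[:-1, :] -= g[:-1, :]
    return out


def _laplacian(u: np.ndarray) -> np.ndarray:
    """Self-adjoint 5-point Laplacian with Neumann boundaries: −(DᵀD)u."""
    return -(_dxT(_dx(u)) + _dyT(_dy(u)))


# ---------------------------------------------------------------------------
# Criterion terms
# ---------------------------------------------------------------------------

def _fid_weight(I_meas: np.ndarray, floor: float) -> np.ndarray:
    return 1.0 / np.maximum(I_meas, floor)


def data_fidelity(maps: SampleMaps, I_meas: IntensityImage,
                  config: OpticsConfig, K: CoherenceKernel | None = None,
                  intensity_floor: float = 1.0) -> float:
    """Σ (I_model − I_meas)² / max(I_meas, floor)."""
    K_hat = _kernel_tf(K, maps.shape)
    from .optics import _predict_intensity
    I_model = _predict_intensity(maps.L, maps.A, config, K_hat)
    w = _fid_weight(I_meas.values, intensity_floor)
    return float(np.sum(w * (I_model - I_meas.values) ** 2))


def _reg1_value_grad(L: np.ndarray, A: np.ndarray, wavelength: float,
                     eps: float, want_grad: bool):
    E = _transmission(L, A, wavelength)
    ex, ey = _dx(E), _dy(E)
    t = np.sqrt(np.abs(ex) ** 2 + np.abs(ey) ** 2 + eps ** 2)
    sL = np.sqrt(L ** 2 + eps ** 2)
    pos = A > 0
    value = float(np.sum(t) + np.sum(sL) + 10.0 * np.sum(A[pos] ** 2))
    if not want_grad:
        return value, None, None
    # Wirtinger gradient of Σt w.r.t. conj(E), chained to the real maps via
    # dE = E·(2iπ/λ dL + dA):  dJ/dL = −(4π/λ)·Im(conj(g_E)E), dJ/dA = 2Re(·)
    gE = _dxT(ex / (2.0 * t)) + _dyT(ey / (2.0 * t))
    c = np.conj(gE) * E
    gL = -(4.0 * np.pi / wavelength) * np.imag(c) + L / sL
    gA = 2.0 * np.real(c) + np.where(pos, 20.0 * A, 0.0)
    return value, gL, gA


def _reg2_value_grad(L: np.ndarray, A: np.ndarray, eps: float, want_grad: bool):
    lx, ly = _dx(L), _dy(L)
    t = np.sqrt(lx ** 2 + ly ** 2 + eps ** 2)
    sL = np.sqrt(L ** 2 + eps ** 2)
    lapA = _laplacian(A)
    posA = A > 0
    negL = L < 0
    value = float(np.sum(t) + 0.2 * np.sum(sL) + 0.2 * np.sum(lapA ** 2)
                  + 10.0 * np.sum(A[posA] ** 2) + np.sum(L[negL] ** 2))
    if not want_grad:
        return value, None, None
    gL = (_dxT(lx / t) + _dyT(ly / t) + 0.2 * L / sL
          + np.where(negL, 2.0 * L, 0.0))
    gA = 0.4 * _laplacian(lapA) + np.where(posA, 20.0 * A, 0.0)
    return value, gL, gA


def reg_stage1(maps: SampleMaps, wavelength: float, eps: float = 1e-3) -> float:
    """Stage-1 regularizer: TV on the complex field E, sparsity on L, A ≤ 0."""
    v, _, _ = _reg1_value_grad(maps.L, maps.A, wavelength, eps, want_grad=False)
    return v


def reg_stage2(maps: SampleMaps, eps: float = 1e-3) -> float:
    """Stage-2 regularizer: TV on L, sparsity on L, smooth A, A ≤ 0, L ≥ 0."""
    v, _, _ = _reg2_value_grad(maps.L, maps.A, eps, want_grad=False)
    return v


def _criterion_parts(L, A, I_meas, w, config, K_hat, solver: SolverConfig,
                     want_grad: bool):
    """Fidelity + α·reg and the analytic gradient w.r.t. (L, A)."""
    lam = config.wavelength
    Z = config.sample_sensor_distance
    pitch = config.pixel_pitch
    B = config.background

    E = _transmission(L, A, lam)
    U = _propagate(E, Z, lam, pitch)
    s = np.abs(U) ** 2
    I_model = B * _convolve_k(s, K_hat)
    resid = I_model - I_meas
    fid = float(np.sum(w * resid ** 2))

    if solver.stage == "first":
        reg, rgL, rgA = _reg1_value_grad(L, A, lam, solver.tv_smoothing, want_grad)
    else:
        reg, rgL, rgA = _reg2_value_grad(L, A, solver.tv_smoothing, want_grad)

    total = fid + solver.alpha * reg
    if not want_grad:
        return fid, reg, total, None, None

    # adjoint chain of the fidelity term
    W = 2.0 * w * resid                       # dJ/dI_model
    W2 = B * _correlate_k(W, K_hat)           # dJ/d|U|²
    gU = W2 * U                               # Wirtinger dJ/dŪ
    gE = _propagate(gU, -Z, lam, pitch)       # exact adjoint of propagation
    c = np.conj(gE) * E
    gL = -(4.0 * np.pi / lam) * np.imag(c)
    gA = 2.0 * np.real(c)

    gL = gL + solver.alpha * rgL
    gA = gA + solver.alpha * rgA
    if not (np.all(np.isfinite(gL)) and np.all(np.isfinite(gA))):
        raise FloatingPointError("non-finite gradient in criterion evaluation")
    return fid, reg, total, gL, gA


def criterion_and_gradient(maps: SampleMaps, I_meas: IntensityImage,
                           solver: SolverConfig, config: OpticsConfig,
                           K: CoherenceKernel | None = None):
    """Total criterion and its exact analytic gradient w.r.t. L and A.

    Returns ``(total, grad_L, grad_A)``.
    """
    if maps.shape != I_meas.values.shape:
        raise ValueError("maps and measurement shapes differ")
    K_hat = _kernel_tf(K if solver.use_kernel else None, maps.shape)
    w = _fid_weight(I_meas.values, solver.intensity_floor)
    _, _, total, gL, gA = _criterion_parts(
        maps.L, maps.A, I_meas.values, w, config, K_hat, solver, want_grad=True)
    return total, gL, gA


def minimize(I_meas: IntensityImage, init: SampleMaps, solver: SolverConfig,
             config: OpticsConfig, K: CoherenceKernel | None = None) -> ReconResult:
    """Nonlinear conjugate gradient (Polak–Ribière+, restarted) with Armijo
    backtracking line search.  Deterministic given its inputs."""
    if init.shape != I_meas.values.shape:
        raise ValueError("init shape must match the measurement")
    K_hat = _kernel_tf(K if solver.use_kernel else None, init.shape)
    w = _fid_weight(I_meas.values, solver.intensity_floor)
    L = init.L.copy()
    A = init.A.copy()
    notes: list[str] = []

    fid, reg, total, gL, gA = _criterion_parts(
        L, A, I_meas.values, w, config, K_hat, solver, want_grad=True)
    g = np.concatenate([gL.ravel(), gA.ravel()])
    d = -g
    history: list[tuple[float, float, float]] = []
    step = 1.0 / max(np.linalg.norm(g), 1e-12)
    shape = L.shape
    npix = L.size

    def split(x):
        return x[:npix].reshape(shape), x[npix:].reshape(shape)

    x = np.concatenate([L.ravel(), A.ravel()])
    n_run = 0
    for it in range(solver.n_iterations):
        gtd = float(g @ d)
        if gtd >= 0:  # non-descent conjugate direction: restart on steepest descent
            d = -g
            gtd = float(g @ d)
            notes.append(f"iter {it}: restart (non-descent direction)")
        # Armijo backtracking
        t = step * 2.0
        accepted = False
        for _ in range(solver.ls_max_trials):
            Lt, At = split(x + t * d)
            ft, rt, tot_t, _, _ = _criterion_parts(
                Lt, At, I_meas.values, w, config, K_hat, solver, want_grad=False)
            if tot_t <= total + solver.ls_c1 * t * gtd:
                accepted = True
                break
            t *= solver.ls_factor
        if not accepted and d is not None and not np.array_equal(d, -g):
            # steepest-descent fallback for this iteration
            d = -g
            gtd = float(g @ d)
            t = step * 2.0
            for _ in range(solver.ls_max_trials):
                Lt, At = split(x + t * d)
                ft, rt, tot_t, _, _ = _criterion_parts(
                    Lt, At, I_meas.values, w, config, K_hat, solver,
                    want_grad=False)
                if tot_t <= total + solver.ls_c1 * t * gtd:
                    accepted = True
                    notes.append(f"iter {it}: steepest-descent fallback")
                    break
                t *= solver.ls_factor
        if not accepted:
            notes.append(f"iter {it}: line search failed, stopping")
            history.append((fid, reg, total))
            n_run = it + 1
            break

        x = x + t * d
        step = t
        Lc, Ac = split(x)
        fid, reg, total, gLn, gAn = _criterion_parts(
            Lc, Ac, I_meas.values, w, config, K_hat, solver, want_grad=True)
        g_new = np.concatenate([gLn.ravel(), gAn.ravel()])
        history.append((fid, reg, total))
        n_run = it + 1

        # Polak–Ribière+ with periodic restart
        if (it + 1) % min(npix, solver.restart_every) == 0:
            beta = 0.0
        else:
            beta = max(0.0, float(g_new @ (g_new - g)) /
                       max(float(g @ g), 1e-300))
        d = -g_new + beta * d
        g = g_new

    Lf, Af = split(x)
    return ReconResult(SampleMaps(Lf, Af, init.pixel_pitch), history, n_run,
                       converged=n_run == solver.n_iterations, notes=notes)


def first_reconstruction(I_meas: IntensityImage, config: OpticsConfig,
                         alpha: float = DEFAULT_ALPHA_STAGE1,
                         n_iterations: int = 20) -> ReconResult:
    """Fast wrapped reconstruction: null init, Dirac kernel, ζ₁, 20 iterations."""
    init = SampleMaps(np.zeros(I_meas.values.shape),
                      np.zeros(I_meas.values.shape), I_meas.pixel_pitch)
    cfg = SolverConfig(n_iterations=n_iterations, alpha=alpha, stage="first",
                       use_kernel=False)
    return minimize(I_meas, init, cfg, config, K=None)


def second_reconstruction(I_meas: IntensityImage, init: SampleMaps,
                          config: OpticsConfig, K: CoherenceKernel | None,
                          alpha: float = DEFAULT_ALPHA_STAGE2,
                          n_iterations: int = 70) -> ReconResult:
    """Final reconstruction: unwrapped init, full kernel K, ζ₂, 70 iterations."""
    cfg = SolverConfig(n_iterations=n_iterations, alpha=alpha, stage="second",
                       use_kernel=True)
    return minimize(I_meas, init, cfg, config, K=K)
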