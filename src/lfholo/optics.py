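"""Forward model of lens-free in-line holographic image formation.

A thin transmissive object described by an optical path difference map ``L``
(in µm) and a (negative) absorption map ``A`` modulates an incident plane
wave.  The transmitted field is Fresnel-propagated over the sample-to-sensor
distance ``Z`` and the squared modulus, scaled by the illumination background
``B`` and blurred by a partial-coherence kernel ``K``, gives the predicted
hologram intensity::

    E(L, A) = exp(2iπL/λ + A)
    I(L, A) = B · |E * h_Z|² * K

with ``h_Z(r) = 1/(iλZ) · exp(iπ r²/(λZ))`` the paraxial free-space kernel.
All lengths are carried in µm; intensities are grey levels (floats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticsConfig",
    "SampleMaps",
    "ComplexField",
    "CoherenceKernel",
    "IntensityImage",
    "FresnelSamplingWarning",
    "transmission",
    "fresnel_propagate",
    "coherence_kernel",
    "gaussian_kernel",
    "dirac_kernel",
    "predict_intensity",
]


class FresnelSamplingWarning(UserWarning):
    """Grid too coarse for the requested propagation distance/wavelength."""


@dataclass
class OpticsConfig:
    """Acquisition geometry and illumination of a lens-free setup.

    Defaults are the reference simulation conditions: a monochromatic LED
    (450 ± 15 nm) of 50 µm diameter placed 50 mm above the sample, a sensor
    of 1.67 µm pitch at Z = 1270 µm, background of 105 grey levels.
    """

    wavelength: float = 0.450           # µm
    spectral_width: float = 0.030       # µm, full width of the source spectrum
    source_diameter: float = 50.0       # µm
    source_sample_distance: float = 50_000.0  # µm
    sample_sensor_distance: float = 1270.0    # µm (Z)
    pixel_pitch: float = 1.67           # µm
    background: float = 105.0           # grey levels (B)
    n_spectral_samples: int = 5

    def __post_init__(self) -> None:
        for name in ("wavelength", "source_sample_distance",
                     "sample_sensor_distance", "pixel_pitch", "background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.spectral_width < 0 or self.source_diameter < 0:
            raise ValueError("spectral_width and source_diameter must be >= 0")
        if self.n_spectral_samples < 1:
            raise ValueError("n_spectral_samples must be >= 1")

    @property
    def is_coherent(self) -> bool:
        """True when the source is a monochromatic point (K degenerates to a Dirac)."""
        return self.source_diameter == 0.0 and (
            self.spectral_width == 0.0 or self.n_spectral_samples == 1
        )


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")


@dataclass
class SampleMaps:
    """Paired object-plane maps: OPD ``L`` (µm) and negative absorption ``A``."""

    L: np.ndarray
    A: np.ndarray
    pixel_pitch: float = 1.67

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.L.shape != self.A.shape:
            raise ValueError("L and A must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def copy(self) -> "SampleMaps":
        return SampleMaps(self.L.copy(), self.A.copy(), self.pixel_pitch)


@dataclass
class ComplexField:
    """Dimensionless complex amplitude sampled on the object/sensor grid."""

    values: np.ndarray
    pixel_pitch: float = 1.67


@dataclass
class CoherenceKernel:
    """Normalized nonnegative blur kernel modelling source partial coherence.

    The kernel is centered at the geometric image center (``shape // 2``).
    """

    values: np.ndarray
    pixel_pitch: float = 1.67

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("kernel values must be nonnegative")
        s = self.values.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError(f"kernel must sum to 1 (got {s})")

    @property
    def is_dirac(self) -> bool:
        center = tuple(n // 2 for n in self.values.shape)
        return self.values[center] == 1.0


@dataclass
class IntensityImage:
    """Nonnegative hologram intensity in grey levels at the sensor plane."""

    values: np.ndarray
    pixel_pitch: float = 1.67

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("intensity must be nonnegative")


# ---------------------------------------------------------------------------
# Core operations (array-level kernels used by the solver live underneath the
# dataclass API and are re-exported with a leading underscore)
# ---------------------------------------------------------------------------

def _transmission(L: np.ndarray, A: np.ndarray, wavelength: float) -> np.ndarray:
    return np.exp(2j * np.pi * L / wavelength + A)


def transmission(maps: SampleMaps, wavelength: float) -> ComplexField:
    """Complex transmission ``exp(2iπL/λ + A)`` of the sample plane."""
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    _check_finite(maps.L, "L")
    _check_finite(maps.A, "A")
    return ComplexField(_transmission(maps.L, maps.A, wavelength), maps.pixel_pitch)


def _fresnel_tf(shape: tuple[int, int], Z: float, wavelength: float,
                pitch: float) -> np.ndarray:
    """Fresnel transfer function exp(-iπλZ(fx²+fy²)) on the FFT grid.

    The constant plane-wave phase exp(2iπZ/λ) is dropped: it cancels in any
    intensity and makes a uniform field an exact fixed point.  Unit modulus
    makes propagation exactly unitary and propagate(-Z) the exact inverse
    and adjoint.
    """
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return np.exp(-1j * np.pi * wavelength * Z * f2)


def _sampling_guard(shape: tuple[int, int], Z: float, wavelength: float,
                    pitch: float, strict: bool) -> None:
    n = min(shape)
    ratio = wavelength * abs(Z) / (n * pitch ** 2)
    if ratio > 1.0:
        msg = (f"Fresnel transfer function is undersampled for this grid "
               f"(λ|Z|/(N·pitch²) = {ratio:.2f} > 1); results near high "
               f"frequencies are aliased")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, FresnelSamplingWarning, stacklevel=3)


def _propagate(values: np.ndarray, Z: float, wavelength: float, pitch: float,
               pad_factor: int = 1) -> np.ndarray:
    """FFT convolution with the Fresnel kernel.

    ``pad_factor > 1`` zero-pads before the transform (for aperiodic fields);
    the default periodic form is exactly unitary on the grid.
    """
    if pad_factor > 1:
        ny, nx = values.shape
        py, px = ny * (pad_factor - 1) // 2, nx * (pad_factor - 1) // 2
        padded = np.pad(values, ((py, py), (px, px)))
        out = _propagate(padded, Z, wavelength, pitch, pad_factor=1)
        return out[py:py + ny, px:px + nx]
    H = _fresnel_tf(values.shape, Z, wavelength, pitch)
    return np.fft.ifft2(np.fft.fft2(values) * H)


def fresnel_propagate(field: ComplexField, Z: float, wavelength: float,
                      pad_factor: int = 1, strict_sampling: bool = False) -> ComplexField:
    """Propagate a field over distance ``Z`` (µm); negative Z back-propagates."""
    if Z == 0:
        raise ValueError("Z must be nonzero (use the field directly for Z=0)")
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    _sampling_guard(field.values.shape, Z, wavelength, field.pixel_pitch,
                    strict_sampling)
    out = _propagate(field.values, Z, wavelength, field.pixel_pitch)
    return ComplexField(out, field.pixel_pitch)


def dirac_kernel(shape: tuple[int, int], pixel_pitch: float = 1.67) -> CoherenceKernel:
    """Discrete Dirac kernel (identity convolution)."""
    k = np.zeros(shape)
    k[shape[0] // 2, shape[1] // 2] = 1.0
    return CoherenceKernel(k, pixel_pitch)


def gaussian_kernel(shape: tuple[int, int], fwhm: float = 1.75,
                    pixel_pitch: float = 1.67) -> CoherenceKernel:
    """Isotropic normalized Gaussian of given FWHM (µm) on the pixel grid.

    This is the simulation dialect of the partial-coherence kernel: the
    reference parameter table summarizes K by a single 1.75 µm width.
    """
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    cy, cx = shape[0] // 2, shape[1] // 2
    y = (np.arange(shape[0]) - cy) * pixel_pitch
    x = (np.arange(shape[1]) - cx) * pixel_pitch
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    k = np.exp(-r2 / (2.0 * sigma ** 2))
    return CoherenceKernel(k / k.sum(), pixel_pitch)


def _source_points(diameter: float) -> list[tuple[float, float, float]]:
    """Discretize a uniform source disc into ≤ 9 weighted points (x, y, w).

    One axial point plus eight on the ring of radius D/2·√½ (the
    area-weighted mean radius of a uniform disc), equal weights.
    """
    if diameter == 0.0:
        return [(0.0, 0.0, 1.0)]
    r = diameter / 2.0 * np.sqrt(0.5)
    pts = [(0.0, 0.0, 1.0 / 9.0)]
    for k in range(8):
        th = 2.0 * np.pi * k / 8.0
        pts.append((r * np.cos(th), r * np.sin(th), 1.0 / 9.0))
    return pts


def _shift_image(img: np.ndarray, dy: float, dx: float, pitch: float) -> np.ndarray:
    """Subpixel translation of a real image by (dy, dx) µm via the Fourier shift."""
    if dy == 0.0 and dx == 0.0:
        return img
    ny, nx = img.shape
    fy = np.fft.fftfreq(ny, d=pitch)[:, None]
    fx = np.fft.fftfreq(nx, d=pitch)[None, :]
    phase = np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return np.fft.ifft2(np.fft.fft2(img) * phase).real


def _dirac_object_intensity(shape: tuple[int, int], Z: float, wavelength: float,
                            pitch: float) -> np.ndarray:
    """Sensor intensity of a point (single opaque pixel) object under unit illumination."""
    E = np.ones(shape, dtype=complex)
    E[shape[0] // 2, shape[1] // 2] = 0.0
    U = _propagate(E, Z, wavelength, pitch)
    return np.abs(U) ** 2


def coherence_kernel(config: OpticsConfig, grid_shape: tuple[int, int],
                     reg_floor: float = 1e-3) -> CoherenceKernel:
    """Partial-coherence kernel K from paired point-object simulations.

    Simulates the hologram of a Dirac object (a) under fully coherent
    monochromatic point-source illumination (``I_total``) and (b) under the
    configured extended, polychromatic source (``I_partial``): the source
    disc is discretized into ≤ 9 off-axis points whose geometric projection
    shifts the pattern by ``offset · Z / source_sample_distance``, and the
    spectrum into ``n_spectral_samples`` equally weighted wavelengths across
    the full spectral width.  K is the Wiener-regularized deconvolution of
    I_partial by I_total, clipped to nonnegative values and normalized.
    """
    if config.is_coherent:
        # I_partial == I_total identically: skip the (regularized, hence
        # inexact) deconvolution and return the exact answer.
        return dirac_kernel(grid_shape, config.pixel_pitch)

    Z = config.sample_sensor_distance
    pitch = config.pixel_pitch
    lam0 = config.wavelength

    I_total = _dirac_object_intensity(grid_shape, Z, lam0, pitch)

    if config.spectral_width > 0 and config.n_spectral_samples > 1:
        lams = np.linspace(lam0 - config.spectral_width / 2.0,
                           lam0 + config.spectral_width / 2.0,
                           config.n_spectral_samples)
    else:
        lams = np.array([lam0])
    demag = Z / config.source_sample_distance
    pts = _source_points(config.source_diameter)

    I_partial = np.zeros(grid_shape)
    for lam in lams:
        I_lam = _dirac_object_intensity(grid_shape, Z, lam, pitch)
        for (sx, sy, w) in pts:
            I_partial += (w / len(lams)) * _shift_image(
                I_lam, sy * demag, sx * demag, pitch)

    # Convolution with a normalized kernel preserves the mean, so the
    # background-free fringe patterns obey the same relation; deconvolving
    # them keeps the Wiener floor relative to the fringe spectrum instead of
    # the dominant DC term.  The DC gain of a unit-mass kernel is pinned to 1.
    T = np.fft.fft2(I_total - I_total.mean())
    P = np.fft.fft2(I_partial - I_partial.mean())
    floor = reg_floor * np.abs(T).max()
    K_hat = np.conj(T) * P / (np.abs(T) ** 2 + floor ** 2)
    K_hat[0, 0] = 1.0
    K = np.fft.fftshift(np.fft.ifft2(K_hat).real)
    K = np.clip(K, 0.0, None)
    total = K.sum()
    if total <= 0:
        raise RuntimeError("coherence kernel deconvolution produced an empty kernel")
    return CoherenceKernel(K / total, pitch)


def _kernel_tf(K: CoherenceKernel | None, shape: tuple[int, int]) -> np.ndarray | None:
    """FFT of the (centered) kernel, or None when the convolution is the identity."""
    if K is None or K.is_dirac:
        return None
    if K.values.shape != shape:
        raise ValueError("kernel shape must match the image grid")
    return np.fft.fft2(np.fft.ifftshift(K.values))


def _convolve_k(img: np.ndarray, K_hat: np.ndarray | None) -> np.ndarray:
    if K_hat is None:
        return img
    return np.fft.ifft2(np.fft.fft2(img) * K_hat).real


def _correlate_k(img: np.ndarray, K_hat: np.ndarray | None) -> np.ndarray:
    """Adjoint of :func:`_convolve_k`."""
    if K_hat is None:
        return img
    return np.fft.ifft2(np.fft.fft2(img) * np.conj(K_hat)).real


def _predict_intensity(L: np.ndarray, A: np.ndarray, config: OpticsConfig,
                       K_hat: np.ndarray | None) -> np.ndarray:
    E = _transmission(L, A, config.wavelength)
    U = _propagate(E, config.sample_sensor_distance, config.wavelength,
                   config.pixel_pitch)
    I = config.background * _convolve_k(np.abs(U) ** 2, K_hat)
    return I


def predict_intensity(maps: SampleMaps, config: OpticsConfig,
                      K: CoherenceKernel | None = None) -> IntensityImage:
    """Model hologram ``B · |E(L,A) * h_Z|² * K`` (grey levels)."""
    if K is not None and K.values.shape != maps.shape:
        raise ValueError("maps and kernel shapes differ")
    if K is not None and not np.isclose(K.pixel_pitch, maps.pixel_pitch):
        raise ValueError("maps and kernel pixel pitch differ")
    _check_finite(maps.L, "L")
    _check_finite(maps.A, "A")
    K_hat = _kernel_tf(K, maps.shape)
    I = _predict_intensity(maps.L, maps.A, config, K_hat)
    # |.|² * K with a normalized nonnegative K is nonnegative up to round-off
    return IntensityImage(np.clip(I, 0.0, None), maps.pixel_pitch)
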