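"""Synthetic phantoms of cells in suspension and simulated holograms.

Cells are modelled as homogeneous spheres of radius ``r`` with a complex
refractive-index contrast ``Δn = Δn_r + iΔn_i`` to the surrounding medium.
Projected onto the object plane, a sphere contributes its chord thickness
``T(x, y) = 2√(r² − d²)`` (``d`` the in-plane distance to its center), and

    L(x, y) = T(x, y) · Δn_r                 (optical path difference, µm)
    A(x, y) = −2π T(x, y) / λ · Δn_i         (negative absorption)

Thickness contributions of overlapping cells add (projection approximation).
Holograms are the forward-model intensity with per-pixel Poisson noise, grey
levels interpreted as photon counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .optics import (CoherenceKernel, IntensityImage, OpticsConfig,
                     SampleMaps, _kernel_tf, _predict_intensity)

__all__ = [
    "CellSpec",
    "ScenePhantom",
    "SimParams",
    "TrainingPair",
    "sample_scene",
    "render_maps",
    "simulate_hologram",
    "surface_density",
    "build_training_set",
    "extract_vignettes",
]


@dataclass
class CellSpec:
    """One spherical cell: center (µm), radius (µm), index contrast."""

    center_x: float
    center_y: float
    radius: float
    dnr: float
    dni: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.dnr < 0 or self.dni < 0:
            raise ValueError("dnr and dni must be >= 0")


@dataclass
class ScenePhantom:
    """A list of spherical cells on a pixel grid; the simulation ground truth."""

    cells: list[CellSpec]
    grid_shape: tuple[int, int]
    pixel_pitch: float = 1.67

    def __post_init__(self) -> None:
        h = self.grid_shape[0] * self.pixel_pitch
        w = self.grid_shape[1] * self.pixel_pitch
        for c in self.cells:
            if not (0.0 <= c.center_x < w and 0.0 <= c.center_y < h):
                raise ValueError("cell center outside the field of view")


@dataclass
class SimParams:
    """Random-scene distribution: the reference simulation conditions.

    Defaults follow the study conditions: 500–5000 cells per 1000×1000 px
    image (179–1792 cells/mm² at 1.67 µm pitch), radii uniform in 5–20 µm,
    Δn_r uniform in 0.01–0.05, Δn_i uniform in 0–0.005, ±5% jitter on Z and
    ±30% on the background B per image.
    """

    n_cells_range: tuple[int, int] = (500, 5000)
    radius_range: tuple[float, float] = (5.0, 20.0)
    dnr_range: tuple[float, float] = (0.01, 0.05)
    dni_range: tuple[float, float] = (0.0, 0.005)
    z_jitter: float = 0.05
    background_jitter: float = 0.30
    grid_shape: tuple[int, int] = (1000, 1000)
    pixel_pitch: float = 1.67

    def __post_init__(self) -> None:
        for name in ("n_cells_range", "radius_range", "dnr_range", "dni_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max")


@dataclass
class TrainingPair:
    """A first-reconstruction input paired with its ground truth target."""

    input: SampleMaps
    target: SampleMaps
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input.shape != self.target.shape:
            raise ValueError("input and target must share shape")


def sample_scene(params: SimParams, rng: np.random.Generator) -> ScenePhantom:
    """Draw a random scene: cell count uniform on the integer range, radii and
    index contrasts i.i.d. uniform, centers uniform over the field of view."""
    lo, hi = params.n_cells_range
    n = int(rng.integers(lo, hi + 1))
    h = params.grid_shape[0] * params.pixel_pitch
    w = params.grid_shape[1] * params.pixel_pitch
    xs = rng.uniform(0.0, w, n)
    ys = rng.uniform(0.0, h, n)
    rs = rng.uniform(*params.radius_range, n)
    dnrs = rng.uniform(*params.dnr_range, n)
    dnis = rng.uniform(*params.dni_range, n)
    cells = [CellSpec(x, y, r, a, b)
             for x, y, r, a, b in zip(xs, ys, rs, dnrs, dnis)]
    return ScenePhantom(cells, params.grid_shape, params.pixel_pitch)


def _thickness_into(T: np.ndarray, cell: CellSpec, pitch: float,
                    weight: float) -> None:
    """Accumulate weight · chord thickness of one sphere into T (in place)."""
    ny, nx = T.shape
    r_px = cell.radius / pitch
    cx, cy = cell.center_x / pitch, cell.center_y / pitch
    x0 = max(int(np.floor(cx - r_px)) - 1, 0)
    x1 = min(int(np.ceil(cx + r_px)) + 2, nx)
    y0 = max(int(np.floor(cy - r_px)) - 1, 0)
    y1 = min(int(np.ceil(cy + r_px)) + 2, ny)
    if x0 >= x1 or y0 >= y1:
        return
    # pixel centers
    xs = (np.arange(x0, x1) + 0.5) * pitch - cell.center_x
    ys = (np.arange(y0, y1) + 0.5) * pitch - cell.center_y
    d2 = ys[:, None] ** 2 + xs[None, :] ** 2
    inside = d2 < cell.radius ** 2
    chord = np.where(inside, 2.0 * np.sqrt(np.clip(cell.radius ** 2 - d2, 0, None)), 0.0)
    T[y0:y1, x0:x1] += weight * chord


def render_maps(scene: ScenePhantom, wavelength: float = 0.450) -> SampleMaps:
    """Render a scene to (L, A) maps; additive over cells, zero off-cell."""
    L = np.zeros(scene.grid_shape)
    Aacc = np.zeros(scene.grid_shape)
    for c in scene.cells:
        _thickness_into(L, c, scene.pixel_pitch, c.dnr)
        if c.dni != 0.0:
            _thickness_into(Aacc, c, scene.pixel_pitch, c.dni)
    A = -(2.0 * np.pi / wavelength) * Aacc
    return SampleMaps(L, A, scene.pixel_pitch)


def simulate_hologram(maps: SampleMaps, config: OpticsConfig,
                      K: CoherenceKernel | None,
                      rng: np.random.Generator) -> IntensityImage:
    """Noisy hologram: Poisson counts with the forward-model mean."""
    K_hat = _kernel_tf(K, maps.shape)
    mean = _predict_intensity(maps.L, maps.A, config, K_hat)
    mean = np.clip(mean, 0.0, None)
    assert np.all(mean >= 0), "forward model produced negative mean intensity"
    return IntensityImage(rng.poisson(mean).astype(float), maps.pixel_pitch)


def surface_density(n_cells: int, grid_shape: tuple[int, int],
                    pixel_pitch: float) -> int:
    """Cells per mm² of the imaged area, truncated to an integer."""
    if n_cells < 0 or pixel_pitch <= 0:
        raise ValueError("inputs must be positive")
    area_mm2 = (grid_shape[0] * pixel_pitch * 1e-3) * (grid_shape[1] * pixel_pitch * 1e-3)
    return int(n_cells / area_mm2)


def build_training_set(n_images: int, params: SimParams, config: OpticsConfig,
                       solver, rng: np.random.Generator,
                       K: CoherenceKernel | None = None) -> list[TrainingPair]:
    """Simulate scenes and pair their first reconstructions with ground truth.

    ``solver(I_meas, optics) -> ReconResult`` is the first-reconstruction
    operation.  Per image, Z and B are jittered uniformly within their
    tolerance bands; the per-image seed, Z and B are recorded in the pair
    metadata.  Solver non-convergence flags the pair instead of dropping it.
    """
    pairs: list[TrainingPair] = []
    for i in range(n_images):
        z = config.sample_sensor_distance * (
            1.0 + rng.uniform(-params.z_jitter, params.z_jitter))
        b = config.background * (
            1.0 + rng.uniform(-params.background_jitter, params.background_jitter))
        cfg_i = replace(config, sample_sensor_distance=z, background=b)
        scene = sample_scene(params, rng)
        truth = render_maps(scene, cfg_i.wavelength)
        holo = simulate_hologram(truth, cfg_i, K, rng)
        result = solver(holo, cfg_i)
        meta = {"index": i, "Z": z, "B": b, "n_cells": len(scene.cells),
                "converged": bool(getattr(result, "converged", True))}
        pairs.append(TrainingPair(result.maps, truth, meta))
    return pairs


def extract_vignettes(pairs: list[TrainingPair], size: int, n: int,
                      rng: np.random.Generator) -> list[TrainingPair]:
    """Random axis-aligned crops, the same window applied to input and target."""
    if not pairs:
        raise ValueError("no pairs to crop from")
    out: list[TrainingPair] = []
    for _ in range(n):
        pair = pairs[int(rng.integers(0, len(pairs)))]
        ny, nx = pair.input.shape
        if size > ny or size > nx:
            raise ValueError("vignette size exceeds image size")
        y = int(rng.integers(0, ny - size + 1))
        x = int(rng.integers(0, nx - size + 1))
        sl = (slice(y, y + size), slice(x, x + size))
        out.append(TrainingPair(
            SampleMaps(pair.input.L[sl], pair.input.A[sl], pair.input.pixel_pitch),
            SampleMaps(pair.target.L[sl], pair.target.A[sl], pair.target.pixel_pitch),
            dict(pair.meta, crop=(y, x, size)),
        ))
    return out
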