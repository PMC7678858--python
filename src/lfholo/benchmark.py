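"""Scaled-down alternation benchmark: sparse scenes, reduced network, CPU budget.

The reference study conditions (1000×1000 px scenes with 500–5000 cells, a
20-block/32-feature network, 10 epochs of 12 800 vignettes) need hours of
GPU time.  This module fixes a smaller, self-contained instance of the same
physics that trains in a few CPU minutes and exhibits the phenomenon the
alternation exists for: sparse scenes of super-λ/2 spheres whose first
reconstruction is wrapped, a reduced network (6 blocks, 16 features) trained
on 32×32 vignettes of simulated first reconstructions, and the full
three-step pipeline.

Benchmark conditions (fixed):
  grid 128×128 at 1.67 µm pitch, 2–5 cells per scene, radii 5–8 µm,
  Δn_r ∈ [0.02, 0.05] (max OPD 0.2–0.8 µm, i.e. up to ≈1.8λ: one to two
  wraps), Δn_i ∈ [0, 0.002]; 60 training scenes, 30 epochs of 320 vignettes
  (≈6 CPU minutes), Adam at 1e-3, batch 16.  Vignette sampling is biased
  toward cell centers
  (70% of crops) so that most training windows contain wrapped structure.
"""

from __future__ import annotations

import numpy as np

from .optics import OpticsConfig, SampleMaps
from .phantoms import (ScenePhantom, SimParams, TrainingPair, render_maps,
                       sample_scene, simulate_hologram)
from .solver import first_reconstruction
from .unwrap import (NetworkSpec, TrainConfig, TrainedUnwrapper,
                     build_network, train)

__all__ = [
    "benchmark_sim_params",
    "simulate_benchmark_pairs",
    "cell_biased_vignette_source",
    "train_benchmark_unwrapper",
]

VIGNETTE_SIZE = 32
CELL_CROP_FRACTION = 0.7


def benchmark_sim_params(grid: int = 128) -> SimParams:
    """Sparse super-λ/2 scene distribution of the scaled-down benchmark."""
    return SimParams(n_cells_range=(2, 5), radius_range=(5.0, 8.0),
                     dnr_range=(0.02, 0.05), dni_range=(0.0, 0.002),
                     grid_shape=(grid, grid))


def simulate_benchmark_pairs(n_images: int, optics: OpticsConfig,
                             rng: np.random.Generator,
                             params: SimParams | None = None) -> list[TrainingPair]:
    """Simulate scenes and first reconstructions; the scene rides in the meta."""
    params = params or benchmark_sim_params()
    pairs: list[TrainingPair] = []
    for i in range(n_images):
        scene = sample_scene(params, rng)
        truth = render_maps(scene, optics.wavelength)
        holo = simulate_hologram(truth, optics, None, rng)
        res = first_reconstruction(holo, optics)
        pairs.append(TrainingPair(res.maps, truth,
                                  {"index": i, "scene": scene}))
    return pairs


def cell_biased_vignette_source(pairs: list[TrainingPair],
                                size: int = VIGNETTE_SIZE):
    """Vignette sampler whose crops mostly land on cells.

    Uniform random crops of sparse scenes are mostly empty background; with
    the benchmark's ≈5% cell coverage the network would see little wrapped
    structure.  A fraction of crops is therefore centered (with jitter) on a
    randomly chosen cell of the source scene.
    """
    def source(n: int, rng: np.random.Generator) -> list[TrainingPair]:
        out = []
        for _ in range(n):
            pair = pairs[int(rng.integers(0, len(pairs)))]
            scene: ScenePhantom = pair.meta["scene"]
            ny, nx = pair.input.shape
            pitch = pair.input.pixel_pitch
            if scene.cells and rng.uniform() < CELL_CROP_FRACTION:
                c = scene.cells[int(rng.integers(0, len(scene.cells)))]
                cy = int(c.center_y / pitch) + int(rng.integers(-size // 4, size // 4 + 1))
                cx = int(c.center_x / pitch) + int(rng.integers(-size // 4, size // 4 + 1))
                y = int(np.clip(cy - size // 2, 0, ny - size))
                x = int(np.clip(cx - size // 2, 0, nx - size))
            else:
                y = int(rng.integers(0, ny - size + 1))
                x = int(rng.integers(0, nx - size + 1))
            sl = (slice(y, y + size), slice(x, x + size))
            out.append(TrainingPair(
                SampleMaps(pair.input.L[sl], pair.input.A[sl], pitch),
                SampleMaps(pair.target.L[sl], pair.target.A[sl], pitch)))
        return out
    return source


def train_benchmark_unwrapper(seed: int = 0,
                              optics: OpticsConfig | None = None,
                              n_images: int = 60,
                              n_epochs: int = 30,
                              vignettes_per_epoch: int = 320) -> TrainedUnwrapper:
    """Train the reduced unwrapping network under the benchmark conditions."""
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    pairs = simulate_benchmark_pairs(n_images, optics, rng)
    spec = NetworkSpec.reduced()
    model = build_network(spec, rng)
    config = TrainConfig(learning_rate=1e-3, n_epochs=n_epochs,
                         vignettes_per_epoch=vignettes_per_epoch,
                         vignette_size=VIGNETTE_SIZE, batch_size=16,
                         seed=seed, norm_L=optics.wavelength)
    return train(model, cell_biased_vignette_source(pairs), config, rng,
                 training_Z=optics.sample_sensor_distance, spec=spec)
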