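"""Three-step alternation orchestration.

Step 1: fast wrapped variational reconstruction (Dirac kernel, TV on the
complex field, few iterations).  Step 2: the trained network unwraps the
(L, A) pair.  Step 3: a longer variational reconstruction with the full
coherence kernel and TV on L, initialized at the network prediction, pulls
the result back toward the data — correcting deviations the network
introduced — while keeping the unwrapped branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import psnr, refractive_index_recovery, regression_summary
from .optics import (CoherenceKernel, IntensityImage, OpticsConfig,
                     SampleMaps)
from .phantoms import SimParams, render_maps, sample_scene, simulate_hologram
from .solver import (DEFAULT_ALPHA_STAGE1, DEFAULT_ALPHA_STAGE2, ReconResult,
                     SolverConfig, data_fidelity, first_reconstruction,
                     second_reconstruction)
from .unwrap import TrainedUnwrapper, predict

__all__ = ["PipelineConfig", "PipelineResult", "run_alternation",
           "run_validation_experiment"]


@dataclass
class PipelineConfig:
    optics: OpticsConfig
    unwrapper: TrainedUnwrapper
    K: CoherenceKernel | None = None
    alpha_stage1: float = DEFAULT_ALPHA_STAGE1
    alpha_stage2: float = DEFAULT_ALPHA_STAGE2
    n_iter_stage1: int = 20
    n_iter_stage2: int = 70
    z_tolerance: float = 0.05   # relative Z mismatch allowed vs training_Z
    save_intermediates: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    first: ReconResult
    predicted: SampleMaps
    final: ReconResult
    fidelity_at_prediction: float
    provenance: dict = field(default_factory=dict)


def run_alternation(I_meas: IntensityImage, config: PipelineConfig) -> PipelineResult:
    """first_reconstruction → network unwrap → second_reconstruction.

    Refuses holograms whose Z differs from the network's training Z by more
    than the configured tolerance (one network is trained per distance).
    """
    Z = config.optics.sample_sensor_distance
    Zt = config.unwrapper.training_Z
    if abs(Z - Zt) / Zt > config.z_tolerance:
        raise ValueError(
            f"optics Z = {Z} µm is outside {100 * config.z_tolerance:.0f}% of the "
            f"network's training Z = {Zt} µm; train a network for this distance")

    first = first_reconstruction(I_meas, config.optics,
                                 alpha=config.alpha_stage1,
                                 n_iterations=config.n_iter_stage1)
    predicted = predict(config.unwrapper, first.maps)
    fid_pred = data_fidelity(predicted, I_meas, config.optics, config.K)
    final = second_reconstruction(I_meas, predicted, config.optics, config.K,
                                  alpha=config.alpha_stage2,
                                  n_iterations=config.n_iter_stage2)
    provenance = {
        "Z": Z, "training_Z": Zt, "seed": config.seed,
        "alpha_stage1": config.alpha_stage1,
        "alpha_stage2": config.alpha_stage2,
        "n_iter": (config.n_iter_stage1, config.n_iter_stage2),
    }
    return PipelineResult(first, predicted, final, fid_pred, provenance)


def _stage_metrics(maps: SampleMaps, truth: SampleMaps, scene, wavelength: float):
    rec = refractive_index_recovery(maps, scene, wavelength)
    out = {"psnr_L": psnr(maps.L, truth.L, data_range=max(truth.L.max(), 1e-9))}
    if len(rec) >= 3 and np.var([r.dnr_true for r in rec]) > 0:
        reg = regression_summary([r.dnr_true for r in rec],
                                 [r.dnr_recons for r in rec])
        out.update(slope_dnr=reg.slope, r2_dnr=reg.r_squared, n_cells=reg.n_points)
    return out, rec


def run_validation_experiment(params: SimParams, config: PipelineConfig,
                              n_scenes: int, rng: np.random.Generator) -> dict:
    """Simulate scenes, run the alternation, and score every stage.

    Returns a report dict with per-scene, per-stage recovery regressions and
    PSNR, plus the fidelity comparison between the network prediction and
    the final reconstruction.
    """
    scenes = []
    for i in range(n_scenes):
        scene = sample_scene(params, rng)
        truth = render_maps(scene, config.optics.wavelength)
        holo = simulate_hologram(truth, config.optics, config.K, rng)
        result = run_alternation(holo, config)
        entry = {"scene_index": i, "n_cells": len(scene.cells)}
        for name, maps in (("first", result.first.maps),
                           ("predicted", result.predicted),
                           ("final", result.final.maps)):
            metrics, _ = _stage_metrics(maps, truth, scene, config.optics.wavelength)
            entry[name] = metrics
        entry["fidelity_at_prediction"] = result.fidelity_at_prediction
        entry["fidelity_final"] = result.final.history[-1][0]
        scenes.append(entry)
    return {"n_scenes": n_scenes, "scenes": scenes}
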