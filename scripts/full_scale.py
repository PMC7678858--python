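"""Full-scale training and validation protocol (long-running; GPU-class job).

Reproduces the reference protocol end to end: 1000 simulated 1000×1000
scenes of 500–5000 cells, first reconstructions for each, a 20-block /
32-feature unwrapping network trained for 10 epochs of 12 800 random
121×121 vignettes at learning rate 1e-4, and the three-density validation
(≈358 / 909 / 1627 cells/mm²) with per-cell Δn recovery regressions.

On a single CPU this takes on the order of days (the reference
implementation reports ≈10 h on a workstation GPU); it is provided for
completeness and is not part of the test suite.  For the CPU-minute
demonstration of the same physics, see ``lfholo.benchmark`` and
``scripts/acceptance.py``.

Usage:  python scripts/full_scale.py --seed 0 --out scratch/full_scale
"""

import argparse
import json
import os
import warnings

import numpy as np

from lfholo.evaluate import refractive_index_recovery, regression_summary
from lfholo.optics import FresnelSamplingWarning, OpticsConfig, gaussian_kernel
from lfholo.phantoms import (SimParams, extract_vignettes, render_maps,
                             sample_scene, simulate_hologram)
from lfholo.pipeline import PipelineConfig, run_alternation
from lfholo.solver import first_reconstruction
from lfholo.unwrap import (NetworkSpec, TrainConfig, build_network,
                           save_unwrapper, train)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=str, required=True)
    parser.add_argument("--n-train-images", type=int, default=1000)
    parser.add_argument("--n-epochs", type=int, default=10)
    args = parser.parse_args()

    warnings.simplefilter("ignore", FresnelSamplingWarning)
    os.makedirs(args.out, exist_ok=True)
    rng = np.random.default_rng(args.seed)
    optics = OpticsConfig()
    params = SimParams()               # reference conditions: Table values

    print(f"simulating {args.n_train_images} training scenes + first "
          f"reconstructions ...")
    pairs = []
    for i in range(args.n_train_images):
        from dataclasses import replace
        z = optics.sample_sensor_distance * (1 + rng.uniform(-0.05, 0.05))
        b = optics.background * (1 + rng.uniform(-0.30, 0.30))
        cfg_i = replace(optics, sample_sensor_distance=z, background=b)
        scene = sample_scene(params, rng)
        truth = render_maps(scene, cfg_i.wavelength)
        holo = simulate_hologram(truth, cfg_i, None, rng)
        pairs.append(__import__("lfholo").phantoms.TrainingPair(
            first_reconstruction(holo, cfg_i).maps, truth, {"Z": z, "B": b}))
        if (i + 1) % 10 == 0:
            print(f"  {i + 1}/{args.n_train_images}")

    spec = NetworkSpec()               # 20 blocks, 32 features
    model = build_network(spec, rng)
    config = TrainConfig(seed=args.seed, norm_L=optics.wavelength)
    source = lambda n, r: extract_vignettes(pairs, config.vignette_size, n, r)
    print("training the full network (10 epochs x 12800 vignettes) ...")
    unwrapper = train(model, source, config, rng,
                      training_Z=optics.sample_sensor_distance, spec=spec)
    save_unwrapper(unwrapper, os.path.join(args.out, "full_model.npz"))

    print("validating at three densities ...")
    report = {}
    K = gaussian_kernel(params.grid_shape)
    for n_cells in (1001, 2547, 4569):
        p = SimParams(n_cells_range=(n_cells, n_cells))
        scene = sample_scene(p, rng)
        truth = render_maps(scene, optics.wavelength)
        holo = simulate_hologram(truth, optics, K, rng)
        res = run_alternation(holo, PipelineConfig(optics=optics,
                                                   unwrapper=unwrapper, K=K))
        recs = refractive_index_recovery(res.final.maps, scene,
                                         optics.wavelength)
        s = regression_summary([r.dnr_true for r in recs],
                               [r.dnr_recons for r in recs])
        report[str(n_cells)] = {"slope_dnr": s.slope, "r2_dnr": s.r_squared,
                                "n_cells": s.n_points}
        print(f"  {n_cells} cells: slope {s.slope:.3f}  R² {s.r_squared:.3f}")

    with open(os.path.join(args.out, "validation.json"), "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
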