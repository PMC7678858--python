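"""File I/O: single-channel TIFF images, YAML optics configs, array containers."""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import tifffile
import yaml

from .optics import IntensityImage, OpticsConfig, SampleMaps

__all__ = [
    "read_intensity_tiff", "write_intensity_tiff",
    "read_maps", "write_maps",
    "read_optics_config", "write_optics_config",
]


def write_intensity_tiff(path: str, image: IntensityImage) -> None:
    tifffile.imwrite(path, image.values.astype(np.float32),
                     metadata={"pixel_pitch_um": image.pixel_pitch})


def read_intensity_tiff(path: str, pixel_pitch: float = 1.67) -> IntensityImage:
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    return IntensityImage(np.clip(arr, 0.0, None), pixel_pitch)


def write_maps(path: str, maps: SampleMaps) -> None:
    """(L, A) pair in one .npz container with pitch metadata."""
    np.savez(path, L=maps.L, A=maps.A, pixel_pitch=maps.pixel_pitch)


def read_maps(path: str) -> SampleMaps:
    data = np.load(path)
    return SampleMaps(data["L"], data["A"], float(data["pixel_pitch"]))


def write_optics_config(path: str, config: OpticsConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_optics_config(path: str) -> OpticsConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return OpticsConfig(**data)
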