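"""TIFF / JSON plumbing for intensities, gradients and phase maps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import GradientField, IntensityImage, PhaseMap


def read_intensity(path, pixel_size: float = 1.0,
                   plane_offset: float = 0.0) -> IntensityImage:
    """Read a single-channel TIFF (integer or float) as an intensity image."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D TIFF, got shape {arr.shape}")
    return IntensityImage(values=arr.astype(float), pixel_size=pixel_size,
                          plane_offset=plane_offset)


def write_intensity(path, image: IntensityImage) -> None:
    tifffile.imwrite(str(path), image.values.astype(np.float32))


def write_gradients(prefix, g: GradientField) -> None:
    """Write a gradient field as two float TIFFs plus a mask TIFF."""
    prefix = Path(prefix)
    tifffile.imwrite(str(prefix.with_suffix(".h.tif")),
                     g.grad_h.astype(np.float32))
    tifffile.imwrite(str(prefix.with_suffix(".v.tif")),
                     g.grad_v.astype(np.float32))
    tifffile.imwrite(str(prefix.with_suffix(".mask.tif")),
                     g.mask.astype(np.uint8))


def write_phase(path, phase: PhaseMap, extra: dict | None = None) -> None:
    """Phase as 32-bit float TIFF (NaN outside mask) with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(str(path), phase.masked().astype(np.float32))
    meta = {"pixel_pitch_m": phase.pixel_pitch, "units": "um",
            "piston_removed": True}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_phase(path) -> PhaseMap:
    path = Path(path)
    arr = tifffile.imread(str(path)).astype(float)
    mask = np.isfinite(arr)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PhaseMap(values=np.where(mask, arr, 0.0), mask=mask,
                    pixel_pitch=float(meta.get("pixel_pitch_m", 1.0)))
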