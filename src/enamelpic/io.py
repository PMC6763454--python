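"""File formats: orientation TIFFs, polarization stacks, RGB renderings, CSV/JSON.

PIC maps travel as multi-page TIFF: two 32-bit float planes (c', gamma in
degrees) plus an 8-bit mask plane, with pixel size recorded in the TIFF
description tag.  Polarization stacks are multi-page 32-bit float TIFFs
with a JSON sidecar carrying the polarization angles and calibration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from .dichroism import DichroismParams, PICMap, PolarizationStack
from .mechanics import ElasticTensor, StressStrainCurve

__all__ = [
    "write_pic_map",
    "read_pic_map",
    "write_stack",
    "read_stack",
    "write_rgb",
    "read_rgb",
    "read_stress_strain_csv",
    "write_tensor_json",
    "read_tensor_json",
]


def write_pic_map(path: str | Path, pic: PICMap) -> None:
    """Write a PIC map as a 3-page TIFF: c' (f32), gamma (f32), mask (u8)."""
    path = Path(path)
    desc = json.dumps({"pixel_size_nm": pic.pixel_size_nm, "planes": ["c_prime_deg", "gamma_deg", "mask"]})
    with tifffile.TiffWriter(path) as tw:
        tw.write(pic.c_prime_deg.astype(np.float32), description=desc)
        tw.write(pic.gamma_deg.astype(np.float32))
        tw.write(pic.mask.astype(np.uint8))


def read_pic_map(path: str | Path) -> PICMap:
    with tifffile.TiffFile(path) as tf:
        cp = tf.pages[0].asarray().astype(float)
        g = tf.pages[1].asarray().astype(float)
        mask = tf.pages[2].asarray().astype(bool)
        pixel_size = 60.0
        desc = tf.pages[0].description
        if desc:
            try:
                pixel_size = float(json.loads(desc).get("pixel_size_nm", 60.0))
            except (ValueError, AttributeError):
                pass
    return PICMap(cp, g, mask, pixel_size)


def write_stack(path: str | Path, stack: PolarizationStack, params: DichroismParams | None = None) -> None:
    """Write ratio images as multi-page f32 TIFF + JSON sidecar (angles, A, B)."""
    path = Path(path)
    tifffile.imwrite(path, stack.ratio_images.astype(np.float32))
    meta = {
        "angles_deg": list(map(float, stack.angles_deg)),
        "pixel_size_nm": stack.pixel_size_nm,
    }
    if params is not None:
        meta["baseline_a"] = params.baseline_a
        meta["amplitude_b"] = params.amplitude_b
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> tuple[PolarizationStack, dict]:
    path = Path(path)
    images = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    stack = PolarizationStack(np.asarray(meta["angles_deg"]), images, meta.get("pixel_size_nm", 60.0))
    return stack, meta


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_rgb(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    return np.asarray(arr)[..., :3]


def read_stress_strain_csv(path: str | Path, gauge_length_nm: float) -> StressStrainCurve:
    """Read a two-column CSV (strain, stress_gpa; header row required)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    strain_col = next(c for c in cols if c.startswith("strain"))
    stress_col = next(c for c in cols if c.startswith("stress"))
    return StressStrainCurve(df[strain_col].to_numpy(), df[stress_col].to_numpy(), gauge_length_nm)


def write_tensor_json(path: str | Path, t: ElasticTensor) -> None:
    Path(path).write_text(json.dumps({"units": "GPa", "voigt_matrix": t.matrix.tolist()}, indent=1))


def read_tensor_json(path: str | Path) -> ElasticTensor:
    data = json.loads(Path(path).read_text())
    return ElasticTensor(np.asarray(data["voigt_matrix"], dtype=float))
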