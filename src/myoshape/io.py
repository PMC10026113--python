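"""Reading and writing images, masks and scene sidecars.

Images are grayscale TIFF/PNG (8- or 16-bit, or float TIFF); intensities
are normalised to [0, 1] on read.  Label masks travel as 16-bit PNG or
TIFF.  A synthetic scene is stored as ``<stem>.tif`` (image),
``<stem>_mask.png`` (truth labels) and ``<stem>_truth.json``
(per-object parameters).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic import SyntheticScene

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_scene",
    "read_scene",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an RGB read of a grayscale image
        arr = arr.mean(axis=2)
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    out = np.round(arr * 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path).astype(np.int32)
    return np.asarray(iio.imread(path)).astype(np.int32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    out = np.asarray(mask).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def write_scene(scene: SyntheticScene, outdir: str | Path, stem: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image(outdir / f"{stem}.tif", scene.image)
    write_mask(outdir / f"{stem}_mask.png", scene.truth_mask)
    (outdir / f"{stem}_truth.json").write_text(
        json.dumps(scene.truth_params.to_dict(orient="records"), indent=1)
    )


def read_scene(outdir: str | Path, stem: str) -> SyntheticScene:
    outdir = Path(outdir)
    image = read_image(outdir / f"{stem}.tif")
    mask = read_mask(outdir / f"{stem}_mask.png")
    params = pd.DataFrame(
        json.loads((outdir / f"{stem}_truth.json").read_text())
    )
    return SyntheticScene(image=image, truth_mask=mask, truth_params=params)
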