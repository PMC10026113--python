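"""Fluorescence and colour-stain quantification.

Covers the three stained readouts of the profiling study:

* **Fusion index** — from a nucleus label mask (DAPI) and a binary
  myosin-heavy-chain mask: the fraction of all nuclei lying in MHC+
  connected components that contain two or more nuclei (myotubes).
* **Per-nucleus CD56** — cytoplasmic marker intensity measured over a
  distance-limited cell region grown from each nucleus, with the
  centroid distance to the nearest other nucleus.
* **Senescence fraction** — the fraction of cells stained blue in a
  colour beta-galactosidase field, detected in an HSV hue window.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage import color, filters

from .stats import CorrelationReport, rank_correlation

__all__ = [
    "FusionResult",
    "fusion_index",
    "mean_fusion_index",
    "identify_nuclei",
    "cd56_per_nucleus",
    "cd56_distance_correlation",
    "bgal_positive_fraction",
]

_EIGHT = np.ones((3, 3), dtype=bool)

#: Minimum number of MHC-positive cells/myotubes for a well-powered
#: fusion-index estimate; below this the result carries a quality flag.
MIN_MHC_CELLS = 500


@dataclasses.dataclass
class FusionResult:
    """Fusion index of one image."""

    n_nuclei_total: int
    n_nuclei_in_myotubes: int
    fusion_index: float
    n_mhc_cells: int
    low_count_flag: bool


def fusion_index(nuclei: np.ndarray, mhc_mask: np.ndarray) -> FusionResult:
    """Fraction of nuclei inside multinucleated MHC-positive regions.

    A nucleus belongs to the MHC+ 8-connected component containing its
    centroid; components holding two or more nuclei count as myotubes.
    """
    nuclei = np.asarray(nuclei)
    mhc_mask = np.asarray(mhc_mask).astype(bool)
    if nuclei.shape != mhc_mask.shape:
        raise ValueError("nucleus and MHC masks must share dimensions")
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("no nuclei in mask")
    comp, n_comp = ndi.label(mhc_mask, structure=_EIGHT)
    centroids = ndi.center_of_mass(nuclei > 0, nuclei, ids)
    per_comp = np.zeros(n_comp + 1, dtype=int)
    for r, c in centroids:
        comp_id = comp[int(round(r)), int(round(c))]
        per_comp[comp_id] += 1
    in_myotubes = int(per_comp[1:][per_comp[1:] >= 2].sum())
    total = len(ids)
    return FusionResult(
        n_nuclei_total=total,
        n_nuclei_in_myotubes=in_myotubes,
        fusion_index=in_myotubes / total,
        n_mhc_cells=int(n_comp),
        low_count_flag=n_comp < MIN_MHC_CELLS,
    )


def mean_fusion_index(results: Sequence[FusionResult | float]) -> float:
    """Unweighted mean of per-image fusion indices (centre + cardinal fields)."""
    if len(results) < 1:
        raise ValueError("at least one image is required")
    values = [
        r.fusion_index if isinstance(r, FusionResult) else float(r)
        for r in results
    ]
    return float(np.mean(values))


def identify_nuclei(blue: np.ndarray, min_diameter: float = 6.0) -> np.ndarray:
    """Segment nuclei from the DAPI channel (Otsu + size filter)."""
    blue = np.asarray(blue, dtype=float)
    t = filters.threshold_otsu(blue)
    labels, n = ndi.label(blue > t, structure=_EIGHT)
    if n == 0:
        return labels
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(np.sqrt(4.0 * counts / np.pi) >= min_diameter) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def cd56_per_nucleus(
    nuclei: np.ndarray,
    red: np.ndarray,
    max_expansion: float = 30.0,
    support: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean marker intensity per nucleus over a grown cell region.

    Every pixel within ``max_expansion`` of a nucleus is assigned to its
    nearest nucleus (distance-limited expansion); the mean red-channel
    intensity over that region is the cell's marker level.  ``support``
    optionally restricts the grown regions to a cytoplasm mask (e.g. the
    stained-cell foreground) so background pixels do not dilute the mean.
    Also reports each nucleus's centroid distance to its nearest
    neighbour (NaN for a single nucleus).
    """
    nuclei = np.asarray(nuclei)
    red = np.asarray(red, dtype=float)
    if nuclei.shape != red.shape:
        raise ValueError("nucleus mask and intensity image must share dimensions")
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("no nuclei in mask")
    dist, (ir, ic) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
    owner = nuclei[ir, ic]
    owner = np.where(dist <= max_expansion, owner, 0)
    if support is not None:
        support = np.asarray(support).astype(bool)
        if support.shape != nuclei.shape:
            raise ValueError("support mask must share dimensions")
        owner = np.where(support | (nuclei > 0), owner, 0)
    means = ndi.mean(red, owner, ids)
    cents = np.array(ndi.center_of_mass(nuclei > 0, nuclei, ids), dtype=float)
    if len(ids) > 1:
        tree = cKDTree(cents)
        dd, _ = tree.query(cents, k=2)
        closest = dd[:, 1]
    else:
        closest = [math.nan]
    return pd.DataFrame(
        {
            "nucleus": ids.astype(int),
            "centroid_row": cents[:, 0],
            "centroid_col": cents[:, 1],
            "cd56_mean_intensity": np.asarray(means, dtype=float),
            "closest_nucleus_distance": np.asarray(closest, dtype=float),
        }
    )


def cd56_distance_correlation(records: pd.DataFrame) -> CorrelationReport:
    """Rank correlation of per-nucleus marker intensity vs neighbour distance."""
    return rank_correlation(
        records["cd56_mean_intensity"], records["closest_nucleus_distance"]
    )


def bgal_positive_fraction(
    image: np.ndarray,
    cells: np.ndarray,
    hue_window: tuple[float, float] = (180.0, 260.0),
    min_saturation: float = 0.15,
    min_blue_pixel_fraction: float = 0.10,
) -> float:
    """Fraction of cells stained blue in a colour senescence field.

    A cell is positive when at least ``min_blue_pixel_fraction`` of its
    pixels fall in the blue hue window (degrees) at sufficient
    saturation.
    """
    image = np.asarray(image, dtype=float)
    cells = np.asarray(cells)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    if image.shape[:2] != cells.shape:
        raise ValueError("image and cell mask must share dimensions")
    ids = np.unique(cells)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("no cells in mask")
    hsv = color.rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    blue = (
        (hue >= hue_window[0]) & (hue <= hue_window[1])
        & (hsv[..., 1] >= min_saturation)
    )
    frac_blue = ndi.mean(blue.astype(float), cells, ids)
    positives = int((np.asarray(frac_blue) >= min_blue_pixel_fraction).sum())
    return positives / len(ids)
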