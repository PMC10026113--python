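"""Synthetic microscopy scenes, plates and donor cohorts with ground truth.

Every downstream stage of the package (segmentation, shape profiling,
tracking, fluorescence assays, plate assays, cohort statistics) is
exercised against data produced here, where the truth is known exactly:

* ``make_cell_scene`` renders non-overlapping spindle-shaped cells
  (rotated ellipses, bright interior with a thin dark halo just outside)
  on a textured brightfield-like background, with a pixel-exact truth
  label mask.
* ``make_timelapse`` moves those cells with a persistent-identity random
  walk, emulating frames taken every few minutes.
* ``make_fluorescence_scene`` builds a three-channel stained scene
  (blue nuclei, green sarcomeric-myosin cytoplasm, red CD56) in which the
  ground-truth fusion index is exact by construction.
* ``make_bgal_scene`` renders senescence-stained colour fields with a
  known fraction of blue-positive cells.
* ``make_od_plate`` produces a 96-well-style optical-density table for an
  esterase-activity assay: a 1:3 serial-dilution standard series from
  1000 mU/mL, duplicate sample wells and a blank.
* ``make_cohort`` draws donor tables (age, sex, BMI, lifestyle flags,
  marker percentages, fusion index) with a linear age-to-fusion-index
  coupling whose strength is a parameter.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .shapes import DESCRIPTORS

__all__ = [
    "SyntheticScene",
    "FluorescenceScene",
    "BGalScene",
    "ODPlate",
    "CohortSpec",
    "PlacementError",
    "make_cell_scene",
    "make_timelapse",
    "make_fluorescence_scene",
    "make_bgal_scene",
    "make_od_plate",
    "make_cohort",
    "attach_shape_summaries",
    "SCREEN_DESCRIPTORS",
]

#: Descriptor columns used by the cohort-level correlation screen: the
#: image-level area total plus every per-object descriptor mean.
SCREEN_DESCRIPTORS: tuple[str, ...] = ("total_area_occupied",) + DESCRIPTORS


class PlacementError(RuntimeError):
    """Raised when the requested object density cannot be placed."""


@dataclasses.dataclass
class SyntheticScene:
    """A rendered frame plus its pixel-exact ground truth.

    ``truth_params`` has one row per object: label, centroid (row, col),
    semi-axes and orientation (radians, measured from the row axis).
    """

    image: np.ndarray
    truth_mask: np.ndarray
    truth_params: pd.DataFrame


@dataclasses.dataclass
class FluorescenceScene:
    """Three-channel stained scene with exact nucleus/myotube truth.

    ``truth_nuclei`` has one row per nucleus: id, centroid, the id of the
    myotube it belongs to (-1 for nuclei in mononucleated cells), its cell
    id and the true mean CD56 intensity of that cell.
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    truth_nuclei: pd.DataFrame
    truth_fusion_index: float
    truth_cd56: dict[int, float]


@dataclasses.dataclass
class BGalScene:
    """Colour senescence-stain field with known positive cells."""

    image: np.ndarray  # H x W x 3, float in [0, 1]
    cells: np.ndarray  # label mask
    positive_labels: tuple[int, ...]
    truth_fraction: float


@dataclasses.dataclass
class ODPlate:
    """Optical densities for a serial-dilution standard series and samples."""

    standard_concs: np.ndarray  # mU/mL, descending
    standard_ods: np.ndarray
    sample_ods: np.ndarray  # (n_samples, 2) duplicate wells
    blank_od: float
    truth_concs: np.ndarray


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic donor cohort.

    The fusion index is ``clip(fi_intercept + fi_age_slope * age + eps, 0, 1)``
    with ``eps ~ N(0, noise_sd)``; ages are uniform over ``age_range``
    (the study cohort spans 16-92 years with no stated distribution).
    """

    n_donors: int
    age_range: tuple[float, float] = (16.0, 92.0)
    fi_intercept: float = 0.8
    fi_age_slope: float = -0.005
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 3:
            raise ValueError("n_donors must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# brightfield scenes

# Cell geometry: length ~34 px at elongation 3 gives a ~11 px width, inside
# the working range of the 7-px line-enhancement element (ridges must stay
# narrower than the element's 15 px diameter to be amplified).
_CELL_SEMI_MAJOR = 17.0
_HALO_WIDTH = 1.5  # px of dark shading just outside the cell
_INTERIOR = 0.88
_HALO = 0.22
_BACKGROUND = 0.50


def _ellipse_mask(shape, centre, a, b, theta) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=float),
        np.arange(shape[1], dtype=float),
        indexing="ij",
    )
    dr, dc = rr - centre[0], cc - centre[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _render_scene(size, params, noise_sd, rng) -> SyntheticScene:
    image = np.full((size, size), _BACKGROUND)
    if noise_sd > 0:
        texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 3.0)
        sd = texture.std()
        if sd > 0:
            image += noise_sd * texture / sd
    mask = np.zeros((size, size), dtype=np.int32)
    for row in params.itertuples():
        body = _ellipse_mask(
            (size, size), (row.centroid_row, row.centroid_col),
            row.semi_major, row.semi_minor, row.orientation,
        )
        halo = _ellipse_mask(
            (size, size), (row.centroid_row, row.centroid_col),
            row.semi_major + _HALO_WIDTH, row.semi_minor + _HALO_WIDTH,
            row.orientation,
        ) & ~body
        image[halo] = _HALO
        image[body] = _INTERIOR
        mask[body] = row.label
    return SyntheticScene(
        image=np.clip(image, 0.0, 1.0), truth_mask=mask, truth_params=params
    )


def _place_cells(n_cells, size, elongation, rng, semi_major=_CELL_SEMI_MAJOR):
    """Rejection-sample non-overlapping centres; bounded retries."""
    records = []
    placed: list[tuple[float, float, float]] = []  # row, col, clearance radius
    attempts = 0
    max_attempts = 600 * max(n_cells, 1)
    while len(records) < n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(records)} of {n_cells} cells at size {size}; "
                "density infeasible"
            )
        attempts += 1
        a = semi_major * rng.uniform(0.9, 1.1)
        b = a / elongation
        margin = a + _HALO_WIDTH + 4
        r = rng.uniform(margin, size - margin)
        c = rng.uniform(margin, size - margin)
        clearance = a + _HALO_WIDTH + 6  # keeps gaps > merge distance
        if any(
            math.hypot(r - pr, c - pc) < clearance + pcl
            for pr, pc, pcl in placed
        ):
            continue
        placed.append((r, c, clearance))
        records.append(
            dict(
                label=len(records) + 1,
                centroid_row=r,
                centroid_col=c,
                semi_major=a,
                semi_minor=b,
                orientation=rng.uniform(0.0, math.pi),
            )
        )
    columns = [
        "label", "centroid_row", "centroid_col",
        "semi_major", "semi_minor", "orientation",
    ]
    return pd.DataFrame(records, columns=columns)


def make_cell_scene(
    n_cells: int,
    size: int = 960,
    elongation: float = 3.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> SyntheticScene:
    """Render spindle cells on a textured background with exact truth.

    Cells are rotated ellipses with a bright interior and a thin dark halo
    just outside the truth boundary (the optical shadow at the cell edge);
    the truth mask covers exactly the bright interior.  Deterministic for
    a fixed seed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    params = _place_cells(n_cells, size, elongation, rng)
    return _render_scene(size, params, noise_sd, rng)


def make_timelapse(
    scene: SyntheticScene,
    n_frames: int,
    step_px: float,
    seed: int = 0,
) -> list[SyntheticScene]:
    """Random-walk time-lapse with persistent cell identities.

    Each cell takes one step per frame with Rayleigh-distributed length of
    mean ``step_px`` and uniform direction; moves that would leave the
    field or collide with another cell are re-drawn (the cell stays put if
    no valid move is found).  Truth labels are preserved across frames.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    size = scene.image.shape[0]
    frames = [scene]
    params = scene.truth_params.copy()
    scale = step_px / math.sqrt(math.pi / 2.0) if step_px > 0 else 0.0
    for _ in range(1, n_frames):
        new = params.copy()
        for i in new.index:
            a = new.at[i, "semi_major"]
            margin = a + _HALO_WIDTH + 4
            clearance = 2 * (a + _HALO_WIDTH + 6)
            for _try in range(20):
                length = rng.rayleigh(scale) if scale > 0 else 0.0
                angle = rng.uniform(0.0, 2.0 * math.pi)
                r = params.at[i, "centroid_row"] + length * math.cos(angle)
                c = params.at[i, "centroid_col"] + length * math.sin(angle)
                if not (margin <= r <= size - margin and margin <= c <= size - margin):
                    continue
                ok = all(
                    math.hypot(r - new.at[j, "centroid_row"], c - new.at[j, "centroid_col"])
                    >= clearance
                    for j in new.index
                    if j != i
                )
                if ok:
                    new.at[i, "centroid_row"] = r
                    new.at[i, "centroid_col"] = c
                    break
        params = new
        frames.append(_render_scene(size, params, 0.02, rng))
    return frames


# ---------------------------------------------------------------------------
# fluorescence scenes

_NUCLEUS_RADIUS = 5.0
_NUCLEUS_SPACING = 22.0  # along a myotube axis


def make_fluorescence_scene(
    n_nuclei: int,
    fusion_fraction: float,
    seed: int = 0,
    size: int = 512,
) -> FluorescenceScene:
    """Stained scene whose fusion index is exact by construction.

    A fraction ``fusion_fraction`` of the nuclei is grouped into
    multinucleated green (myosin-positive) myotubes of 2-4 nuclei; the
    rest sit in mononucleated green cells.  The red channel carries a
    uniform per-cell CD56 intensity recorded as truth.
    """
    if not 0.0 <= fusion_fraction <= 1.0:
        raise ValueError("fusion_fraction must lie in [0, 1]")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    rng = np.random.default_rng(seed)

    n_fused = int(round(fusion_fraction * n_nuclei))
    if n_fused == 1:
        n_fused = 2 if fusion_fraction >= 0.5 else 0
    groups: list[int] = []
    remaining = n_fused
    while remaining > 0:
        g = int(rng.integers(2, 5))
        g = min(g, remaining)
        if remaining - g == 1:
            g += 1
        groups.append(g)
        remaining -= g

    blue = np.full((size, size), 0.04)
    green = np.full((size, size), 0.04)
    red = np.full((size, size), 0.02)

    # placed regions as capsules: (endpoint, endpoint, radius)
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    nuclei_rows = []
    truth_cd56: dict[int, float] = {}
    cell_id = 0
    nuc_id = 0

    def _segment_distance(p0, p1, q0, q1) -> float:
        """Minimum distance between 2-D segments p0-p1 and q0-q1."""

        def point_seg(p, a, b):
            ab = b - a
            denom = float(ab @ ab)
            t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
            return float(np.hypot(*(p - (a + t * ab))))

        if _segments_cross(p0, p1, q0, q1):
            return 0.0
        return min(
            point_seg(p0, q0, q1), point_seg(p1, q0, q1),
            point_seg(q0, p0, p1), point_seg(q1, p0, p1),
        )

    def _segments_cross(p0, p1, q0, q1) -> bool:
        def orient(a, b, c):
            return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

        d1, d2 = orient(q0, q1, p0), orient(q0, q1, p1)
        d3, d4 = orient(p0, p1, q0), orient(p0, p1, q1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    def _place(half_len: float, radius: float, theta: float):
        """Place a capsule of given half-length/radius/orientation."""
        seg_half = max(half_len - radius, 0.0)
        margin = half_len + 4
        axis = np.array([math.cos(theta), math.sin(theta)])
        for _ in range(4000):
            centre = rng.uniform(margin, size - margin, 2)
            p0, p1 = centre - seg_half * axis, centre + seg_half * axis
            if all(
                _segment_distance(p0, p1, q0, q1) >= radius + qr + 8
                for q0, q1, qr in placed
            ):
                placed.append((p0, p1, radius))
                return centre
        raise PlacementError(
            f"could not place a region of extent {half_len:.0f} px at size {size}"
        )

    def _paint_cell(mask: np.ndarray, intensity: float) -> None:
        green[mask] = 0.72
        red[mask] = intensity

    def _add_nucleus(r: float, c: float, myotube: int, cell: int, cd56: float):
        nonlocal nuc_id
        nuc_id += 1
        disk = _ellipse_mask(
            (size, size), (r, c), _NUCLEUS_RADIUS, _NUCLEUS_RADIUS, 0.0
        )
        blue[disk] = 0.92
        nuclei_rows.append(
            dict(
                nucleus=nuc_id, centroid_row=r, centroid_col=c,
                myotube_id=myotube, cell_id=cell, cd56=cd56,
            )
        )

    for g in groups:  # multinucleated myotubes
        cell_id += 1
        half_len = (g - 1) * _NUCLEUS_SPACING / 2.0 + 3 * _NUCLEUS_RADIUS + 4
        theta = rng.uniform(0.0, math.pi)
        r, c = _place(half_len, 13.0, theta)
        body = _ellipse_mask((size, size), (r, c), half_len, 13.0, theta)
        cd56 = rng.uniform(0.3, 0.9)
        truth_cd56[cell_id] = cd56
        _paint_cell(body, cd56)
        for k in range(g):
            offset = (k - (g - 1) / 2.0) * _NUCLEUS_SPACING
            _add_nucleus(
                r + offset * math.cos(theta), c + offset * math.sin(theta),
                myotube=cell_id, cell=cell_id, cd56=cd56,
            )

    for _ in range(n_nuclei - n_fused):  # mononucleated cells
        cell_id += 1
        theta = rng.uniform(0.0, math.pi)
        r, c = _place(15.0, 10.0, theta)
        body = _ellipse_mask((size, size), (r, c), 15.0, 10.0, theta)
        cd56 = rng.uniform(0.3, 0.9)
        truth_cd56[cell_id] = cd56
        _paint_cell(body, cd56)
        _add_nucleus(r, c, myotube=-1, cell=cell_id, cd56=cd56)

    truth = pd.DataFrame(
        nuclei_rows,
        columns=["nucleus", "centroid_row", "centroid_col",
                 "myotube_id", "cell_id", "cd56"],
    )
    fi = float((truth["myotube_id"] >= 0).sum()) / n_nuclei if n_nuclei else 0.0
    return FluorescenceScene(
        blue=blue, green=green, red=red,
        truth_nuclei=truth, truth_fusion_index=fi, truth_cd56=truth_cd56,
    )


# ---------------------------------------------------------------------------
# senescence stain scenes

_BLUE_RGB = (0.20, 0.33, 0.60)  # HSV hue ~ 220 deg, saturation ~ 0.66
_GREY_RGB = (0.55, 0.55, 0.55)


def make_bgal_scene(
    n_cells: int,
    positive_fraction: float,
    seed: int = 0,
    size: int = 384,
) -> BGalScene:
    """Colour field with a known fraction of blue (senescent) cells."""
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = int(round(positive_fraction * n_cells))
    params = _place_cells(n_cells, size, 1.8, rng, semi_major=14.0)
    image = np.full((size, size, 3), 0.85)
    cells = np.zeros((size, size), dtype=np.int32)
    positive = tuple(
        int(x) + 1 for x in rng.choice(n_cells, size=n_pos, replace=False)
    )
    for row in params.itertuples():
        body = _ellipse_mask(
            (size, size), (row.centroid_row, row.centroid_col),
            row.semi_major, row.semi_minor, row.orientation,
        )
        colour = _BLUE_RGB if row.label in positive else _GREY_RGB
        image[body] = colour
        cells[body] = row.label
    return BGalScene(
        image=image, cells=cells, positive_labels=positive,
        truth_fraction=n_pos / n_cells,
    )


# ---------------------------------------------------------------------------
# plate assays

def _default_curve(conc: np.ndarray) -> np.ndarray:
    """Saturating OD response, ~1.4 OD at the 1000 mU/mL top standard."""
    conc = np.asarray(conc, dtype=float)
    return 1.9 * conc / (conc + 350.0)


def make_od_plate(
    sample_concs: Sequence[float],
    curve_shape: Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ODPlate:
    """OD table for a 1:3 serial-dilution standard series plus samples.

    Standards run from 1000 mU/mL down through seven 1:3 dilutions
    (1000 .. 1.37); each sample is read in duplicate wells.  Every OD is
    ``blank + curve_shape(conc) + noise``.
    """
    from .plates import serial_dilution

    sample_concs = np.asarray(sample_concs, dtype=float)
    if (sample_concs < 0).any():
        raise ValueError("sample concentrations must be >= 0")
    curve = curve_shape or _default_curve
    rng = np.random.default_rng(seed)
    blank = 0.045
    standards = serial_dilution(1000.0, 3.0, 7)
    standard_ods = blank + curve(standards) + rng.normal(0.0, noise_sd, 7)
    sample_ods = (
        blank
        + curve(sample_concs)[:, None]
        + rng.normal(0.0, noise_sd, (len(sample_concs), 2))
    )
    return ODPlate(
        standard_concs=standards,
        standard_ods=standard_ods,
        sample_ods=sample_ods,
        blank_od=blank,
        truth_concs=sample_concs,
    )


# ---------------------------------------------------------------------------
# donor cohorts

def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a donor table with a linear age-to-fusion-index coupling.

    The senescence fraction rises with age, the progenitor-marker
    percentage (CD34) falls with the fusion index, and the remaining
    columns are drawn around realistic cohort-scale values.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_donors
    age = rng.uniform(*spec.age_range, n)
    fi = np.clip(
        spec.fi_intercept + spec.fi_age_slope * age + rng.normal(0, spec.noise_sd, n),
        0.0, 1.0,
    )
    bgal = np.clip(0.02 + 0.004 * (age - spec.age_range[0]) + rng.normal(0, 0.05, n), 0, 1)
    cd34 = np.clip(25.0 - 25.0 * fi + rng.normal(0, 5.0, n), 0.0, 100.0)
    return pd.DataFrame(
        {
            "Donor": [f"D{i + 1:02d}" for i in range(n)],
            "Age": age,
            "Sex": rng.choice(["M", "F"], size=n, p=[5 / 14, 9 / 14]),
            "Ethnicity": ["Caucasian"] * n,
            "Tissue": rng.choice(["AR", "VL"], size=n, p=[11 / 14, 3 / 14]),
            "Diabetes": np.zeros(n, dtype=int),
            "BMI": np.clip(rng.normal(30.9, 7.3, n), 16.0, 60.0),
            "Tobacco": rng.binomial(1, 8 / 14, n),
            "Alcohol": rng.binomial(1, 5 / 14, n),
            "NonIVDrug": rng.binomial(1, 5 / 14, n),
            "FusionIndex": fi,
            "CD56": np.clip(rng.normal(55.8, 16.8, n), 0.0, 100.0),
            "CD34": cd34,
            "CD90": np.clip(rng.normal(94.9, 8.3, n), 0.0, 100.0),
            "BGal": bgal,
            "AChE": np.clip(rng.normal(10.1, 5.8, n), 0.1, None),
        }
    )


def attach_shape_summaries(
    cohort: pd.DataFrame,
    coupling: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    passages: Sequence[str] = ("P2", "P3"),
    timepoints: Sequence[str] = ("12h", "24h"),
) -> pd.DataFrame:
    """Add per-donor image-summary descriptor columns to a cohort table.

    Each column ``{descriptor}_{passage}_{timepoint}`` is
    ``coupling[descriptor] * z(FusionIndex) + N(0, noise_sd)``: zero
    coupling gives descriptors independent of the fusion index (the null
    of the correlation screen), a negative coupling ties a descriptor
    negatively to myogenicity.
    """
    coupling = coupling or {}
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    fi = out["FusionIndex"].to_numpy(dtype=float)
    sd = fi.std()
    z = (fi - fi.mean()) / sd if sd > 0 else np.zeros_like(fi)
    for desc in SCREEN_DESCRIPTORS:
        for p in passages:
            for tp in timepoints:
                out[f"{desc}_{p}_{tp}"] = coupling.get(desc, 0.0) * z + rng.normal(
                    0.0, noise_sd, len(out)
                )
    return out
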