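"""Orchestration: run the profile-then-correlate analysis end to end.

``run_profile`` turns a directory of time-lapse frames into a per-object
descriptor table and a per-image summary table; ``run_correlate`` joins
per-image summaries with a donor table and emits the descriptor-vs-
fusion-index screen plus the demographics summary; ``run_simulate``
writes a complete synthetic dataset (scenes, truth, cohort) to disk.
All runs are deterministic for fixed inputs, configuration and seed, and
the per-frame object count is logged for every image.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .segmentation import SegmentationConfig, segment_pipeline
from .shapes import profile_objects, summarize_image
from .stats import demographics_summary, descriptor_fusion_screen
from .synthetic import CohortSpec, make_cell_scene, make_cohort, make_timelapse
from .tracking import TrackingConfig

log = logging.getLogger("myoshape")

SCHEMA_VERSION = 1
_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclasses.dataclass
class RunConfig:
    """Run-wide configuration: stage parameters, timepoints, seed, output."""

    segmentation: SegmentationConfig = dataclasses.field(
        default_factory=SegmentationConfig
    )
    tracking: TrackingConfig = dataclasses.field(default_factory=TrackingConfig)
    timepoints_h: tuple[float, ...] = (12.0, 24.0)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.timepoints_h:
            raise ValueError("at least one timepoint is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("schema_version", None)
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        trk = TrackingConfig(**raw.pop("tracking", {}))
        if "timepoints_h" in raw:
            raw["timepoints_h"] = tuple(raw["timepoints_h"])
        return cls(segmentation=seg, tracking=trk, **raw)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "segmentation": dataclasses.asdict(self.segmentation),
            "tracking": dataclasses.asdict(self.tracking),
            "timepoints_h": list(self.timepoints_h),
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _frame_paths(image_dir: Path) -> list[Path]:
    return sorted(
        p for p in image_dir.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES and not p.stem.endswith("_mask")
    )


def run_profile(
    image_dir: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and profile every frame in a directory.

    Returns (per-object table, per-image table) and, when ``out_dir`` is
    given, writes them as ``per_object.csv`` / ``per_image.csv``.
    Unreadable frames are reported per file and skipped; the run raises at
    the end if any frame failed.
    """
    config = config or RunConfig()
    image_dir = Path(image_dir)
    paths = _frame_paths(image_dir)
    if not paths:
        raise FileNotFoundError(f"no frames found in {image_dir}")
    per_object = []
    per_image = []
    failures = []
    for frame_idx, path in enumerate(paths):
        try:
            image = mio.read_image(path)
            labels = segment_pipeline(image, config.segmentation)
            profiles = profile_objects(labels)
            summary = summarize_image(labels, profiles)
        except Exception as exc:  # noqa: BLE001 - per-file error reporting
            log.error("frame %s failed: %s", path.name, exc)
            failures.append((path.name, str(exc)))
            continue
        log.info("frame %s: %d objects", path.name, summary.n_objects)
        profiles.insert(0, "frame", frame_idx)
        profiles.insert(1, "file", path.name)
        per_object.append(profiles)
        row = {
            "frame": frame_idx,
            "file": path.name,
            "n_objects": summary.n_objects,
            "total_area_occupied": summary.total_area_occupied,
        }
        row.update({f"{k}_mean": v for k, v in summary.means.items()})
        row.update({f"{k}_sd": v for k, v in summary.sds.items()})
        per_image.append(row)
    obj_df = (
        pd.concat(per_object, ignore_index=True) if per_object else pd.DataFrame()
    )
    img_df = pd.DataFrame(per_image)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        obj_df.to_csv(out_dir / "per_object.csv", index=False)
        img_df.to_csv(out_dir / "per_image.csv", index=False)
    if failures:
        raise RuntimeError(f"{len(failures)} frame(s) failed: {failures}")
    return obj_df, img_df


def run_correlate(
    donor_table: str | Path | pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Demographics summary plus the descriptor-vs-fusion-index screen.

    ``donor_table`` must carry the donor demographic columns and may carry
    descriptor summary columns named ``{descriptor}_{passage}_{timepoint}``.
    Results are returned as a dict and optionally written as CSV + JSON.
    """
    config = config or RunConfig()
    cohort = (
        donor_table
        if isinstance(donor_table, pd.DataFrame)
        else pd.read_csv(donor_table)
    )
    if "FusionIndex" not in cohort.columns:
        raise ValueError("donor table lacks a FusionIndex column")
    demo = demographics_summary(cohort)
    screen, missing = descriptor_fusion_screen(cohort)
    report = {
        "schema_version": SCHEMA_VERSION,
        "demographics": demo,
        "screen": screen.to_dict(orient="records"),
        "missing_descriptor_columns": missing,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        screen.to_csv(out_dir / "descriptor_screen.csv", index=False)
        (out_dir / "correlate_report.json").write_text(
            json.dumps(report, indent=1, default=float)
        )
    return report


def run_simulate(
    out_dir: str | Path,
    n_cells: int = 20,
    size: int = 960,
    n_frames: int = 1,
    step_px: float = 3.0,
    n_donors: int = 14,
    seed: int = 0,
    force: bool = False,
) -> dict:
    """Write a synthetic dataset (scenes + truth + cohort) to disk."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    scene = make_cell_scene(n_cells=n_cells, size=size, seed=seed)
    frames = (
        make_timelapse(scene, n_frames, step_px, seed=seed)
        if n_frames > 1
        else [scene]
    )
    for i, fr in enumerate(frames):
        mio.write_scene(fr, out_dir, f"frame_{i:04d}")
    cohort = make_cohort(CohortSpec(n_donors=n_donors, seed=seed))
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_cells": n_cells,
        "size": size,
        "n_frames": n_frames,
        "step_px": step_px,
        "n_donors": n_donors,
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
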