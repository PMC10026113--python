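"""Frame-to-frame object linking and growth timing for time-lapse imaging.

Objects are linked between consecutive frames by greedy nearest-neighbour
matching with a hard distance gate; a track is the per-frame sequence of
(frame, label, centroid) of one cell identity.  ``track_distance``
reports cumulative path length within a time window (the motility
readout), and ``doubling_time`` the interpolated time at which the
per-frame object count first reaches twice its initial value (the
overlap-free proxy for culture growth).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = [
    "TrackingConfig",
    "Track",
    "FrameMatching",
    "link_frames",
    "build_tracks",
    "track_distance",
    "doubling_time",
]


@dataclasses.dataclass
class TrackingConfig:
    """Linking parameters in pixels/minutes.

    ``avg_diameter`` documents the expected cell size for the matching
    step (45 px); the greedy matcher itself gates only on
    ``max_match_distance`` (70 px).  ``frame_interval`` is the imaging
    cadence in minutes.
    """

    avg_diameter: float = 45.0
    max_match_distance: float = 70.0
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        if self.max_match_distance <= 0:
            raise ValueError("max_match_distance must be > 0")


@dataclasses.dataclass
class FrameMatching:
    """Result of linking one frame pair (indices into the centroid lists)."""

    matches: list[tuple[int, int]]
    unmatched_prev: list[int]
    unmatched_next: list[int]


@dataclasses.dataclass
class Track:
    """One object identity across frames."""

    track_id: int
    frames: list[int]
    labels: list[int]
    centroids: list[tuple[float, float]]


def link_frames(
    prev: np.ndarray, next_: np.ndarray, config: TrackingConfig | None = None
) -> FrameMatching:
    """Greedy one-to-one matching by ascending displacement.

    Candidate pairs within the distance gate are taken in order of
    increasing distance (ties broken by lower (row, col) of the previous
    then next centroid); each object participates in at most one match.
    """
    config = config or TrackingConfig()
    prev = np.asarray(prev, dtype=float).reshape(-1, 2)
    next_ = np.asarray(next_, dtype=float).reshape(-1, 2)
    if len(prev) == 0 or len(next_) == 0:
        return FrameMatching([], list(range(len(prev))), list(range(len(next_))))
    diff = prev[:, None, :] - next_[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    candidates = [
        (dist[i, j], prev[i, 0], prev[i, 1], next_[j, 0], next_[j, 1], i, j)
        for i in range(len(prev))
        for j in range(len(next_))
        if dist[i, j] <= config.max_match_distance
    ]
    candidates.sort()
    used_p: set[int] = set()
    used_n: set[int] = set()
    matches = []
    for _, _, _, _, _, i, j in candidates:
        if i in used_p or j in used_n:
            continue
        matches.append((i, j))
        used_p.add(i)
        used_n.add(j)
    return FrameMatching(
        matches=matches,
        unmatched_prev=[i for i in range(len(prev)) if i not in used_p],
        unmatched_next=[j for j in range(len(next_)) if j not in used_n],
    )


def build_tracks(
    centroids_per_frame: list[np.ndarray],
    config: TrackingConfig | None = None,
    labels_per_frame: list[np.ndarray] | None = None,
) -> list[Track]:
    """Chain frame-pair matchings into tracks over a whole sequence.

    Unmatched next-frame objects start new tracks; unmatched previous-frame
    objects end theirs.
    """
    config = config or TrackingConfig()
    if labels_per_frame is None:
        labels_per_frame = [
            np.arange(1, len(np.asarray(c).reshape(-1, 2)) + 1)
            for c in centroids_per_frame
        ]
    tracks: list[Track] = []
    active: dict[int, Track] = {}  # index in current frame -> track
    for f, cents in enumerate(centroids_per_frame):
        cents = np.asarray(cents, dtype=float).reshape(-1, 2)
        labs = np.asarray(labels_per_frame[f])
        if f == 0:
            for i, (rc, lab) in enumerate(zip(cents, labs)):
                t = Track(len(tracks) + 1, [0], [int(lab)], [tuple(rc)])
                tracks.append(t)
                active[i] = t
            prev_cents = cents
            continue
        matching = link_frames(prev_cents, cents, config)
        new_active: dict[int, Track] = {}
        for i, j in matching.matches:
            t = active[i]
            t.frames.append(f)
            t.labels.append(int(labs[j]))
            t.centroids.append(tuple(cents[j]))
            new_active[j] = t
        for j in matching.unmatched_next:
            t = Track(len(tracks) + 1, [f], [int(labs[j])], [tuple(cents[j])])
            tracks.append(t)
            new_active[j] = t
        active = new_active
        prev_cents = cents
    return tracks


@dataclasses.dataclass
class WindowDistances:
    """Per-track path lengths over a time window, plus the image mean."""

    per_track: pd.Series
    mean: float
    defined: bool


def track_distance(
    tracks: list[Track],
    window_start: float,
    window_len: float = 2.0,
    frame_interval: float = 5.0,
) -> WindowDistances:
    """Cumulative path length per track within [start, start + len] hours.

    The window is inclusive of both endpoints, so a 2-h window at 5-min
    frames spans 25 frames and 24 displacement steps.  Only tracks alive
    for the whole window contribute; the image-level value is their mean.
    With no such track the result is flagged undefined (NaN mean).
    """
    f0 = int(math.ceil(window_start * 60.0 / frame_interval))
    f1 = int(math.floor((window_start + window_len) * 60.0 / frame_interval))
    wanted = list(range(f0, f1 + 1))
    lengths = {}
    for t in tracks:
        index = {f: k for k, f in enumerate(t.frames)}
        if not all(f in index for f in wanted):
            continue
        pts = np.array([t.centroids[index[f]] for f in wanted])
        steps = np.diff(pts, axis=0)
        lengths[t.track_id] = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    per_track = pd.Series(lengths, dtype=float)
    defined = len(per_track) > 0
    return WindowDistances(
        per_track=per_track,
        mean=float(per_track.mean()) if defined else math.nan,
        defined=defined,
    )


def doubling_time(
    object_counts: np.ndarray, frame_interval: float = 5.0
) -> float:
    """Hours until the per-frame object count doubles its initial value.

    Linearly interpolated between the last frame below and the first frame
    at/above twice the first frame's count; NaN when never reached.
    """
    counts = np.asarray(object_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count series")
    target = 2.0 * counts[0]
    if counts[0] <= 0:
        raise ValueError("first-frame count must be positive")
    reached = np.flatnonzero(counts >= target)
    if reached.size == 0:
        return math.nan
    i = int(reached[0])
    if i == 0:
        frame = 0.0
    else:
        c0, c1 = counts[i - 1], counts[i]
        frame = i - 1 + (target - c0) / (c1 - c0)
    return float(frame * frame_interval / 60.0)
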