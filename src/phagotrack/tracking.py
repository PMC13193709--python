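"""Frame-to-frame linking of detections into cell trajectories.

Linking follows the nearest-neighbor particle-linking scheme standard in
time-lapse microscopy: for each consecutive frame pair, active track ends
are matched one-to-one to new detections by minimizing total squared
displacement (optimal bipartite assignment), with matches beyond a maximum
per-frame displacement forbidden.  Unmatched detections seed new tracks;
tracks unmatched for more than ``memory_frames`` frames are closed.
Trajectories shorter than a minimum number of frames are discarded by
:func:`filter_tracks` (default minimum: five frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .segment import Detection

__all__ = ["Track", "LinkConfig", "link", "filter_tracks", "tracks_to_frame"]

UNKNOWN = "unknown"


@dataclass
class Track:
    """One cell's time-ordered detections, with an optional class label."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    class_label: str = UNKNOWN

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("detection frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def positions_px(self) -> np.ndarray:
        """(n, 2) array of (y, x) centroids in pixels."""
        return np.array([d.centroid_yx_px for d in self.detections], dtype=float)


@dataclass(frozen=True)
class LinkConfig:
    max_disp_px_per_frame: float = 10.0
    memory_frames: int = 0
    min_track_len_frames: int = 5

    def __post_init__(self) -> None:
        if self.max_disp_px_per_frame <= 0:
            raise ValueError("max_disp_px_per_frame must be positive")
        if self.memory_frames < 0:
            raise ValueError("memory_frames must be nonnegative")
        if self.min_track_len_frames < 1:
            raise ValueError("min_track_len_frames must be >= 1")


def _assign(ends_yx: np.ndarray, new_yx: np.ndarray, max_disp: float):
    """Gated min-total-squared-distance one-to-one assignment.

    Returns (pairs, unmatched_ends, unmatched_new); pairs are (end_idx,
    new_idx).  Implemented as a rectangular Hungarian assignment with a
    large penalty on pairs beyond ``max_disp``; such pairs are dropped from
    the solution afterwards, which yields the minimum-cost assignment among
    those respecting the gate.
    """
    n_e, n_d = len(ends_yx), len(new_yx)
    if n_e == 0 or n_d == 0:
        return [], list(range(n_e)), list(range(n_d))
    d2 = (
        (ends_yx[:, None, 0] - new_yx[None, :, 0]) ** 2
        + (ends_yx[:, None, 1] - new_yx[None, :, 1]) ** 2
    )
    gate = max_disp**2
    big = 4.0 * gate * max(n_e, n_d) + 1.0
    cost = np.where(d2 <= gate, d2, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if d2[r, c] <= gate]
    matched_e = {r for r, _ in pairs}
    matched_d = {c for _, c in pairs}
    return (
        pairs,
        [i for i in range(n_e) if i not in matched_e],
        [j for j in range(n_d) if j not in matched_d],
    )


def link(
    detections_by_frame: dict[int, list[Detection]], cfg: LinkConfig
) -> list[Track]:
    """Link detections across frames into tracks.

    ``detections_by_frame`` maps frame index to that frame's detections.
    Every input detection appears in exactly one output track.  Empty input
    yields an empty list.  Tracks are returned ordered by track_id
    (creation order: frame, then detection index).
    """
    frames = sorted(detections_by_frame)
    tracks: list[Track] = []
    active: list[int] = []  # indices into tracks
    for f in frames:
        dets = detections_by_frame[f]
        # close tracks that have been silent too long
        still = []
        for ti in active:
            last = tracks[ti].detections[-1].frame
            if f - last <= cfg.memory_frames + 1:
                still.append(ti)
        active = still
        ends = np.array(
            [tracks[ti].detections[-1].centroid_yx_px for ti in active], dtype=float
        ).reshape(-1, 2)
        new = np.array([d.centroid_yx_px for d in dets], dtype=float).reshape(-1, 2)
        pairs, _, unmatched_new = _assign(ends, new, cfg.max_disp_px_per_frame)
        next_active = []
        for r, c in sorted(pairs):
            tracks[active[r]].detections.append(dets[c])
            next_active.append(active[r])
        # ends that stay open via memory
        matched_e = {r for r, _ in pairs}
        for i, ti in enumerate(active):
            if i not in matched_e:
                next_active.append(ti)
        for j in unmatched_new:
            ti = len(tracks)
            tracks.append(Track(track_id=ti, detections=[dets[j]]))
            next_active.append(ti)
        active = sorted(next_active)
    return tracks


def filter_tracks(tracks: list[Track], min_len_frames: int = 5) -> list[Track]:
    """Keep tracks with at least ``min_len_frames`` detections (inclusive).

    Track length is counted as the number of detections; gap frames do not
    count.  The default of five frames keeps a 5-detection track.
    """
    return [t for t in tracks if len(t) >= min_len_frames]


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into a tidy table (one row per detection)."""
    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": d.frame,
                    "y_px": d.centroid_yx_px[0],
                    "x_px": d.centroid_yx_px[1],
                    "area_px2": d.area_px2,
                    "eccentricity": d.eccentricity,
                    "solidity": d.solidity,
                    "equivalent_diameter_px": d.equivalent_diameter_px,
                    "perimeter_px": d.perimeter_px,
                    "label": d.label,
                    "class_label": t.class_label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "frame",
            "y_px",
            "x_px",
            "area_px2",
            "eccentricity",
            "solidity",
            "equivalent_diameter_px",
            "perimeter_px",
            "label",
            "class_label",
        ],
    )


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Rebuild :class:`Track` objects from a tidy detection table."""
    tracks = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        dets = [
            Detection(
                frame=int(r.frame),
                label=int(getattr(r, "label", 0) or 0),
                centroid_yx_px=(float(r.y_px), float(r.x_px)),
                area_px2=float(r.area_px2),
                eccentricity=float(getattr(r, "eccentricity", 0.0)),
                solidity=float(getattr(r, "solidity", 1.0)),
                equivalent_diameter_px=float(
                    getattr(r, "equivalent_diameter_px", 0.0)
                ),
                perimeter_px=float(getattr(r, "perimeter_px", 0.0)),
            )
            for r in grp.itertuples()
        ]
        label = UNKNOWN
        if "class_label" in grp.columns:
            label = str(grp["class_label"].iloc[0])
        elif "class" in grp.columns:
            label = str(grp["class"].iloc[0])
        tracks.append(Track(track_id=int(tid), detections=dets, class_label=label))
    return tracks
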