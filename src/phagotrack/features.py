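"""Per-track morphology and motility descriptors.

Each trajectory is summarized by a 15-dimensional feature vector: five
morphological track-averages (area, its variability, eccentricity, solidity,
equivalent diameter) and ten motility terms (duration, path length, net
displacement, straightness, mean/max/sd of step speed, mean turning angle,
arrest coefficient, displacement rate).  The vector is defined by name and
serialized in a fixed order, so classifiers can rely on a stable layout.

Conventions
-----------
* Step speed = step distance / step time; with gaps, step time spans the
  frame gap.
* straightness = net displacement / path length (0 when the path length is
  0), hence always in [0, 1].
* Turning angles are measured between consecutive nonzero step vectors, in
  degrees in [0, 180]; the mean is 0 when fewer than two such steps exist.
* arrest coefficient = fraction of steps slower than ``arrest_speed_um_per_min``
  (default 2 um/min, a conventional cutoff separating arrested from motile
  myeloid cells).
* A single-detection track has all motility entries 0 and morphology from
  its one detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = ["FEATURE_NAMES", "TrackFeatures", "extract_features", "features_table"]

FEATURE_NAMES: tuple[str, ...] = (
    "mean_area_um2",
    "sd_area_um2",
    "mean_eccentricity",
    "mean_solidity",
    "mean_equivalent_diameter_um",
    "duration_frames",
    "path_length_um",
    "net_displacement_um",
    "straightness",
    "mean_speed_um_per_min",
    "max_step_speed_um_per_min",
    "sd_step_speed_um_per_min",
    "mean_turning_angle_deg",
    "arrest_coefficient",
    "displacement_rate_um_per_min",
)


@dataclass(frozen=True)
class TrackFeatures:
    """The 15-entry named descriptor vector for one track."""

    mean_area_um2: float
    sd_area_um2: float
    mean_eccentricity: float
    mean_solidity: float
    mean_equivalent_diameter_um: float
    duration_frames: float
    path_length_um: float
    net_displacement_um: float
    straightness: float
    mean_speed_um_per_min: float
    max_step_speed_um_per_min: float
    sd_step_speed_um_per_min: float
    mean_turning_angle_deg: float
    arrest_coefficient: float
    displacement_rate_um_per_min: float

    def to_array(self) -> np.ndarray:
        """Serialize in the fixed :data:`FEATURE_NAMES` order."""
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def __post_init__(self) -> None:
        vec = self.to_array()
        if not np.all(np.isfinite(vec)):
            raise ValueError("all features must be finite")


def extract_features(
    track: Track,
    pixel_size_um: float,
    frame_interval_s: float,
    arrest_speed_um_per_min: float = 2.0,
) -> TrackFeatures:
    """Compute the 15-dimensional descriptor vector of one track."""
    if len(track) == 0:
        raise ValueError("cannot featurize an empty track")
    areas = np.array([d.area_px2 for d in track.detections]) * pixel_size_um**2
    eccs = np.array([d.eccentricity for d in track.detections])
    sols = np.array([d.solidity for d in track.detections])
    eqds = (
        np.array([d.equivalent_diameter_px for d in track.detections]) * pixel_size_um
    )
    frames = np.array(track.frames, dtype=float)
    pos_um = track.positions_px * pixel_size_um

    duration = frames[-1] - frames[0] + 1.0
    morph = dict(
        mean_area_um2=float(areas.mean()),
        sd_area_um2=float(areas.std()),
        mean_eccentricity=float(eccs.mean()),
        mean_solidity=float(sols.mean()),
        mean_equivalent_diameter_um=float(eqds.mean()),
        duration_frames=float(duration),
    )
    if len(track) < 2:
        return TrackFeatures(
            **morph,
            path_length_um=0.0,
            net_displacement_um=0.0,
            straightness=0.0,
            mean_speed_um_per_min=0.0,
            max_step_speed_um_per_min=0.0,
            sd_step_speed_um_per_min=0.0,
            mean_turning_angle_deg=0.0,
            arrest_coefficient=0.0,
            displacement_rate_um_per_min=0.0,
        )

    steps = np.diff(pos_um, axis=0)
    step_dist = np.hypot(steps[:, 0], steps[:, 1])
    step_time_min = np.diff(frames) * frame_interval_s / 60.0
    speeds = step_dist / step_time_min

    path = float(step_dist.sum())
    net = float(np.hypot(*(pos_um[-1] - pos_um[0])))
    straightness = net / path if path > 0 else 0.0

    nz = steps[step_dist > 0]
    if len(nz) >= 2:
        a, b = nz[:-1], nz[1:]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        mean_turn = float(angles.mean())
    else:
        mean_turn = 0.0

    duration_min = (frames[-1] - frames[0]) * frame_interval_s / 60.0
    return TrackFeatures(
        **morph,
        path_length_um=path,
        net_displacement_um=net,
        straightness=float(min(straightness, 1.0)),
        mean_speed_um_per_min=float(speeds.mean()),
        max_step_speed_um_per_min=float(speeds.max()),
        sd_step_speed_um_per_min=float(speeds.std()),
        mean_turning_angle_deg=mean_turn,
        arrest_coefficient=float(np.mean(speeds < arrest_speed_um_per_min)),
        displacement_rate_um_per_min=float(net / duration_min)
        if duration_min > 0
        else 0.0,
    )


def features_table(
    tracks: list[Track],
    pixel_size_um: float,
    frame_interval_s: float,
    arrest_speed_um_per_min: float = 2.0,
) -> pd.DataFrame:
    """One row per track: track_id + the 15 named feature columns."""
    rows = []
    for t in tracks:
        f = extract_features(
            t, pixel_size_um, frame_interval_s, arrest_speed_um_per_min
        )
        row = {"track_id": t.track_id}
        row.update({n: getattr(f, n) for n in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["track_id", *FEATURE_NAMES])
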