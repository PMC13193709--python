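"""Spatial rules for still-image (histology) phenotyping.

Three operations used to phenotype macrophages in stained tissue sections:

* :func:`double_positive_count` — the proximity rule: a marker-A cell (e.g.
  IBA1+) counts as double-positive when its nearest marker-B cell (e.g.
  CD169+) lies within 5.0 um, boundary inclusive.  Distances are Euclidean,
  centroid to centroid.
* :func:`inside_outside_ratio` — partition points against a region polygon
  (e.g. the tumor outline); boundary points count as inside.
* :func:`masked_object_count` — count labeled objects whose centroid falls
  in a binary region mask (e.g. tumor-cell objects inside macrophage
  surfaces).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from skimage import measure

__all__ = [
    "double_positive_count",
    "inside_outside_ratio",
    "masked_object_count",
    "layer_densities",
]


def double_positive_count(
    points_A: np.ndarray, points_B: np.ndarray, max_dist_um: float = 5.0
) -> tuple[int, np.ndarray]:
    """Count A-points with a B-neighbor within ``max_dist_um`` (inclusive).

    ``points_A`` and ``points_B`` are (n, 2) arrays of (x, y) positions in
    um.  Returns the count and a boolean flag per A-point.  An empty B set
    gives count 0.
    """
    A = np.asarray(points_A, dtype=float).reshape(-1, 2)
    B = np.asarray(points_B, dtype=float).reshape(-1, 2)
    if max_dist_um < 0:
        raise ValueError("max_dist_um must be nonnegative")
    if A.shape[0] == 0:
        return 0, np.zeros(0, dtype=bool)
    if B.shape[0] == 0:
        return 0, np.zeros(A.shape[0], dtype=bool)
    dist, _ = cKDTree(B).query(A, k=1)
    flags = dist <= max_dist_um
    return int(flags.sum()), flags


def inside_outside_ratio(
    points: np.ndarray, region_xy_um: np.ndarray
) -> tuple[int, int, float]:
    """Partition points against a simple polygon; boundary counts inside.

    Returns (n_inside, n_outside, ratio_inside) with
    ratio_inside = n_inside / n_points.  Zero points → ratio is NaN
    (undefined, flagged rather than silently 0).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    poly = Polygon(np.asarray(region_xy_um, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise ValueError("region must be a simple (non-self-intersecting) polygon")
    inside = sum(poly.covers(Point(x, y)) for x, y in pts)
    n = pts.shape[0]
    ratio = inside / n if n > 0 else float("nan")
    return int(inside), int(n - inside), float(ratio)


def masked_object_count(
    objects_mask: np.ndarray,
    region_mask: np.ndarray,
    mode: str = "centroid",
) -> int:
    """Count labeled objects lying inside a binary region.

    ``mode="centroid"`` (default) counts an object when its centroid pixel
    (nearest integer) lies in the region; ``mode="any-pixel"`` counts it
    when any of its pixels does.  An empty region gives 0.
    """
    objects = np.asarray(objects_mask)
    region = np.asarray(region_mask, dtype=bool)
    if objects.shape != region.shape:
        raise ValueError("object and region masks must have the same shape")
    if mode not in ("centroid", "any-pixel"):
        raise ValueError("mode must be 'centroid' or 'any-pixel'")
    count = 0
    for rp in measure.regionprops(objects.astype(np.int64)):
        if mode == "centroid":
            r = int(round(rp.centroid[0]))
            c = int(round(rp.centroid[1]))
            r = min(max(r, 0), region.shape[0] - 1)
            c = min(max(c, 0), region.shape[1] - 1)
            count += bool(region[r, c])
        else:
            rr, cc = np.nonzero(objects == rp.label)
            count += bool(region[rr, cc].any())
    return count


def layer_densities(
    points: pd.DataFrame, roi_areas_mm2: dict[str, float]
) -> pd.DataFrame:
    """Per-layer point counts and densities per mm^2 of ROI area.

    ``points`` needs a ``layer`` column; ``roi_areas_mm2`` maps layer name
    to its ROI area.  Layers without an area get NaN density.
    """
    counts = points.groupby("layer").size()
    rows = []
    for layer, n in counts.items():
        area = roi_areas_mm2.get(str(layer))
        rows.append(
            {
                "layer": layer,
                "count": int(n),
                "density_per_mm2": n / area if area else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["layer", "count", "density_per_mm2"])
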