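"""Baseline per-frame segmentation of the myeloid channel.

A deterministic, parameter-light segmenter: threshold (Otsu by default),
morphological opening with a radius-1 disk, hole filling, connected-component
labeling, and a minimum-area filter.  Externally produced label masks (e.g.
from a learned segmentation model) can be imported instead and fed to the
same downstream tracking/feature code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from scipy import ndimage

__all__ = ["Detection", "segment_frame", "segment_movie", "regionprops", "import_masks"]


@dataclass(frozen=True)
class Detection:
    """One segmented cell in one frame.

    Coordinates are 0-based (row=y, col=x) with pixel centers at integers.
    """

    frame: int
    label: int
    centroid_yx_px: tuple[float, float]
    area_px2: float
    eccentricity: float
    solidity: float
    equivalent_diameter_px: float
    perimeter_px: float


def segment_frame(
    image: np.ndarray,
    min_area_px2: float = 10.0,
    threshold_method: str | float = "otsu",
) -> np.ndarray:
    """Segment one 2D frame into a label mask (0 = background).

    ``threshold_method`` is either ``"otsu"`` or a fixed numeric threshold.
    A constant image under the automatic threshold yields an empty mask
    rather than an error.  Deterministic: the same input always yields the
    same mask.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("segment_frame expects a 2D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        if np.ptp(image) == 0:
            return np.zeros(image.shape, dtype=np.int32)
        thresh = threshold_otsu(image)
    else:
        thresh = float(threshold_method)
    fg = image > thresh
    fg = morphology.opening(fg, morphology.disk(1))
    fg = ndimage.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=1)
    if min_area_px2 > 0:
        counts = np.bincount(labels.ravel())
        too_small = np.flatnonzero(counts < min_area_px2)
        labels[np.isin(labels, too_small[too_small > 0])] = 0
        labels = measure.label(labels > 0, connectivity=1)
    return labels.astype(np.int32)


def segment_movie(
    stack: np.ndarray,
    min_area_px2: float = 10.0,
    threshold_method: str | float = "otsu",
) -> np.ndarray:
    """Apply :func:`segment_frame` to every frame of a (T, Y, X) stack."""
    return np.stack(
        [segment_frame(frame, min_area_px2, threshold_method) for frame in stack]
    )


def regionprops(
    mask: np.ndarray, frame: int = 0, intensity: np.ndarray | None = None
) -> list[Detection]:
    """Measure one :class:`Detection` per positive label of a mask.

    Centroids are unweighted pixel centroids regardless of ``intensity``
    (the intensity image is accepted for future weighted measures but not
    used for the centroid).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("regionprops expects a 2D label mask")
    out = []
    for rp in measure.regionprops(mask.astype(np.int64)):
        out.append(
            Detection(
                frame=frame,
                label=int(rp.label),
                centroid_yx_px=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px2=float(rp.area),
                eccentricity=float(rp.eccentricity),
                solidity=float(rp.solidity),
                equivalent_diameter_px=float(rp.equivalent_diameter_area),
                perimeter_px=float(rp.perimeter),
            )
        )
    return out


def import_masks(masks: np.ndarray, movie_shape: tuple[int, int, int]) -> np.ndarray:
    """Validate externally produced label masks against a movie's shape.

    ``masks`` must be an integer (T, Y, X) stack matching ``movie_shape``
    (same axis convention as the segmenter's output).
    """
    masks = np.asarray(masks)
    if masks.shape != tuple(movie_shape):
        raise ValueError(
            f"mask stack shape {masks.shape} does not match movie shape "
            f"{tuple(movie_shape)}"
        )
    if not np.issubdtype(masks.dtype, np.integer):
        raise ValueError("label masks must be integer-valued")
    if masks.min() < 0:
        raise ValueError("labels must be nonnegative")
    return masks.astype(np.int32)
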