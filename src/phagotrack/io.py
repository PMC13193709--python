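"""Reading and writing the pipeline's on-disk formats.

Movies travel as OME-TIFF with TCYX axes and pixel-size / frame-interval
metadata; label masks as plain integer TIFF stacks; tracks, detections and
features as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import Movie

__all__ = [
    "write_movie",
    "read_movie",
    "write_label_masks",
    "read_label_masks",
    "write_tracks_csv",
    "read_tracks_csv",
]


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as OME-TIFF (TCYX) with physical metadata."""
    tifffile.imwrite(
        str(path),
        movie.data,
        ome=True,
        metadata={
            "axes": "TCYX",
            "PhysicalSizeX": movie.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": movie.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": movie.frame_interval_s,
            "TimeIncrementUnit": "s",
            "Channel": {"Name": list(movie.channels)},
        },
    )


def read_movie(
    path: str | Path,
    channels: tuple[str, ...] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> Movie:
    """Read a TCYX OME-TIFF movie; explicit arguments override metadata."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta_channels: tuple[str, ...] | None = None
        px = dt = None
        if tf.ome_metadata:
            import re

            ome = tf.ome_metadata
            m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', ome)
            px = float(m.group(1)) if m else None
            m = re.search(r'TimeIncrement="([\d.eE+-]+)"', ome)
            dt = float(m.group(1)) if m else None
            names = re.findall(r'Channel[^>]*Name="([^"]+)"', ome)
            if names:
                meta_channels = tuple(names)
    if data.ndim == 3:  # single channel
        data = data[:, None]
    if data.ndim != 4:
        raise ValueError(f"expected a TCYX movie, got shape {data.shape}")
    chans = channels or meta_channels or tuple(
        f"ch{i}" for i in range(data.shape[1])
    )
    return Movie(
        data=np.asarray(data, dtype=np.float32),
        channels=chans,
        pixel_size_um=pixel_size_um or px or 1.0,
        frame_interval_s=frame_interval_s or dt or 55.0,
    )


def write_label_masks(masks: np.ndarray, path: str | Path) -> None:
    """Write a (T, Y, X) label stack as integer TIFF."""
    tifffile.imwrite(
        str(path), np.asarray(masks, dtype=np.int32), photometric="minisblack"
    )


def read_label_masks(path: str | Path) -> np.ndarray:
    masks = tifffile.imread(str(path))
    if masks.ndim == 2:
        masks = masks[None]
    return masks.astype(np.int32)


def write_tracks_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report_json(report: dict, path: str | Path) -> None:
    """Write an analysis report (e.g. a group comparison) as JSON."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
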