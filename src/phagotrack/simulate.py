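"""Seeded synthetic-data generators for the imaging pipeline.

The generators emulate the statistical structure of intravital two-photon
time-lapse data of myeloid cells in tumor-bearing skin: two myeloid
populations that differ in size and motility (tissue-resident macrophages are
large and slow; neutrophils/monocytes are small and fast), a spatially
clustered tumor channel, per-frame additive pixel noise, and frame intervals
in the 50-60 s range.  A separate generator produces histology-style point
patterns with marker co-positivity for the proximity rules.

Everything is deterministic given the spec and seed, and every movie comes
with exact ground truth (per-frame label masks, a track table, and class
labels) so segmentation, tracking, feature extraction and classification can
be validated against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "MovieSpec",
    "Movie",
    "GroundTruth",
    "generate_movie",
    "generate_track_table",
    "generate_histology_points",
    "MACROPHAGE",
    "NEUTROPHIL_MONOCYTE",
]

MACROPHAGE = "macrophage"
NEUTROPHIL_MONOCYTE = "neutrophil_monocyte"

#: Anatomical skin-layer vocabulary used for histology point labels.
LAYERS = ("epidermis", "dermis", "DWAT", "panniculus", "adventitia", "NA")


@dataclass(frozen=True)
class PopulationSpec:
    """One myeloid population: size and motility distributions.

    Parameters
    ----------
    name
        Class label attached to every cell of this population.
    mean_area_um2, sd_area_um2
        Gaussian cell-area distribution (um^2); per-cell draw, fixed over time.
    mean_speed_um_per_min, speed_sd
        Gaussian per-step speed distribution (um/min), truncated at 0.
    straightness_bias
        Directional persistence in [0, 1]: 0 gives an uncorrelated random
        walk, 1 a perfectly straight path.  Implemented as a wrapped-normal
        turn-angle with sd = pi * (1 - straightness_bias).
    n_cells
        Number of cells of this population per movie.
    """

    name: str
    mean_area_um2: float
    sd_area_um2: float = 0.0
    mean_speed_um_per_min: float = 1.0
    speed_sd: float = 0.0
    straightness_bias: float = 0.5
    n_cells: int = 1

    def __post_init__(self) -> None:
        if self.mean_area_um2 <= 0:
            raise ValueError("mean_area_um2 must be positive")
        if self.sd_area_um2 < 0 or self.speed_sd < 0:
            raise ValueError("sd values must be nonnegative")
        if self.mean_speed_um_per_min < 0:
            raise ValueError("mean_speed_um_per_min must be nonnegative")
        if not 0.0 <= self.straightness_bias <= 1.0:
            raise ValueError("straightness_bias must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def default_populations() -> list[PopulationSpec]:
    """Default macrophage and neutrophil/monocyte populations.

    Values are typical of skin intravital imaging: tissue-resident
    macrophages are large (~120 um^2 in a single z-slice) and sessile to
    slowly motile (~1 um/min), while neutrophils/monocytes are small
    (~40 um^2) and patrol rapidly (~8 um/min) with straighter paths.
    """
    return [
        PopulationSpec(
            name=MACROPHAGE,
            mean_area_um2=120.0,
            sd_area_um2=15.0,
            mean_speed_um_per_min=1.0,
            speed_sd=0.4,
            straightness_bias=0.3,
            n_cells=15,
        ),
        PopulationSpec(
            name=NEUTROPHIL_MONOCYTE,
            mean_area_um2=40.0,
            sd_area_um2=8.0,
            mean_speed_um_per_min=8.0,
            speed_sd=2.0,
            straightness_bias=0.7,
            n_cells=15,
        ),
    ]


@dataclass(frozen=True)
class MovieSpec:
    """Full description of a synthetic single-z two-channel movie.

    ``tumor_blobs`` is a list of ``((y_um, x_um), radius_um, intensity)``
    disks summed into the tumor channel; all blob centers must lie within
    the frame.  ``min_separation_um`` is the enforced gap between cell
    boundaries (cells exclude each other sterically), which also keeps the
    ground truth unambiguous: no two cells ever share a pixel.
    """

    n_frames: int = 30
    frame_interval_s: float = 55.0
    pixel_size_um: float = 1.0
    height_px: int = 256
    width_px: int = 256
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    tumor_blobs: list[tuple[tuple[float, float], float, float]] = field(
        default_factory=list
    )
    noise_sd: float = 0.02
    cell_intensity: float = 1.0
    min_separation_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 50.0 <= self.frame_interval_s <= 60.0:
            raise ValueError("frame_interval_s must lie in [50, 60] s")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("frame dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        h_um = self.height_px * self.pixel_size_um
        w_um = self.width_px * self.pixel_size_um
        for (cy, cx), radius, _ in self.tumor_blobs:
            if radius <= 0:
                raise ValueError("tumor blob radius must be positive")
            if not (0 <= cy <= h_um and 0 <= cx <= w_um):
                raise ValueError(
                    f"tumor blob center ({cy}, {cx}) um lies outside the "
                    f"{h_um} x {w_um} um frame"
                )


@dataclass
class Movie:
    """In-memory movie: ``data`` has axes (T, C, Y, X), float32."""

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, Y, X) stack for one named channel."""
        return self.data[:, self.channels.index(name)]


@dataclass
class GroundTruth:
    """Exact per-frame truth for a generated movie.

    ``label_masks`` has shape (T, Y, X); label ``i`` in any frame is cell
    index ``i - 1``.  ``tracks`` has one row per (cell, visible frame) with
    columns track_id, frame, y_px, x_px, area_px2, class.  Centroids and
    areas are measured from the rendered (clipped) pixels, so the table is
    consistent with the masks by construction.
    """

    label_masks: np.ndarray
    tracks: pd.DataFrame
    classes: dict[int, str]


# --------------------------------------------------------------------------
# cell-walk simulation


def _simulate_walks(spec: MovieSpec, rng: np.random.Generator):
    """Simulate persistent random walks for every cell.

    Returns per-cell arrays of center positions (um) of shape
    (n_cells, n_frames, 2), plus per-cell shape parameters and class labels.
    New direction = previous direction rotated by a wrapped-normal angle
    whose sd is pi * (1 - straightness_bias); speed is redrawn each step.
    Centers reflect off the field borders; a step that would bring two cell
    boundaries closer than ``min_separation_um`` is retried a few times and
    otherwise skipped (the cell pauses), so cells never overlap.
    """
    h_um = spec.height_px * spec.pixel_size_um
    w_um = spec.width_px * spec.pixel_size_um
    dt_min = spec.frame_interval_s / 60.0

    areas, speeds_mu, speeds_sd, turn_sd, classes = [], [], [], [], []
    for pop in spec.populations:
        for _ in range(pop.n_cells):
            a = rng.normal(pop.mean_area_um2, pop.sd_area_um2)
            areas.append(max(a, 1.0))
            speeds_mu.append(pop.mean_speed_um_per_min)
            speeds_sd.append(pop.speed_sd)
            turn_sd.append(math.pi * (1.0 - pop.straightness_bias))
            classes.append(pop.name)
    n = len(areas)
    areas = np.asarray(areas)
    axis_ratio = rng.uniform(1.0, 2.0, size=n)
    orientation = rng.uniform(0.0, math.pi, size=n)
    # semi-axes from area = pi * a * b with a/b = ratio
    semi_major = np.sqrt(areas * axis_ratio / math.pi)
    reach = semi_major  # worst-case boundary radius per cell

    def too_close(pos, i, candidate):
        lim = reach[i] + reach + spec.min_separation_um
        d = np.hypot(pos[:, 0] - candidate[0], pos[:, 1] - candidate[1])
        d[i] = np.inf
        return bool(np.any(d < lim))

    # Centers are kept at least one cell-radius from the borders (reflecting
    # walls), so cells are normally rendered whole; rendering still clips
    # any ellipse that would extend past the frame.
    lo = reach.copy()
    hi_y = h_um - reach
    hi_x = w_um - reach
    if np.any(hi_y <= lo) or np.any(hi_x <= lo):
        raise ValueError("field too small for the requested cell sizes")

    # initial non-overlapping placement by rejection sampling
    pos = np.empty((n, 2))
    for i in range(n):
        for _ in range(10_000):
            cand = np.array(
                [rng.uniform(lo[i], hi_y[i]), rng.uniform(lo[i], hi_x[i])]
            )
            lim = reach[i] + reach[:i] + spec.min_separation_um
            if i == 0 or np.all(
                np.hypot(pos[:i, 0] - cand[0], pos[:i, 1] - cand[1]) >= lim
            ):
                pos[i] = cand
                break
        else:
            raise ValueError(
                "could not place all cells without overlap; reduce n_cells "
                "or cell areas, or enlarge the field"
            )

    heading = rng.uniform(0.0, 2 * math.pi, size=n)
    centers = np.empty((n, spec.n_frames, 2))
    centers[:, 0] = pos
    for t in range(1, spec.n_frames):
        for i in range(n):
            placed = False
            for _ in range(8):
                turn = rng.normal(0.0, turn_sd[i]) if turn_sd[i] > 0 else 0.0
                new_heading = heading[i] + turn
                speed = max(rng.normal(speeds_mu[i], speeds_sd[i]), 0.0)
                step = speed * dt_min
                cand = pos[i] + step * np.array(
                    [math.sin(new_heading), math.cos(new_heading)]
                )
                # reflect at the per-cell margins
                for k, hi in enumerate((hi_y[i], hi_x[i])):
                    if cand[k] < lo[i]:
                        cand[k] = 2 * lo[i] - cand[k]
                    if cand[k] > hi:
                        cand[k] = 2 * hi - cand[k]
                    cand[k] = min(max(cand[k], lo[i]), hi)
                if not too_close(pos, i, cand):
                    pos[i] = cand
                    heading[i] = new_heading
                    placed = True
                    break
            if not placed:
                pass  # cell pauses this frame
        centers[:, t] = pos
    return centers, areas, axis_ratio, orientation, np.array(classes)


def _render_ellipse(mask: np.ndarray, cy_px, cx_px, area_px2, ratio, theta, label):
    """Paint a filled ellipse of the given pixel area into ``mask``."""
    a = math.sqrt(area_px2 * ratio / math.pi)  # semi-major, px
    b = a / ratio
    h, w = mask.shape
    y0 = max(int(math.floor(cy_px - a)) - 1, 0)
    y1 = min(int(math.ceil(cy_px + a)) + 2, h)
    x0 = max(int(math.floor(cx_px - a)) - 1, 0)
    x1 = min(int(math.ceil(cx_px + a)) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy_px
    dx = xx - cx_px
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[y0:y1, x0:x1][inside] = label


def generate_movie(spec: MovieSpec) -> tuple[Movie, GroundTruth]:
    """Render a two-channel movie and its exact ground truth.

    Channels are ``("myeloid", "tumor")``.  Cells are filled ellipses of
    constant per-cell area following persistent random walks; the tumor
    channel is the sum of the spec's disk blobs.  Additive Gaussian noise of
    sd ``spec.noise_sd`` is applied independently per pixel, frame and
    channel.  The returned :class:`GroundTruth` is measured from the
    rendered label masks, so every rendered cell has exactly one
    ground-truth detection in every frame in which it is visible.
    """
    rng = np.random.default_rng(spec.seed)
    centers, areas_um2, ratio, theta, classes = _simulate_walks(spec, rng)
    n = centers.shape[0]
    px = spec.pixel_size_um

    shape = (spec.n_frames, spec.height_px, spec.width_px)
    labels = np.zeros(shape, dtype=np.int32)
    myeloid = np.zeros(shape, dtype=np.float32)
    tumor = np.zeros(shape, dtype=np.float32)

    tumor_frame = np.zeros((spec.height_px, spec.width_px), dtype=np.float32)
    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    for (cy, cx), radius, intensity in spec.tumor_blobs:
        r2 = ((yy - cy / px) ** 2 + (xx - cx / px) ** 2) * px**2
        tumor_frame[r2 <= radius**2] += intensity

    rows = []
    for t in range(spec.n_frames):
        for i in range(n):
            cy_px = centers[i, t, 0] / px
            cx_px = centers[i, t, 1] / px
            _render_ellipse(
                labels[t], cy_px, cx_px, areas_um2[i] / px**2, ratio[i], theta[i], i + 1
            )
        myeloid[t][labels[t] > 0] = spec.cell_intensity
        tumor[t] = tumor_frame
        for i in range(n):
            ys, xs = np.nonzero(labels[t] == i + 1)
            if ys.size == 0:
                continue  # clipped entirely out of frame
            rows.append(
                {
                    "track_id": i,
                    "frame": t,
                    "y_px": float(ys.mean()),
                    "x_px": float(xs.mean()),
                    "area_px2": float(ys.size),
                    "class": classes[i],
                }
            )
        if spec.noise_sd > 0:
            myeloid[t] += rng.normal(0.0, spec.noise_sd, myeloid[t].shape).astype(
                np.float32
            )
            tumor[t] += rng.normal(0.0, spec.noise_sd, tumor[t].shape).astype(
                np.float32
            )

    data = np.stack([myeloid, tumor], axis=1)
    movie = Movie(
        data=data,
        channels=("myeloid", "tumor"),
        pixel_size_um=spec.pixel_size_um,
        frame_interval_s=spec.frame_interval_s,
    )
    tracks = pd.DataFrame(
        rows, columns=["track_id", "frame", "y_px", "x_px", "area_px2", "class"]
    )
    truth = GroundTruth(
        label_masks=labels,
        tracks=tracks,
        classes={i: str(classes[i]) for i in range(n)},
    )
    return movie, truth


def generate_track_table(spec: MovieSpec) -> pd.DataFrame:
    """Simulate cell walks without rendering; return a detection table.

    Fast path for classifier-scale experiments: same motion and size model
    as :func:`generate_movie` but positions/areas are analytic (no
    rasterization, no clipping).  Columns match the ground-truth track table
    plus per-detection shape descriptors derived from the cell's ellipse.
    """
    rng = np.random.default_rng(spec.seed)
    centers, areas_um2, ratio, theta, classes = _simulate_walks(spec, rng)
    px = spec.pixel_size_um
    n = centers.shape[0]
    # eccentricity of an ellipse with axis ratio q: sqrt(1 - 1/q^2)
    ecc = np.sqrt(1.0 - 1.0 / ratio**2)
    rows = []
    for i in range(n):
        for t in range(spec.n_frames):
            rows.append(
                {
                    "track_id": i,
                    "frame": t,
                    "y_px": centers[i, t, 0] / px,
                    "x_px": centers[i, t, 1] / px,
                    "area_px2": areas_um2[i] / px**2,
                    "eccentricity": float(ecc[i]),
                    "solidity": 1.0,
                    "equivalent_diameter_px": float(
                        2.0 * math.sqrt(areas_um2[i] / math.pi) / px
                    ),
                    "perimeter_px": float(
                        2.0 * math.pi * math.sqrt(areas_um2[i] / math.pi) / px
                    ),
                    "class": classes[i],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# histology point patterns


def generate_histology_points(
    n_A: int,
    n_B: int,
    coupling_fraction: float,
    coupling_dist_um: float = 3.0,
    field_um: float = 500.0,
    seed: int = 0,
    marker_A: str = "IBA1",
    marker_B: str = "CD169",
    assign_layers: bool = False,
) -> pd.DataFrame:
    """Generate a histology-style point pattern with marker co-positivity.

    ``n_B`` marker-B points are placed uniformly in a ``field_um`` square;
    exactly ``round(coupling_fraction * n_A)`` marker-A points are placed
    within ``coupling_dist_um`` of some B point (uniform in the disk around
    a random B point, resampled until inside the field), and the remaining A
    points uniformly at random.  Returns a table with columns
    ``x_um, y_um, marker`` (and ``layer`` if requested).
    """
    if n_A < 0 or n_B < 0:
        raise ValueError("point counts must be nonnegative")
    if not 0.0 <= coupling_fraction <= 1.0:
        raise ValueError("coupling_fraction must lie in [0, 1]")
    if coupling_fraction > 0 and n_A > 0 and n_B == 0:
        raise ValueError("cannot couple A points to an empty B set")
    rng = np.random.default_rng(seed)
    b_xy = rng.uniform(0.0, field_um, size=(n_B, 2))
    n_coupled = round(coupling_fraction * n_A)
    rows = []
    for x, y in b_xy:
        rows.append({"x_um": x, "y_um": y, "marker": marker_B})
    for j in range(n_A):
        if j < n_coupled:
            anchor = b_xy[rng.integers(n_B)]
            while True:
                r = coupling_dist_um * math.sqrt(rng.uniform())
                phi = rng.uniform(0.0, 2 * math.pi)
                x = anchor[0] + r * math.cos(phi)
                y = anchor[1] + r * math.sin(phi)
                if 0.0 <= x <= field_um and 0.0 <= y <= field_um:
                    break
        else:
            x, y = rng.uniform(0.0, field_um, size=2)
        rows.append({"x_um": x, "y_um": y, "marker": marker_A})
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "marker"])
    if assign_layers:
        df["layer"] = rng.choice(LAYERS[:-1], size=len(df))
    else:
        df["layer"] = "NA"
    return df
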