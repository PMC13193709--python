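"""Shared fixtures: small rendered movies and separable track tables."""

from __future__ import annotations

import numpy as np
import pytest

import phagotrack as pt


def separable_populations(n_cells: int = 15) -> list[pt.PopulationSpec]:
    """Two myeloid populations with effectively disjoint (area, speed)
    supports: large slow macrophages vs small fast neutrophils/monocytes."""
    return [
        pt.PopulationSpec(
            name=pt.MACROPHAGE,
            mean_area_um2=120.0,
            sd_area_um2=10.0,
            mean_speed_um_per_min=1.0,
            speed_sd=0.3,
            straightness_bias=0.3,
            n_cells=n_cells,
        ),
        pt.PopulationSpec(
            name=pt.NEUTROPHIL_MONOCYTE,
            mean_area_um2=40.0,
            sd_area_um2=6.0,
            mean_speed_um_per_min=8.0,
            speed_sd=1.5,
            straightness_bias=0.7,
            n_cells=n_cells,
        ),
    ]


def linking_gate_px(spec: pt.MovieSpec) -> float:
    """Displacement gate from the known population speeds: the largest
    plausible per-frame step (mean + 4 sd) plus centroid jitter."""
    dt_min = spec.frame_interval_s / 60.0
    vmax = max(p.mean_speed_um_per_min + 4 * p.speed_sd for p in spec.populations)
    return vmax * dt_min / spec.pixel_size_um + 2.0


@pytest.fixture(scope="session")
def small_movie():
    """A noise-free 20-frame movie with 30 cells and a tumor blob."""
    spec = pt.MovieSpec(
        n_frames=20,
        height_px=160,
        width_px=160,
        seed=11,
        noise_sd=0.0,
        populations=separable_populations(15),
        tumor_blobs=[((80.0, 80.0), 40.0, 1.0)],
    )
    movie, truth = pt.generate_movie(spec)
    return spec, movie, truth


@pytest.fixture(scope="session")
def uniform_field_rng():
    return np.random.default_rng(2024)
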