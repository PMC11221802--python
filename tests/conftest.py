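"""Shared fixtures: phantom cases and pipeline reports are expensive, so
they are built once per session and shared across the suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from laflow import phantoms, pipeline
from laflow.fields import LA, OUTSIDE, RectGrid, RegionMaskSeries, VelocityFieldSeries
from laflow.timing import CardiacTiming


@lru_cache(maxsize=None)
def get_case(preset: str) -> phantoms.PhantomCase:
    return phantoms.make_phantom(preset)


@lru_cache(maxsize=None)
def get_report(preset: str):
    case = get_case(preset)
    return pipeline.analyze(case.field, case.masks, case.planes, case.timing)


@pytest.fixture(scope="session")
def case_factory():
    return get_case


@pytest.fixture(scope="session")
def report_factory():
    return get_report


def make_uniform_case(
    u=(0.1, 0.0, 0.0),
    box=(40.0, 20.0, 20.0),
    spacing=2.0,
    n_frames=4,
    cycle_length=1.0,
):
    """A rigid all-LA box with a spatially uniform steady velocity, embedded
    in a two-voxel OUTSIDE shell (thicker than the wall-tolerance band, so
    escapes register as lost); handy for advection unit tests."""
    nx, ny, nz = (int(round(b / spacing)) + 4 for b in box)
    grid = RectGrid(
        (-1.5 * spacing, -1.5 * spacing, -1.5 * spacing),
        (spacing,) * 3,
        (nx, ny, nz),
    )
    times = np.arange(n_frames) * cycle_length / n_frames
    data = np.broadcast_to(
        np.asarray(u, dtype=float), (n_frames,) + grid.shape + (3,)
    ).copy()
    X, Y, Z = grid.meshgrid()
    inside = (
        (X > 0) & (X < box[0]) & (Y > 0) & (Y < box[1]) & (Z > 0) & (Z < box[2])
    )
    labels = np.where(inside, LA, OUTSIDE).astype(np.uint8)
    labels = np.broadcast_to(labels, (n_frames,) + grid.shape).copy()
    field = VelocityFieldSeries(grid, times, data, cycle_length)
    masks = RegionMaskSeries(grid, times, labels, cycle_length)
    timing = CardiacTiming(cycle_length, t_mv_open=0.4, n_frames=n_frames)
    return field, masks, timing


def make_rotation_case(omega=2 * np.pi, half=30.0, spacing=2.0, n_frames=4):
    """Steady solid-body rotation about the z axis: u = omega * (-y, x, 0)
    in mm/s. Linear in space, so trilinear sampling is exact and any
    endpoint error is the integrator's own."""
    n = int(round(2 * half / spacing))
    grid = RectGrid((-half + spacing / 2,) * 3, (spacing,) * 3, (n, n, n))
    period = 2 * np.pi / omega

    def fn(X, Y, Z, t):
        return -omega * Y / 1000.0, omega * X / 1000.0, np.zeros_like(Z)

    times = np.arange(n_frames) * period / n_frames
    field = VelocityFieldSeries.from_function(fn, grid, times, period)
    labels = np.full((n_frames,) + grid.shape, LA, dtype=np.uint8)
    masks = RegionMaskSeries(grid, times, labels, period)
    return field, masks, period
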