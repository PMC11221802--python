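"""Particle seeding.

Two complementary strategies cover all atrial blood:

* **Volume seeding** — an isotropic Cartesian lattice (default pitch 2 mm)
  filling the LA at its end-systolic maximum, each particle representing one
  lattice cell (0.008 mL at 2 mm).
* **Pulmonary-vein seeding** — lattices on each vein interface plane
  (default pitch 1 mm), re-released every 0.025 s over one full cycle; each
  particle's represented volume is the flux through its patch cell during
  one release interval, V = A · v_norm · dt, so the released volumes sum to
  the blood volume entering the atrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, SeedingError
from .fields import LA, InterfacePlane, RegionMaskSeries, VelocityFieldSeries
from .timing import CardiacTiming


@dataclass(frozen=True)
class SeedSpec:
    """Seeding resolution parameters (mm, s)."""

    volume_spacing: float = 2.0
    plane_spacing: float = 1.0
    release_interval: float = 0.025
    anchor: tuple[float, float, float] | None = None

    def __post_init__(self):
        if min(self.volume_spacing, self.plane_spacing, self.release_interval) <= 0:
            raise ConfigError("seed spacings and release interval must be positive")

    @property
    def plane_area_per_seed(self) -> float:
        """A of the flux formula, mm² (= plane_spacing²)."""
        return self.plane_spacing**2


@dataclass
class SeedSet:
    """A batch of seeded particles."""

    origin: str  # "VOLUME" or a PV plane id
    positions: np.ndarray  # (N, 3) mm
    times: np.ndarray  # (N,) release times, s
    volumes_ml: np.ndarray  # (N,) represented volumes, mL

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def total_volume_ml(self) -> float:
        return float(self.volumes_ml.sum())

    def to_dataframe(self):
        """Tabular view (id, origin, seed_time, x, y, z, volume_mL)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "origin": self.origin,
                "seed_time_s": self.times,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
                "volume_ml": self.volumes_ml,
            }
        )


def _snapped_anchor(masks: RegionMaskSeries, la_mask: np.ndarray, spec: SeedSpec):
    """Lattice anchor: the LA centroid snapped to the mask's voxel-corner
    lattice, making seeding translation-robust yet free of boundary ties."""
    if spec.anchor is not None:
        return np.asarray(spec.anchor, dtype=float)
    g = masks.grid
    ax = g.axes()
    idx = np.argwhere(la_mask)
    centroid = np.array([ax[a][idx[:, a]].mean() for a in range(3)])
    corner0 = np.asarray(g.origin) - 0.5 * np.asarray(g.spacing)
    steps = np.round((centroid - corner0) / np.asarray(g.spacing))
    return corner0 + steps * np.asarray(g.spacing)


def seed_volume(
    masks: RegionMaskSeries, timing: CardiacTiming, spec: SeedSpec
) -> SeedSet:
    """Seed the end-systolic atrial volume on an isotropic Cartesian lattice.

    Lattice cells of pitch ``volume_spacing`` are anchored at the (snapped)
    LA centroid; a cell contributes one particle at its center when that
    center lies in the LA at ``t_mv_open``. Each particle represents the
    cell volume (spacing³, i.e. 0.008 mL at 2 mm).
    """
    t0 = timing.t_mv_open
    k = int(masks.frame_index(t0))
    la = masks.labels[k] == LA
    if not np.any(la):
        raise SeedingError("LA region empty at t_mv_open")
    anchor = _snapped_anchor(masks, la, spec)
    s = spec.volume_spacing
    ax = masks.grid.axes()
    pts_1d = []
    for a in range(3):
        lo = ax[a][0] - masks.grid.spacing[a]
        hi = ax[a][-1] + masks.grid.spacing[a]
        k_lo = int(np.floor((lo - anchor[a]) / s))
        k_hi = int(np.ceil((hi - anchor[a]) / s))
        pts_1d.append(anchor[a] + (np.arange(k_lo, k_hi) + 0.5) * s)
    X, Y, Z = np.meshgrid(*pts_1d, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = masks.grid.contains(pts) & (masks.label_at(pts, t0) == LA)
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise SeedingError(
            f"volume seeding produced no particles (spacing {s} mm larger than chamber?)"
        )
    vol = s**3 / 1000.0  # mm^3 -> mL
    return SeedSet(
        "VOLUME",
        pts,
        np.full(pts.shape[0], t0),
        np.full(pts.shape[0], vol),
    )


def seed_plane(
    plane: InterfacePlane,
    field_series: VelocityFieldSeries,
    timing: CardiacTiming,
    spec: SeedSpec,
    release_start: float | None = None,
) -> SeedSet:
    """Release flux-weighted particles from a vein interface plane.

    At each release time (every ``release_interval`` over one full cycle,
    starting by default at the beginning of ventricular systole) a lattice
    of pitch ``plane_spacing`` covers the patch; each seed represents
    V = A · v_norm · dt where v_norm is the velocity component along the
    plane normal at the seed point and release time. Seeds with
    v_norm ≤ 0 (instantaneous backflow at the vein) are not released.
    """
    if release_start is None:
        release_start = timing.t_mv_close
    T = timing.cycle_length
    n_rel = int(round(T / spec.release_interval))
    if n_rel < 1:
        raise ConfigError("release_interval longer than the cycle")
    lattice = plane.lattice(spec.plane_spacing)
    if lattice.shape[0] == 0:
        raise SeedingError(f"plane {plane.id}: patch produced no seed lattice")
    A = spec.plane_area_per_seed  # mm^2
    all_pts, all_t, all_v = [], [], []
    for i in range(n_rel):
        tau = release_start + i * spec.release_interval
        v = field_series.probe(lattice, tau)
        v_norm = v @ plane.normal  # m/s
        keep = v_norm > 0.0
        if not np.any(keep):
            continue
        # mm^2 * m/s * s = mL  (unit algebra: 1 mm^2·m = 1 mL)
        vols = A * v_norm[keep] * spec.release_interval
        all_pts.append(lattice[keep])
        all_t.append(np.full(int(keep.sum()), tau))
        all_v.append(vols)
    if not all_pts:
        return SeedSet(plane.id, np.empty((0, 3)), np.empty(0), np.empty(0))
    return SeedSet(
        plane.id,
        np.vstack(all_pts),
        np.concatenate(all_t),
        np.concatenate(all_v),
    )
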