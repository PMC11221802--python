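"""Spatial containers: rectilinear grids, velocity-field series, region-mask
series and interface planes.

Coordinates are physical millimeters everywhere; velocities are meters per
second. Velocity series interpolate trilinearly in space and linearly in time
with periodic wrap over the cycle; masks are categorical and use
nearest-frame lookup in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, LabelingError, TimingError

# Canonical region codes. PV_k maps to PV_BASE + k (k >= 1).
OUTSIDE = 0
LA = 1
LV = 2
PV_BASE = 2  # PV_1 == 3


def pv_code(k: int) -> int:
    return PV_BASE + k


def region_name(code: int) -> str:
    if code == OUTSIDE:
        return "OUTSIDE"
    if code == LA:
        return "LA"
    if code == LV:
        return "LV"
    return f"PV_{code - PV_BASE}"


def region_code(name: str) -> int:
    name = name.upper()
    if name in ("OUTSIDE", "LA", "LV"):
        return {"OUTSIDE": OUTSIDE, "LA": LA, "LV": LV}[name]
    if name.startswith("PV_"):
        return pv_code(int(name[3:]))
    raise LabelingError(f"unknown region name {name!r}")


@dataclass(frozen=True)
class RectGrid:
    """Uniform rectilinear grid of sample points (voxel centers).

    ``origin`` is the center of the first voxel; voxel faces therefore lie at
    ``origin - spacing/2 + i*spacing``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.shape):
            raise ConfigError("grid spacing must be positive and shape >= 1")

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0  # mm^3 -> mL

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def meshgrid(self):
        return np.meshgrid(*self.axes(), indexing="ij")

    def fractional_index(self, x: np.ndarray) -> np.ndarray:
        """Continuous index coordinates, clamped to the grid (nearest-inside)."""
        f = (np.atleast_2d(x) - np.asarray(self.origin)) / np.asarray(self.spacing)
        hi = np.asarray(self.shape, dtype=float) - 1.0
        return np.clip(f, 0.0, hi)

    def contains(self, x: np.ndarray) -> np.ndarray:
        """Points within the voxel-covered box (half a voxel past centers)."""
        x = np.atleast_2d(x)
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return np.all((x >= lo) & (x <= hi), axis=1)

    def nearest_index(self, x: np.ndarray) -> tuple[np.ndarray, ...]:
        f = self.fractional_index(x)
        idx = np.rint(f).astype(np.intp)
        return idx[:, 0], idx[:, 1], idx[:, 2]

    def same_geometry(self, other: "RectGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


try:  # numba accelerates the hot interpolation kernel when available
    from numba import njit as _njit

    @_njit(cache=False, fastmath=True)
    def _tri_kernel(flat, nx, ny, nz, ox, oy, oz, sx, sy, sz, pts, out):
        for p in range(pts.shape[0]):
            fx = (pts[p, 0] - ox) / sx
            fy = (pts[p, 1] - oy) / sy
            fz = (pts[p, 2] - oz) / sz
            if fx < 0.0:
                fx = 0.0
            elif fx > nx - 1:
                fx = nx - 1.0
            if fy < 0.0:
                fy = 0.0
            elif fy > ny - 1:
                fy = ny - 1.0
            if fz < 0.0:
                fz = 0.0
            elif fz > nz - 1:
                fz = nz - 1.0
            ix = int(fx)
            iy = int(fy)
            iz = int(fz)
            if ix > nx - 2:
                ix = max(nx - 2, 0)
            if iy > ny - 2:
                iy = max(ny - 2, 0)
            if iz > nz - 2:
                iz = max(nz - 2, 0)
            wx = fx - ix if nx > 1 else 0.0
            wy = fy - iy if ny > 1 else 0.0
            wz = fz - iz if nz > 1 else 0.0
            dx = ny * nz if nx > 1 else 0
            dy = nz if ny > 1 else 0
            dz = 1 if nz > 1 else 0
            b = (ix * ny + iy) * nz + iz
            for m in range(3):
                c00 = flat[b, m] * (1 - wx) + flat[b + dx, m] * wx
                c10 = flat[b + dy, m] * (1 - wx) + flat[b + dx + dy, m] * wx
                c01 = flat[b + dz, m] * (1 - wx) + flat[b + dx + dz, m] * wx
                c11 = flat[b + dy + dz, m] * (1 - wx) + flat[b + dx + dy + dz, m] * wx
                c0 = c00 * (1 - wy) + c10 * wy
                c1 = c01 * (1 - wy) + c11 * wy
                out[p, m] = c0 * (1 - wz) + c1 * wz

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _trilinear(grid: RectGrid, data: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``data`` (nx, ny, nz, m) at points (N, 3)."""
    if _HAVE_NUMBA and data.shape[-1] == 3 and x.shape[0] >= 64:
        nx, ny, nz = grid.shape
        flat = np.ascontiguousarray(data).reshape(nx * ny * nz, 3)
        pts = np.ascontiguousarray(np.atleast_2d(x))
        out = np.empty((pts.shape[0], 3))
        _tri_kernel(
            flat, nx, ny, nz,
            grid.origin[0], grid.origin[1], grid.origin[2],
            grid.spacing[0], grid.spacing[1], grid.spacing[2],
            pts, out,
        )
        return out
    f = grid.fractional_index(x)
    nx, ny, nz = grid.shape
    i0 = np.minimum(f.astype(np.intp), np.array([nx - 2, ny - 2, nz - 2])).clip(min=0)
    w = f - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    wx, wy, wz = w[:, 0:1], w[:, 1:2], w[:, 2:3]
    # Degenerate axes (size 1): weight collapses to 0.
    if nx == 1:
        wx = np.zeros_like(wx)
    if ny == 1:
        wy = np.zeros_like(wy)
    if nz == 1:
        wz = np.zeros_like(wz)
    dx = 0 if nx == 1 else ny * nz
    dy = 0 if ny == 1 else nz
    dz = 0 if nz == 1 else 1
    flat = data.reshape(nx * ny * nz, -1)
    base = (ix * ny + iy) * nz + iz
    c000 = flat[base]
    c100 = flat[base + dx]
    c010 = flat[base + dy]
    c110 = flat[base + dx + dy]
    c001 = flat[base + dz]
    c101 = flat[base + dx + dz]
    c011 = flat[base + dy + dz]
    c111 = flat[base + dx + dy + dz]
    c00 = c000 * (1 - wx) + c100 * wx
    c10 = c010 * (1 - wx) + c110 * wx
    c01 = c001 * (1 - wx) + c101 * wx
    c11 = c011 * (1 - wx) + c111 * wx
    c0 = c00 * (1 - wy) + c10 * wy
    c1 = c01 * (1 - wy) + c11 * wy
    return c0 * (1 - wz) + c1 * wz


class VelocityFieldSeries:
    """Periodic sequence of sampled 3-D velocity frames.

    ``data`` has shape (n_frames, nx, ny, nz, 3) in m/s; ``frame_times`` are
    strictly increasing within [0, cycle_length).
    """

    def __init__(self, grid, frame_times, data, cycle_length, periodic=True):
        frame_times = np.asarray(frame_times, dtype=float)
        data = np.asarray(data, dtype=float)
        if data.ndim != 5 or data.shape[-1] != 3:
            raise ConfigError("velocity data must have shape (n, nx, ny, nz, 3)")
        if data.shape[0] != frame_times.size:
            raise TimingError("frame count does not match number of frame times")
        if frame_times.size > 1 and not np.all(np.diff(frame_times) > 0):
            raise TimingError("frame times must be strictly increasing")
        if frame_times.size and (
            frame_times[0] < 0 or frame_times[-1] >= cycle_length
        ):
            raise TimingError("frame times must lie within [0, cycle_length)")
        if tuple(data.shape[1:4]) != grid.shape:
            raise ConfigError("velocity data shape does not match grid shape")
        self.grid = grid
        self.frame_times = frame_times
        self.data = data
        self.cycle_length = float(cycle_length)
        self.periodic = bool(periodic)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @classmethod
    def from_function(cls, fn, grid, frame_times, cycle_length, periodic=True):
        """Sample an analytic field ``fn(X, Y, Z, t) -> (u, v, w)`` [m/s]."""
        X, Y, Z = grid.meshgrid()
        frames = np.empty((len(frame_times),) + grid.shape + (3,), dtype=float)
        for k, t in enumerate(frame_times):
            u, v, w = fn(X, Y, Z, t)
            frames[k, ..., 0] = u
            frames[k, ..., 1] = v
            frames[k, ..., 2] = w
        return cls(grid, frame_times, frames, cycle_length, periodic)

    def _bracket(self, t: float):
        """Frames bracketing time ``t`` with periodic wrap: (k0, k1, alpha)."""
        n = self.n_frames
        if n == 1:
            return 0, 0, 0.0
        T = self.cycle_length
        tt = t % T if self.periodic else min(max(t, self.frame_times[0]), T)
        if tt < self.frame_times[0]:
            tt += T  # falls in the wrap interval [t_{n-1}, t_0 + T)
            k0 = n - 1
        else:
            k0 = int(np.searchsorted(self.frame_times, tt, side="right")) - 1
        if k0 == n - 1:
            t0 = self.frame_times[-1]
            t1 = self.frame_times[0] + T
            k1 = 0
        else:
            t0 = self.frame_times[k0]
            t1 = self.frame_times[k0 + 1]
            k1 = k0 + 1
        return k0, k1, (tt - t0) / (t1 - t0)

    def probe(self, x: np.ndarray, t: float) -> np.ndarray:
        """Velocity (m/s) at positions ``x`` (N, 3) and scalar time ``t``.

        Positions outside the sampled box are clamped to the box edge
        (nearest-inside extrapolation); the caller is responsible for
        treating far-outside queries as crossings.

        For large ensembles the two bracketing frames are blended once on
        the grid (O(grid) work) so each query costs a single trilinear
        gather; small queries interpolate per point instead.
        """
        k0, k1, a = self._bracket(t)
        if a == 0.0 or k0 == k1:
            return _trilinear(self.grid, self.data[k0], x)
        if x.shape[0] >= 256:
            return _trilinear(self.grid, self._blended(k0, k1, a), x)
        v0 = _trilinear(self.grid, self.data[k0], x)
        v1 = _trilinear(self.grid, self.data[k1], x)
        return (1.0 - a) * v0 + a * v1

    def _blended(self, k0: int, k1: int, a: float) -> np.ndarray:
        key = (k0, k1, a)
        if getattr(self, "_blend_key", None) != key:
            self._blend_key = key
            self._blend = (1.0 - a) * self.data[k0] + a * self.data[k1]
        return self._blend


class RegionMaskSeries:
    """Per-frame categorical labeling of the domain.

    ``labels`` has shape (n_frames, nx, ny, nz) with canonical region codes.
    Temporal lookup is nearest-frame (labels are categorical). A one-voxel
    dilation of the LA is precomputed per frame: positions whose voxel is
    OUTSIDE but adjacent to the LA are treated as still inside, absorbing the
    discrete motion of the wall between frames.
    """

    def __init__(self, grid, frame_times, labels, cycle_length):
        frame_times = np.asarray(frame_times, dtype=float)
        labels = np.asarray(labels)
        if labels.ndim != 4:
            raise ConfigError("labels must have shape (n, nx, ny, nz)")
        if labels.shape[0] != frame_times.size:
            raise TimingError("frame count does not match number of frame times")
        if tuple(labels.shape[1:]) != grid.shape:
            raise ConfigError("label shape does not match grid shape")
        for k in range(labels.shape[0]):
            if not np.any(labels[k] == LA):
                raise LabelingError(f"LA region empty in mask frame {k}")
        self.grid = grid
        self.frame_times = frame_times
        self.labels = labels.astype(np.uint8)
        self.cycle_length = float(cycle_length)
        self._la_dilated = None

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def la_dilated(self) -> np.ndarray:
        if self._la_dilated is None:
            struct = np.ones((3, 3, 3), dtype=bool)
            dil = np.empty(self.labels.shape, dtype=bool)
            for k in range(self.n_frames):
                dil[k] = ndimage.binary_dilation(self.labels[k] == LA, struct)
            self._la_dilated = dil
        return self._la_dilated

    def frame_index(self, t) -> np.ndarray:
        """Nearest frame (periodic) for scalar or vector times."""
        T = self.cycle_length
        t = np.asarray(t, dtype=float)
        d = np.abs(((t[..., None] - self.frame_times + T / 2) % T) - T / 2)
        return np.argmin(d, axis=-1)

    def bracket_frames(self, t):
        """The two frames bracketing time ``t`` (periodic wrap)."""
        T = self.cycle_length
        t = np.asarray(t, dtype=float)
        tt = t % T
        k0 = np.searchsorted(self.frame_times, tt, side="right") - 1
        k0 = np.where(k0 < 0, self.n_frames - 1, k0)
        k1 = (k0 + 1) % self.n_frames
        return k0, k1

    def label_at(self, x: np.ndarray, t) -> np.ndarray:
        """Region code at positions (N, 3); ``t`` scalar or per-particle."""
        ix, iy, iz = self.grid.nearest_index(x)
        k = self.frame_index(t)
        if k.ndim == 0:
            return self.labels[int(k), ix, iy, iz]
        return self.labels[k, ix, iy, iz]

    def inside_la(self, x: np.ndarray, t, pad: bool = True) -> np.ndarray:
        """LA membership for moving masks.

        A particle counts as inside when its voxel is LA in *either* frame
        bracketing ``t`` (the true wall position always lies between the two
        discrete walls), with a one-voxel dilation band absorbing the voxel
        quantization of the wall. Crossings into labelled neighbor regions
        (LV, PV) are unaffected: the band only relabels OUTSIDE voxels.
        """
        ix, iy, iz = self.grid.nearest_index(x)
        k0, k1 = self.bracket_frames(t)
        k0 = np.broadcast_to(k0, ix.shape)
        k1 = np.broadcast_to(k1, ix.shape)
        ins = np.zeros(ix.shape, dtype=bool)
        blocked = np.zeros(ix.shape, dtype=bool)
        for k in (k0, k1):
            lab = self.labels[k, ix, iy, iz]
            ins |= lab == LA
            if pad:
                ins |= (lab == OUTSIDE) & self.la_dilated[k, ix, iy, iz]
            # a voxel labelled LV/PV in either frame is a genuine neighbor
            # region, never part of the tolerance band
            blocked |= (lab != LA) & (lab != OUTSIDE)
        return ins & ~blocked

    def la_volume_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(frame_times, LA volume in mL) from voxel counts."""
        counts = (self.labels == LA).sum(axis=(1, 2, 3))
        return self.frame_times.copy(), counts * self.grid.voxel_volume_ml

    def region_codes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels))


@dataclass
class InterfacePlane:
    """Bounded plane patch at a chamber interface.

    The normal points in the nominal forward-flow direction: into the LA for
    PV planes, out of the LA toward the LV for the MV plane. The patch is a
    rectangle spanned by two in-plane unit axes with half-extents, or a disc
    (``radius``) when ``half_extents`` is None.
    """

    id: str
    origin: np.ndarray
    normal: np.ndarray
    axis_u: np.ndarray | None = None
    axis_v: np.ndarray | None = None
    half_extents: tuple[float, float] | None = None
    radius: float | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if abs(nn - 1.0) > 1e-9:
            raise ConfigError(f"plane {self.id}: normal must be unit length")
        self.normal = n / nn
        if self.axis_u is None:
            # Build any orthonormal in-plane basis.
            a = np.array([1.0, 0, 0]) if abs(self.normal[0]) < 0.9 else np.array([0, 1.0, 0])
            u = np.cross(self.normal, a)
            self.axis_u = u / np.linalg.norm(u)
        else:
            self.axis_u = np.asarray(self.axis_u, dtype=float)
        if self.axis_v is None:
            self.axis_v = np.cross(self.normal, self.axis_u)
        else:
            self.axis_v = np.asarray(self.axis_v, dtype=float)
        if self.half_extents is None and self.radius is None:
            raise ConfigError(f"plane {self.id}: needs half_extents or radius")

    def signed_distance(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.origin) @ self.normal

    def in_patch(self, x: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        """Whether the projection of ``x`` onto the plane lies in the patch."""
        d = np.atleast_2d(x) - self.origin
        pu = d @ self.axis_u
        pv = d @ self.axis_v
        if self.half_extents is not None:
            hu, hv = self.half_extents
            return (np.abs(pu) <= hu + tol) & (np.abs(pv) <= hv + tol)
        return pu**2 + pv**2 <= (self.radius + tol) ** 2

    def lattice(self, spacing: float) -> np.ndarray:
        """Seed points at the centers of a ``spacing`` lattice over the patch."""
        if self.half_extents is not None:
            hu, hv = self.half_extents
        else:
            hu = hv = self.radius
        nu = max(1, int(round(2 * hu / spacing)))
        nv = max(1, int(round(2 * hv / spacing)))
        cu = (-hu + (np.arange(nu) + 0.5) * spacing)
        cv = (-hv + (np.arange(nv) + 0.5) * spacing)
        UU, VV = np.meshgrid(cu, cv, indexing="ij")
        pts = (
            self.origin
            + UU.ravel()[:, None] * self.axis_u
            + VV.ravel()[:, None] * self.axis_v
        )
        if self.radius is not None:
            keep = (UU.ravel() ** 2 + VV.ravel() ** 2) <= self.radius**2
            pts = pts[keep]
        return pts

    @property
    def region(self) -> int:
        """Region code on the far side of this plane (PV_k or LV for MV)."""
        return LV if self.id == "MV" else region_code(self.id)
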