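"""Pathline integration through the periodic velocity field.

Particles are advanced with classical 4th-order Runge–Kutta at a constant
step (the final partial step is shortened to land exactly on the end time).
Backward tracking integrates the same field with the time direction
reversed. The whole ensemble shares one clock, which keeps the integration
fully vectorized over particles.

Region/plane crossings are resolved by bisection on the LA-membership
predicate along the straight step segment; the crossing is attributed to an
interface plane when the crossing point lies within a patch, otherwise to
the raw region transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .fields import (
    LA,
    LV,
    OUTSIDE,
    InterfacePlane,
    RegionMaskSeries,
    VelocityFieldSeries,
    region_name,
)

# terminal statuses
ACTIVE = "active"
COMPLETED = "completed"
EXITED_MV = "exited_MV"
EXITED_PV = "exited_PV"
LOST = "lost"

_MM_PER_M = 1000.0


@dataclass
class CrossingEvent:
    """A particle's passage through the LA boundary."""

    time: float
    via: str  # plane id or region name
    region: int  # canonical region code entered
    direction: str  # "exit_LA" or "enter_LA"
    position: np.ndarray


@dataclass
class ParticleTrajectory:
    """One seeded particle: represented volume, samples and crossings."""

    seed_origin: str  # "VOLUME" or a PV plane id
    seed_time: float
    volume_ml: float
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    speeds: np.ndarray = field(default_factory=lambda: np.empty(0))
    events: list[CrossingEvent] = field(default_factory=list)
    status: str = ACTIVE


def interpolate_velocity(field_series: VelocityFieldSeries, x, t: float) -> np.ndarray:
    """Velocity (m/s) at position(s) ``x`` [mm] and time ``t`` [s].

    Linear in time with periodic wrap, trilinear in space; out-of-domain
    positions are clamped to the nearest sampled point.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    v = field_series.probe(np.atleast_2d(x), t)
    return v[0] if single else v


class EnsembleResult:
    """Arrays-of-structs result of an ensemble advection.

    Entry/exit times are absolute times on the integration clock (they can be
    negative for backward tracking). ``via`` codes are canonical region codes
    of the region entered at the crossing; OUTSIDE means the particle was
    lost through the wall.
    """

    def __init__(self, n: int, t_start: float, t_end: float):
        self.t_start = t_start
        self.t_end = t_end
        self.entry_time = np.full(n, np.nan)
        self.entry_region = np.full(n, -1, dtype=int)
        self.entry_pos = np.full((n, 3), np.nan)
        self.exit_time = np.full(n, np.nan)
        self.exit_region = np.full(n, -1, dtype=int)
        self.exit_pos = np.full((n, 3), np.nan)
        self.exit_via = np.full(n, "", dtype=object)  # plane id or region name
        self.status = np.full(n, ACTIVE, dtype=object)
        self.final_pos = np.full((n, 3), np.nan)
        self.rec_times: np.ndarray | None = None
        self.rec_speed: np.ndarray | None = None  # (n, R) m/s, NaN when absent
        self.rec_inside: np.ndarray | None = None  # (n, R) bool

    @property
    def n(self) -> int:
        return len(self.status)


def _rk4_step(field_series, x, t, h):
    """One RK4 step of size h (signed, seconds) on positions x (mm)."""
    s = _MM_PER_M * h
    k1 = field_series.probe(x, t)
    k2 = field_series.probe(x + 0.5 * s * k1, t + 0.5 * h)
    k3 = field_series.probe(x + 0.5 * s * k2, t + 0.5 * h)
    k4 = field_series.probe(x + s * k3, t + h)
    return x + (s / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _bisect_boundary(masks, p0, p1, t0, t1, n_iter=40):
    """Locate the LA-membership change along straight segments.

    Returns (t_cross, x_cross, region_beyond): the crossing on the outside
    side of the boundary and the region code found there.
    """
    m = p0.shape[0]
    lo = np.zeros(m)
    hi = np.ones(m)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pm = p0 + mid[:, None] * (p1 - p0)
        tm = t0 + mid * (t1 - t0)
        ins = masks.inside_la(pm, tm)
        lo = np.where(ins, mid, lo)
        hi = np.where(ins, hi, mid)
    x_cross = p0 + hi[:, None] * (p1 - p0)
    t_cross = t0 + hi * (t1 - t0)
    region = masks.label_at(x_cross, t_cross)
    # If the bisected point still reads LA (razor-thin band), fall back to
    # the step endpoint's region.
    bad = region == LA
    if np.any(bad):
        region = np.where(bad, masks.label_at(p1, np.full(m, t1)), region)
    return t_cross, x_cross, region.astype(int)


def _attribute(planes, x, region):
    """Plane id when the crossing point lies within a matching patch, else
    the raw region name. Simultaneous patches resolve to the nearer patch
    center; exact ties take deterministic order (MV first, then PV_1..k)."""
    if not planes:
        return region_name(int(region))
    ordered = sorted(planes, key=lambda p: (p.id != "MV", p.id))
    best, best_d = None, np.inf
    for p in ordered:
        if p.region != region:
            continue
        pt = np.atleast_2d(x)
        if p.in_patch(pt)[0] and abs(p.signed_distance(pt)[0]) <= 2.0 * max(
            1.0, float(np.max(np.abs(p.normal)))
        ):
            d = float(np.linalg.norm(pt[0] - p.origin))
            if d < best_d - 1e-12:
                best, best_d = p.id, d
    return best if best is not None else region_name(int(region))


def detect_crossing(
    p0, p1, t0: float, t1: float, masks: RegionMaskSeries, planes=None
) -> CrossingEvent | None:
    """Resolve the boundary crossing on one trajectory segment.

    The flanking samples must lie on different sides of the LA boundary;
    returns None when both ends are inside (or both outside) the LA.
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    in0 = bool(masks.inside_la(p0, t0)[0])
    in1 = bool(masks.inside_la(p1, t1)[0])
    if in0 == in1:
        return None
    if in0:
        tc, xc, reg = _bisect_boundary(masks, p0, p1, t0, t1)
        direction = "exit_LA"
    else:
        tc, xc, reg = _bisect_boundary(masks, p1, p0, t1, t0)
        direction = "enter_LA"
    via = _attribute(planes, xc[0], reg[0])
    return CrossingEvent(float(tc[0]), via, int(reg[0]), direction, xc[0])


def advect_ensemble(
    field_series: VelocityFieldSeries,
    masks: RegionMaskSeries,
    x0: np.ndarray,
    t0: float,
    t1: float,
    dt: float,
    *,
    release_times=None,
    planes=None,
    record_stride: int = 0,
) -> EnsembleResult:
    """Advect an ensemble of particles from ``t0`` to ``t1``.

    Particles seeded outside the LA (plane seeding) are in a pre-entry
    phase: their first LA crossing is recorded as an entry event, after
    which the first crossing out of the LA terminates them. Particles
    seeded inside the LA terminate at their first exit. Backward tracking
    is requested with ``t1 < t0``.

    ``release_times`` (per-particle) activate particles once the clock
    passes their release time; they must be commensurate with the step so
    activation is exact. ``record_stride`` > 0 stores speed and LA-membership
    every that many steps (plus the endpoint).
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    if t1 == t0:
        raise ConfigError("t1 must differ from t0")
    x0 = np.asarray(x0, dtype=float)
    n = x0.shape[0]
    res = EnsembleResult(n, t0, t1)
    direction = 1.0 if t1 > t0 else -1.0
    span = abs(t1 - t0)
    n_steps = int(np.ceil(span / dt - 1e-12))

    pos = x0.copy()
    if release_times is None:
        started = np.ones(n, dtype=bool)
    else:
        release_times = np.asarray(release_times, dtype=float)
        started = direction * (t0 - release_times) >= -1e-12
    # entered: particle currently counted inside the LA
    entered = started & np.asarray(masks.inside_la(pos, t0))
    # pre-entry particles seeded inside would double-book; treat seeds as
    # in-LA iff inside at their activation time.
    done = np.zeros(n, dtype=bool)

    if record_stride > 0:
        rec_idx = np.arange(0, n_steps + 1, record_stride)
        if rec_idx[-1] != n_steps:
            rec_idx = np.append(rec_idx, n_steps)
        rec_t = t0 + direction * np.minimum(rec_idx * dt, span)
        res.rec_times = rec_t
        res.rec_speed = np.full((n, rec_t.size), np.nan)
        res.rec_inside = np.zeros((n, rec_t.size), dtype=bool)
        rec_map = {int(i): j for j, i in enumerate(rec_idx)}
        _record(field_series, pos, t0, started & ~done, entered, res, rec_map.get(0))

    t = t0
    for step in range(1, n_steps + 1):
        h_abs = min(dt, span - (step - 1) * dt)
        h = direction * h_abs
        t_new = t0 + direction * min(step * dt, span)
        if release_times is not None:
            newly = ~started & (direction * (t - release_times) >= -1e-12)
            if np.any(newly):
                ni = np.flatnonzero(newly)
                started[ni] = True
                # Plane seeds activate outside the LA; their entry is
                # detected as a crossing. Seeds already inside book directly.
                entered[ni] = np.asarray(masks.inside_la(pos[ni], t_new))
        act = started & ~done
        if np.any(act):
            idx = np.flatnonzero(act)
            p_old = pos[idx]
            p_new = _rk4_step(field_series, p_old, t, h)
            pos[idx] = p_new
            ins = np.asarray(masks.inside_la(p_new, t_new))
            was_in = entered[idx]
            # entries: pre-entry particles now inside
            ent = ~was_in & ins
            if np.any(ent):
                sub = np.flatnonzero(ent)
                tc, xc, _ = _bisect_boundary(
                    masks, p_new[sub], p_old[sub], t_new, t
                )
                gi = idx[sub]
                res.entry_time[gi] = tc
                res.entry_pos[gi] = xc
                res.entry_region[gi] = LA
                entered[gi] = True
            # exits: in-LA particles now outside
            ext = was_in & ~ins
            if np.any(ext):
                sub = np.flatnonzero(ext)
                tc, xc, reg = _bisect_boundary(
                    masks, p_old[sub], p_new[sub], t, t_new
                )
                gi = idx[sub]
                res.exit_time[gi] = tc
                res.exit_pos[gi] = xc
                res.exit_region[gi] = reg
                for j, g in enumerate(gi):
                    res.exit_via[g] = _attribute(planes, xc[j], reg[j])
                    res.status[g] = (
                        LOST
                        if reg[j] == OUTSIDE
                        else (EXITED_MV if reg[j] == LV else EXITED_PV)
                    )
                done[gi] = True
        t = t_new
        if record_stride > 0 and step in rec_map:
            _record(
                field_series, pos, t, started & ~done, entered, res, rec_map[step]
            )
    res.final_pos[:] = pos
    res.status[np.asarray(res.status, dtype=object) == ACTIVE] = COMPLETED
    return res


def _record(field_series, pos, t, active, entered, res, col):
    if col is None:
        return
    act = np.flatnonzero(active)
    if act.size:
        v = field_series.probe(pos[act], t)
        res.rec_speed[act, col] = np.linalg.norm(v, axis=1)
    res.rec_inside[:, col] = active & entered


def advect(
    field_series,
    masks,
    planes,
    x0,
    t0: float,
    t1: float,
    dt: float,
    volume_ml: float = 1.0,
    seed_origin: str = "VOLUME",
    record_stride: int = 1,
) -> ParticleTrajectory:
    """Track one particle from ``t0`` to ``t1`` (backward when t1 < t0).

    Single-particle convenience wrapper around :func:`advect_ensemble`;
    returns a :class:`ParticleTrajectory` with its terminal crossing event,
    if any.
    """
    res = advect_ensemble(
        field_series,
        masks,
        np.atleast_2d(np.asarray(x0, dtype=float)),
        t0,
        t1,
        dt,
        planes=planes,
        record_stride=record_stride,
    )
    traj = ParticleTrajectory(seed_origin, t0, volume_ml)
    traj.times = res.rec_times if res.rec_times is not None else np.array([t1])
    traj.speeds = (
        res.rec_speed[0] if res.rec_speed is not None else np.empty(0)
    )
    traj.positions = np.vstack([res.final_pos[0]])
    direction = "exit_LA" if t1 > t0 else "enter_LA"
    if np.isfinite(res.exit_time[0]):
        traj.events.append(
            CrossingEvent(
                float(res.exit_time[0]),
                str(res.exit_via[0]),
                int(res.exit_region[0]),
                direction,
                res.exit_pos[0],
            )
        )
    traj.status = str(res.status[0])
    return traj
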