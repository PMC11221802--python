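"""Analytic periodic chamber phantoms with known component volumes.

The phantom is an axis-aligned chamber of length L (x in [0, L]) and
cross-section S(t) = W · H(t), with a moving top wall at z = H(t), an inlet
tube (the pulmonary-vein side, x < 0) and an outlet (the mitral side,
x > L). Mass conservation fixes the interior axial velocity

    u(x, t) = (Q_in(t) − (x/L) · (Q_in(t) − Q_out(t))) / S(t)

and the wall-normal component w(z, t) = z · H'(t)/H(t) is linear across the
section, so the sampled field is exactly divergence free and exactly
reproduced by trilinear interpolation. Realism is deliberately sacrificed
for verifiability: because the axial dynamics are one-dimensional, every
component volume has a brute-force characteristics referee.

Waveforms mirror the physiological phasing: a systolic inflow lobe fills
the chamber while the outlet is closed (reservoir phase), early (E) and
late (A) diastolic outflow lobes empty it, an optional negative inflow lobe
during the A wave produces late-diastolic vein backflow, and an optional
sealed stagnant pocket contributes pure residual volume.

Ground truth refers to the frame-sampled field the pipeline actually
consumes: the oracle interpolates the frame-sampled axial velocity profiles
linearly in time (the same contract as the velocity series) and integrates
them with fine fixed steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigError
from .fields import (
    LA,
    LV,
    OUTSIDE,
    InterfacePlane,
    RectGrid,
    RegionMaskSeries,
    VelocityFieldSeries,
    pv_code,
)
from .timing import CardiacTiming

PRESETS = (
    "pure_conduit",
    "reservoir_mix",
    "backflow",
    "stagnant_pocket",
    "full_mix",
)


# --------------------------------------------------------------------------
# waveform lobes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SineLobe:
    """Half-sine flow lobe integrating to ``volume_mm3`` over [a, b]."""

    a: float
    b: float
    volume_mm3: float

    def q(self, t):
        t = np.asarray(t, dtype=float)
        inside = (t >= self.a) & (t <= self.b)
        amp = self.volume_mm3 * math.pi / (2.0 * (self.b - self.a))
        return np.where(inside, amp * np.sin(math.pi * (t - self.a) / (self.b - self.a)), 0.0)

    def cum(self, t):
        t = np.asarray(t, dtype=float)
        phase = np.clip((t - self.a) / (self.b - self.a), 0.0, 1.0)
        return self.volume_mm3 * 0.5 * (1.0 - np.cos(math.pi * phase))


@dataclass(frozen=True)
class TrapezoidLobe:
    """Plateau ``q0`` on [a + ramp, b − ramp] with linear ramps.

    Sampled at frame times whose spacing equals ``ramp``, linear
    interpolation reproduces this waveform exactly, so the phantom's
    "steady" diastolic flow is steady for the sampled field too.
    """

    a: float
    b: float
    ramp: float
    q0: float  # mm^3/s

    def q(self, t):
        t = np.asarray(t, dtype=float)
        up = np.clip((t - self.a) / self.ramp, 0.0, 1.0)
        down = np.clip((self.b - t) / self.ramp, 0.0, 1.0)
        return self.q0 * np.minimum(up, down) * ((t >= self.a) & (t <= self.b))

    def cum(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        # integrate piecewise
        t1, t2, t3 = self.a + self.ramp, self.b - self.ramp, self.b
        seg = np.clip(t, self.a, t1) - self.a
        out += 0.5 * self.q0 * seg**2 / self.ramp
        out += self.q0 * (np.clip(t, t1, t2) - t1)
        seg = np.clip(t, t2, t3) - t2
        out += self.q0 * (seg - 0.5 * seg**2 / self.ramp)
        return out

    @property
    def volume_mm3(self) -> float:
        return self.q0 * (self.b - self.a - self.ramp)


def _q_sum(lobes, t):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for lo in lobes:
        out = out + lo.q(t)
    return out


def _cum_sum(lobes, t):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for lo in lobes:
        out = out + lo.cum(t)
    return out


# --------------------------------------------------------------------------
# phantom definition
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PocketBox:
    """Sealed stagnant subregion (labelled LA, zero velocity)."""

    x0: float
    x1: float
    y0: float
    y1: float
    z0: float
    z1: float

    @property
    def volume_ml(self) -> float:
        return (
            (self.x1 - self.x0) * (self.y1 - self.y0) * (self.z1 - self.z0) / 1000.0
        )

    def contains(self, x, y, z):
        return (
            (x > self.x0) & (x < self.x1)
            & (y > self.y0) & (y < self.y1)
            & (z > self.z0) & (z < self.z1)
        )


@dataclass
class Phantom:
    """Geometry, waveforms and frame samples of one analytic chamber."""

    name: str
    L: float
    W: float
    H_min: float
    tube_len: float
    n_pv: int
    timing: CardiacTiming
    q_in_lobes: tuple
    q_out_lobes: tuple
    pocket: PocketBox | None
    spacing: float
    # frame samples (filled in __post_init__)
    frame_times: np.ndarray = dc_field(init=False)
    q_in_f: np.ndarray = dc_field(init=False)
    q_out_f: np.ndarray = dc_field(init=False)
    H_f: np.ndarray = dc_field(init=False)
    Hdot_f: np.ndarray = dc_field(init=False)

    def __post_init__(self):
        T = self.timing.cycle_length
        tt = self.timing.frame_times
        net = _cum_sum(self.q_in_lobes, np.array([T]))[0] - _cum_sum(
            self.q_out_lobes, np.array([T])
        )[0]
        if abs(net) > 1e-6 * max(1.0, self.chamber_volume_mm3(0.0)):
            raise ConfigError(
                f"phantom waveforms violate periodicity: net volume {net:.3g} mm^3"
            )
        self.frame_times = tt
        self.q_in_f = _q_sum(self.q_in_lobes, tt)
        self.q_out_f = _q_sum(self.q_out_lobes, tt)
        self.H_f = self.H(tt)
        self.Hdot_f = (self.q_in_f - self.q_out_f) / (self.L * self.W)

    # -- analytic geometry --------------------------------------------------

    def H(self, t):
        t = np.asarray(t, dtype=float) % self.timing.cycle_length
        dv = _cum_sum(self.q_in_lobes, t) - _cum_sum(self.q_out_lobes, t)
        return self.H_min + dv / (self.L * self.W)

    def chamber_volume_mm3(self, t):
        return self.L * self.W * self.H(t)

    @property
    def H_max(self) -> float:
        return float(self.H(self.timing.t_mv_open))

    @property
    def z_top(self) -> float:
        z = self.H_max
        if self.pocket is not None:
            z = max(z, self.pocket.z1)
        s = self.spacing
        return math.ceil(z / s - 1e-9) * s

    @property
    def y_top(self) -> float:
        y = self.W
        if self.pocket is not None:
            y = max(y, self.pocket.y1)
        s = self.spacing
        return math.ceil(y / s - 1e-9) * s

    # -- frame interpolation (the contract shared with the sampled field) ---

    def _bracket(self, t: float):
        T = self.timing.cycle_length
        tt = t % T
        n = len(self.frame_times)
        k0 = int(np.searchsorted(self.frame_times, tt, side="right")) - 1
        if k0 < 0:
            k0 = n - 1
        if k0 == n - 1:
            t0, t1, k1 = self.frame_times[-1], self.frame_times[0] + T, 0
        else:
            t0, t1, k1 = self.frame_times[k0], self.frame_times[k0 + 1], k0 + 1
        a = (tt - t0) / (t1 - t0)
        return k0, k1, a

    def q_in_interp(self, t: float) -> float:
        k0, k1, a = self._bracket(t)
        return (1 - a) * self.q_in_f[k0] + a * self.q_in_f[k1]

    def u_axial(self, x, t: float):
        """Axial velocity (mm/s), the exact 1-D restriction of the sampled
        field: linear-in-time blend of the frame profiles, each evaluated as
        the piecewise-linear interpolant through the axial voxel-center
        samples (so the tube-chamber interface smear of the trilinear
        lookup is reproduced exactly).
        """
        k0, k1, a = self._bracket(t)
        return (1 - a) * self._u_frame(x, k0) + a * self._u_frame(x, k1)

    def _u_zone(self, x, k: int):
        """Raw zone formula at arbitrary positions (tube / chamber / outlet)."""
        x = np.asarray(x, dtype=float)
        qi, qo, H = self.q_in_f[k], self.q_out_f[k], self.H_f[k]
        S = self.W * H
        u_ch = (qi - (x / self.L) * (qi - qo)) / S
        u_in = qi / (self.W * self.H_min)
        u_out = qo / (self.W * self.z_top)
        return np.where(x < 0, u_in, np.where(x > self.L, u_out, u_ch))

    def _u_frame(self, x, k: int):
        x = np.asarray(x, dtype=float)
        s = self.spacing
        c0 = -self.tube_len + s / 2  # first axial voxel center
        j = np.floor((x - c0) / s)
        xl = c0 + j * s
        w = (x - xl) / s
        return (1 - w) * self._u_zone(xl, k) + w * self._u_zone(xl + s, k)


# --------------------------------------------------------------------------
# case assembly: sampled field, masks, planes
# --------------------------------------------------------------------------


@dataclass
class PhantomCase:
    """A phantom together with everything the pipeline consumes."""

    phantom: Phantom
    timing: CardiacTiming
    field: VelocityFieldSeries
    masks: RegionMaskSeries
    planes: list
    truth: dict  # component label -> mL (characteristics oracle)
    truth_meta: dict  # analytic reference integrals


def _build_grid(ph: Phantom) -> RectGrid:
    s = ph.spacing
    nx = int(round((ph.L + 2 * ph.tube_len) / s))
    ny = int(round(ph.y_top / s))
    nz = int(round(ph.z_top / s))
    origin = (-ph.tube_len + s / 2, s / 2, s / 2)
    return RectGrid(origin, (s, s, s), (nx, ny, nz))


def _sample_case(ph: Phantom) -> tuple[VelocityFieldSeries, RegionMaskSeries, list]:
    grid = _build_grid(ph)
    X, Y, Z = grid.meshgrid()
    T = ph.timing.cycle_length
    n = len(ph.frame_times)
    vel = np.zeros((n,) + grid.shape + (3,))
    lab = np.zeros((n,) + grid.shape, dtype=np.uint8)
    in_tube = X < 0
    chamber_x = (X > 0) & (X < ph.L)
    out_tube = X > ph.L
    if ph.pocket is not None:
        pocket = ph.pocket.contains(X, Y, Z)
        # Zero the velocity on the pocket-adjacent wall layer too, so that
        # interpolation is identically zero everywhere inside the pocket at
        # any seeding resolution. The pocket sits two voxels away from the
        # flow channel, so the channel-side interpolation stays exact.
        p = ph.pocket
        s = ph.spacing
        pocket_pad = (
            (X > p.x0 - s) & (X < p.x1 + s)
            & (Y > p.y0 - s) & (Y < p.y1 + s)
            & (Z > p.z0 - s) & (Z < p.z1 + s)
        )
    else:
        pocket = np.zeros_like(X, bool)
        pocket_pad = pocket
    for k in range(n):
        qi, qo, H, Hd = ph.q_in_f[k], ph.q_out_f[k], ph.H_f[k], ph.Hdot_f[k]
        S = ph.W * H
        u = np.where(
            in_tube,
            qi / (ph.W * ph.H_min),
            np.where(out_tube, qo / (ph.W * ph.z_top), (qi - (X / ph.L) * (qi - qo)) / S),
        )
        w = np.where(chamber_x, Z * Hd / H, 0.0)
        u = np.where(pocket_pad, 0.0, u)
        w = np.where(pocket_pad, 0.0, w)
        vel[k, ..., 0] = u / 1000.0  # mm/s -> m/s
        vel[k, ..., 2] = w / 1000.0
        frame = np.full(grid.shape, OUTSIDE, dtype=np.uint8)
        la = chamber_x & (Y < ph.W) & (Z < H)
        frame[la] = LA
        frame[pocket] = LA
        frame[out_tube] = LV
        for j in range(ph.n_pv):
            wk = ph.W / ph.n_pv
            sel = in_tube & (Y >= j * wk) & ((Y < (j + 1) * wk) | (j == ph.n_pv - 1))
            frame[sel] = pv_code(j + 1)
        lab[k] = frame
    field = VelocityFieldSeries(grid, ph.frame_times, vel, T, periodic=True)
    masks = RegionMaskSeries(grid, ph.frame_times, lab, T)
    planes = []
    wk = ph.W / ph.n_pv
    for j in range(ph.n_pv):
        planes.append(
            InterfacePlane(
                id=f"PV_{j + 1}",
                origin=np.array([-ph.spacing / 2, (j + 0.5) * wk, ph.H_min / 2]),
                normal=np.array([1.0, 0.0, 0.0]),
                axis_u=np.array([0.0, 1.0, 0.0]),
                axis_v=np.array([0.0, 0.0, 1.0]),
                half_extents=(wk / 2, ph.H_min / 2),
            )
        )
    planes.append(
        InterfacePlane(
            id="MV",
            origin=np.array([ph.L, ph.W / 2, ph.z_top / 2]),
            normal=np.array([1.0, 0.0, 0.0]),
            axis_u=np.array([0.0, 1.0, 0.0]),
            axis_v=np.array([0.0, 0.0, 1.0]),
            half_extents=(ph.W / 2, ph.z_top / 2),
        )
    )
    return field, masks, planes


# --------------------------------------------------------------------------
# characteristics oracle
# --------------------------------------------------------------------------


def _integrate_1d(
    ph: Phantom,
    x0: np.ndarray,
    t0: float,
    t1: float,
    dt: float,
    start_times: np.ndarray | None = None,
):
    """RK4 on dx/dt = u(x, t); returns crossing times/sides.

    Crossing sides: +1 above L (mitral), −1 below 0 (vein). Entry detection
    for seeds starting below 0 records the first upward crossing of 0.
    ``start_times`` (forward only) hold seeds frozen until released.
    """
    direction = 1.0 if t1 > t0 else -1.0
    n_steps = int(np.ceil(abs(t1 - t0) / dt - 1e-12))
    x = x0.astype(float).copy()
    n = x.size
    cross_t = np.full(n, np.nan)
    cross_side = np.zeros(n, dtype=int)
    entry_t = np.full(n, np.nan)
    entered = x0 > 0
    active = np.ones(n, dtype=bool)
    t = t0
    for s in range(1, n_steps + 1):
        h = direction * min(dt, abs(t1 - t0) - (s - 1) * dt)
        t_new = t + h
        act = active
        if start_times is not None:
            act = act & (direction * (t - start_times) >= -1e-12)
        idx = np.flatnonzero(act)
        if idx.size == 0:
            t = t_new
            continue
        xs = x[idx]
        k1 = ph.u_axial(xs, t)
        k2 = ph.u_axial(xs + 0.5 * h * k1, t + 0.5 * h)
        k3 = ph.u_axial(xs + 0.5 * h * k2, t + 0.5 * h)
        k4 = ph.u_axial(xs + h * k3, t + h)
        xn = xs + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        # entries (pre-entry seeds crossing 0 upward)
        pre = ~entered[idx]
        ent = pre & (xn > 0)
        if np.any(ent):
            g = idx[ent]
            frac = (0.0 - xs[ent]) / (xn[ent] - xs[ent])
            entry_t[g] = t + frac * h
            entered[g] = True
        # exits for entered seeds
        was_in = entered[idx]
        hi = was_in & (xn > ph.L)
        lo = was_in & (xn < 0) & ~ent
        for sel, side, bound in ((hi, 1, ph.L), (lo, -1, 0.0)):
            if np.any(sel):
                g = idx[sel]
                frac = (bound - xs[sel]) / (xn[sel] - xs[sel])
                cross_t[g] = t + frac * h
                cross_side[g] = side
                active[g] = False
        x[idx] = xn
        t = t_new
    return cross_t, cross_side, entry_t


def characteristics_oracle(
    ph: Phantom,
    volume_spacing: float = 2.0,
    release_interval: float = 0.025,
    dt: float | None = None,
) -> dict:
    """Brute-force referee: fine-step 1-D integration plus the component
    rules, exploiting that all seeds in one axial column share dynamics."""
    tm = ph.timing
    T = tm.cycle_length
    if dt is None:
        dt = T / 1e4
    t0 = tm.t_mv_open
    s = volume_spacing

    # volume seeds: one characteristic per axial column, with multiplicity
    xs = np.arange(s / 2, ph.L, s)
    # lattice cell centers (k + 1/2) s strictly inside the cross-section
    ny = int(math.ceil(ph.W / s - 0.5 - 1e-9))
    nz = int(math.ceil(ph.H_max / s - 0.5 - 1e-9))
    mult = ny * nz
    seed_vol = s**3 / 1000.0
    fwd_t, fwd_side, _ = _integrate_1d(ph, xs, t0, t0 + T, dt)
    bwd_t, bwd_side, _ = _integrate_1d(ph, xs, t0, t0 - T, dt)

    sys_start = t0 - tm.systole_duration
    vols = {k: 0.0 for k in (
        "CONDUIT", "RESERVOIR", "DELAYED_EJECTION", "RETAINED_INFLOW",
        "RESIDUAL_VOLUME", "PV_BACKFLOW", "LOST",
    )}
    col_vol = mult * seed_vol
    for j in range(xs.size):
        entry = bwd_t[j] if bwd_side[j] == -1 else np.nan
        if fwd_side[j] == -1:
            lab = "PV_BACKFLOW"
        elif fwd_side[j] == 1:
            lab = "RESERVOIR" if (np.isfinite(entry) and entry >= sys_start) else "DELAYED_EJECTION"
        else:
            lab = "RETAINED_INFLOW" if np.isfinite(entry) else "RESIDUAL_VOLUME"
        vols[lab] += col_vol
    if ph.pocket is not None:
        gx = np.arange(s / 2 - ph.tube_len, ph.L + ph.tube_len, s)
        nx_p = int(np.sum((gx > ph.pocket.x0) & (gx < ph.pocket.x1)))
        gy = np.arange(s / 2, ph.y_top, s)
        ny_p = int(np.sum((gy > ph.pocket.y0) & (gy < ph.pocket.y1)))
        gz = np.arange(s / 2, ph.z_top, s)
        nz_p = int(np.sum((gz > ph.pocket.z0) & (gz < ph.pocket.z1)))
        vols["RESIDUAL_VOLUME"] += nx_p * ny_p * nz_p * seed_vol

    # vein seeding: one characteristic per release, volume = Q dt
    n_rel = int(round(T / release_interval))
    rel_times = tm.t_mv_close + release_interval * np.arange(n_rel)
    q_rel = np.array([ph.q_in_interp(t) for t in rel_times])
    keep = q_rel > 0
    pv_inflow = float((q_rel[keep] * release_interval).sum()) / 1000.0
    rel = rel_times[keep]
    relv = q_rel[keep] * release_interval / 1000.0
    # seed plane sits on the first tube voxel-center plane, half a voxel
    # upstream of the vein-atrium interface
    x_start = np.full(rel.size, -ph.spacing / 2)
    t_start = tm.t_mv_close
    t_end = t_start + T + 1.5 * T
    exit_t, exit_side, entry_t = _integrate_1d(
        ph, x_start, t_start, t_end, dt, start_times=rel
    )
    dia_dur = tm.diastole_duration
    for j in range(rel.size):
        tau = rel[j]
        in_dia = not bool(tm.in_systole(tau))
        dia_end = tau + (dia_dur - ((tau - t0) % T)) if in_dia else np.nan
        if exit_side[j] == 1 and in_dia and exit_t[j] <= dia_end + 1e-12:
            vols["CONDUIT"] += relv[j]
        elif exit_side[j] == -1 and exit_t[j] <= tau + T + 1e-12:
            counted = (tau >= t0 - 1e-12) or (exit_t[j] <= t0 + 1e-12)
            if counted:
                vols["PV_BACKFLOW"] += relv[j]
    vols["pv_inflow_ml"] = pv_inflow
    return vols


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------


def make_phantom(
    preset: str,
    *,
    n_frames: int = 20,
    spacing: float = 2.0,
    cycle_length: float = 1.0,
    systole_fraction: float = 0.4,
    jitter: float = 0.0,
    seed: int | None = None,
    compute_truth: bool = True,
    oracle_dt: float | None = None,
) -> PhantomCase:
    """Build one of the named phantom presets.

    ``jitter`` perturbs the waveform volumes multiplicatively (uniform in
    ±jitter, seeded) while re-enforcing continuity, for generating synthetic
    cohorts; the main analysis path is deterministic (jitter 0).
    """
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {PRESETS}")
    T = cycle_length
    Ts = systole_fraction * T
    ramp = T / n_frames
    timing = CardiacTiming(
        cycle_length=T,
        t_mv_open=Ts,
        t_mv_close=0.0,
        t_pre_a=Ts + 0.5 * (T - Ts),
        n_frames=n_frames,
    )
    L, W, H_min, tube_len = 50.0, 20.0, 24.0, 10.0
    rng = np.random.default_rng(seed)

    def j(v):
        return v * (1.0 + rng.uniform(-jitter, jitter)) if jitter > 0 else v

    pocket = None
    n_pv = 1
    if preset in ("pure_conduit", "stagnant_pocket"):
        q0 = 96_000.0  # mm^3/s: transit time L/u = 0.25 s
        lobe = TrapezoidLobe(Ts, T, ramp, j(q0))
        q_in = (lobe,)
        q_out = (lobe,)
    else:
        # Reservoir family: systolic filling with the mitral valve closed,
        # early/mid-diastolic vein inflow, fast E-wave and late A-wave
        # emptying; the atrial maximum sits at end systole (the seed
        # instant) and the minimum at end diastole.
        Td = T - Ts
        v_sys = j(16_000.0)
        v_e = j(18_000.0)
        v_a = j(10_000.0)
        t_mid = Ts + 0.5 * Td  # E/A transition (diastasis, pre-A)
        t_bf = Ts + (2.0 / 3.0) * Td  # vein flow reversal onset
        v_bf = 0.0 if preset == "reservoir_mix" else j(3_000.0)
        v_din = v_e + v_a + v_bf - v_sys  # continuity over the cycle
        q_in = [SineLobe(0.0, Ts, v_sys), SineLobe(Ts, t_bf, v_din)]
        if v_bf > 0:
            q_in.append(SineLobe(t_bf, T, -v_bf))
        q_out = (SineLobe(Ts, t_mid, v_e), SineLobe(t_mid, T, v_a))
        q_in = tuple(q_in)
        if preset == "full_mix":
            n_pv = 2
    if preset in ("stagnant_pocket", "full_mix"):
        # two-voxel wall between channel and pocket (see _sample_case)
        y0 = W + 2 * spacing
        pocket = PocketBox(10.0, 34.0, y0, y0 + 4.0, 0.0, 24.0)

    ph = Phantom(
        name=preset,
        L=L,
        W=W,
        H_min=H_min,
        tube_len=tube_len,
        n_pv=n_pv,
        timing=timing,
        q_in_lobes=tuple(q_in),
        q_out_lobes=tuple(q_out),
        pocket=pocket,
        spacing=spacing,
    )
    field, masks, planes = _sample_case(ph)
    truth = characteristics_oracle(ph, volume_spacing=spacing, dt=oracle_dt) if compute_truth else {}
    meta = {
        "chamber_volume_es_ml": ph.chamber_volume_mm3(timing.t_mv_open) / 1000.0,
        "pocket_volume_ml": pocket.volume_ml if pocket else 0.0,
    }
    if preset in ("pure_conduit", "stagnant_pocket"):
        lobe = q_in[0]
        u = lobe.q0 / (W * H_min)
        t_eff = lobe.b - lobe.a - lobe.ramp  # effective steady-flow duration
        transit = L + spacing / 2  # seeds start on the plane just upstream
        meta["conduit_analytic_ml"] = lobe.q0 * (t_eff - transit / u) / 1000.0
        meta["conduit_plug_speed_mm_s"] = u
        meta["conduit_t_eff_s"] = t_eff
        meta["diastolic_inflow_ml"] = lobe.volume_mm3 / 1000.0
    if preset in ("backflow", "full_mix"):
        # exact integral of the frame-interpolated negative inflow
        meta["backflow_analytic_ml"] = _interp_integral(ph, negative=True)
    meta["pv_inflow_interp_ml"] = _interp_integral(ph, negative=False)
    return PhantomCase(ph, timing, field, masks, planes, truth, meta)


def _interp_integral(ph: Phantom, negative: bool) -> float:
    """Exact integral of the positive (or negative) part of the
    frame-interpolated total inflow waveform, in mL."""
    T = ph.timing.cycle_length
    t = np.append(ph.frame_times, T)
    q = np.append(ph.q_in_f, ph.q_in_f[0])
    total = 0.0
    for k in range(len(t) - 1):
        q0, q1 = q[k], q[k + 1]
        h = t[k + 1] - t[k]
        if negative:
            q0, q1 = -q0, -q1
        if q0 >= 0 and q1 >= 0:
            total += 0.5 * (q0 + q1) * h
        elif q0 <= 0 and q1 <= 0:
            pass
        elif q0 > 0:  # q1 < 0: positive triangle at the segment start
            f = q0 / (q0 - q1)
            total += 0.5 * q0 * f * h
        else:  # q0 < 0 < q1: positive triangle at the segment end
            f = q0 / (q0 - q1)
            total += 0.5 * q1 * (1 - f) * h
    return total / 1000.0


def continuity_audit(case: PhantomCase) -> float:
    """Max relative mismatch between the wall-motion volume rate and the
    net flux of the sampled field, per frame.

    The sampled axial profile is linear in x, so fluxes probed at two
    interior columns extrapolate exactly to the inlet and outlet faces.
    """
    ph = case.phantom
    g = case.field.grid
    ax = g.axes()
    ia = int(np.searchsorted(ax[0], 0.0)) + 1
    ib = int(np.searchsorted(ax[0], ph.L)) - 2
    xa, xb = ax[0][ia], ax[0][ib]
    scale = max(
        np.max(np.abs(ph.q_in_f - ph.q_out_f)), np.max(np.abs(ph.q_in_f)), 1.0
    )
    worst = 0.0
    iy, iz = 0, 0  # any in-chamber sample; the profile is uniform in y, z
    for k in range(case.field.n_frames):
        S = ph.W * ph.H_f[k]
        qa = case.field.data[k, ia, iy, iz, 0] * 1000.0 * S
        qb = case.field.data[k, ib, iy, iz, 0] * 1000.0 * S
        slope = (qb - qa) / (xb - xa)
        q_inlet = qa + slope * (0.0 - xa)
        q_outlet = qa + slope * (ph.L - xa)
        dvdt = ph.L * ph.W * ph.Hdot_f[k]
        worst = max(worst, abs((q_inlet - q_outlet) - dvdt) / scale)
    return worst
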