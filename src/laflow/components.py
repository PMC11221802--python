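"""Six-component classification of atrial blood and temporal decompositions.

Components (ventricular phase convention):

* **conduit** — enters at a pulmonary vein during diastole and leaves
  through the mitral valve within the same diastolic phase.
* **reservoir** — enters during systole (mitral valve closed) and leaves
  through the mitral valve in the following diastole.
* **delayed ejection** — leaves during diastole but entered in the previous
  diastole or was in the atrium before that.
* **retained inflow** — entered in the previous cycle but does not leave in
  the tracked window.
* **residual volume** — stays in the atrium over both tracked cycles.
* **PV backflow** — leaves the atrium retrograde through a pulmonary vein
  (an override: any particle leaving via a vein joins this component).

Volume-seeded particles (snapshot of the atrium at its end-systolic
maximum, tracked one cycle backward and forward) provide every component
except conduit; vein-seeded particles provide conduit and the part of the
PV backflow that never belongs to the snapshot. The merge rule counts each
blood parcel exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .fields import LA, LV, OUTSIDE, PV_BASE
from .timing import CardiacTiming

CONDUIT = "CONDUIT"
RESERVOIR = "RESERVOIR"
DELAYED_EJECTION = "DELAYED_EJECTION"
RETAINED_INFLOW = "RETAINED_INFLOW"
RESIDUAL_VOLUME = "RESIDUAL_VOLUME"
PV_BACKFLOW = "PV_BACKFLOW"
LOST = "LOST"
UNATTRIBUTED = "UNATTRIBUTED"

COMPONENTS = (
    CONDUIT,
    RESERVOIR,
    DELAYED_EJECTION,
    RETAINED_INFLOW,
    RESIDUAL_VOLUME,
    PV_BACKFLOW,
)
VOLUME_SEEDED_LABELS = (
    RESERVOIR,
    DELAYED_EJECTION,
    RETAINED_INFLOW,
    RESIDUAL_VOLUME,
    PV_BACKFLOW,
    LOST,
)


def _is_pv(codes) -> np.ndarray:
    codes = np.asarray(codes)
    return codes > PV_BASE


def classify_volume_seeded_arrays(
    entry_time,
    entry_region,
    exit_time,
    exit_region,
    lost,
    timing: CardiacTiming,
):
    """Vectorized component labels for volume-seeded particles.

    Times are absolute on the tracking clock: seeds sit at ``t_mv_open`` of
    the reference cycle; the backward window is one cycle earlier (entry
    times may be negative), the forward window one cycle later.

    Returns (labels, anomaly_mask) where the anomaly flags mitral exits
    outside the following diastole (valve-model imperfections); those are
    still classified by their entry rule.
    """
    entry_time = np.asarray(entry_time, dtype=float)
    exit_time = np.asarray(exit_time, dtype=float)
    entry_region = np.asarray(entry_region)
    exit_region = np.asarray(exit_region)
    lost = np.asarray(lost, dtype=bool)
    n = entry_time.size

    t_open = timing.t_mv_open
    dia_end = timing.diastole_end_after(t_open)
    sys_start = dia_end - timing.cycle_length  # preceding mitral-valve closure

    has_entry = np.isfinite(entry_time) & _is_pv(entry_region)
    entered_prec_systole = has_entry & (entry_time >= sys_start - 1e-12)
    exit_mv = np.isfinite(exit_time) & (exit_region == LV)
    exit_pv = np.isfinite(exit_time) & _is_pv(exit_region)
    anomaly = exit_mv & (exit_time > dia_end + 1e-12)

    labels = np.full(n, RESIDUAL_VOLUME, dtype=object)
    labels[has_entry] = RETAINED_INFLOW
    labels[exit_mv & entered_prec_systole] = RESERVOIR
    labels[exit_mv & ~entered_prec_systole] = DELAYED_EJECTION
    labels[exit_pv] = PV_BACKFLOW  # override: vein exits trump everything
    # Backward crossings into the LV (regurgitant entry) are not modeled.
    labels[np.isfinite(entry_time) & (entry_region == LV)] = LOST
    labels[lost] = LOST
    return labels, anomaly


def classify_pv_seeded_arrays(
    release_time,
    exit_time,
    exit_region,
    lost,
    timing: CardiacTiming,
):
    """Vectorized labels for vein-seeded particles.

    Conduit requires release during diastole and a mitral exit before that
    same diastolic phase ends; vein returns anywhere in the tracked window
    label PV backflow (the merge applies the de-duplication filter); all
    other fates are 'UNATTRIBUTED' — the particle's destiny is accounted
    for by the volume seeding of the next reference instant.
    """
    release_time = np.asarray(release_time, dtype=float)
    exit_time = np.asarray(exit_time, dtype=float)
    exit_region = np.asarray(exit_region)
    lost = np.asarray(lost, dtype=bool)
    n = release_time.size

    in_dia = ~timing.in_systole(release_time)
    dia_end = np.array([timing.diastole_end_after(t) for t in np.atleast_1d(release_time)])
    exit_mv = np.isfinite(exit_time) & (exit_region == LV)
    # vein return within one cycle of release ("during any time point in
    # the cardiac cycle"); the longer tracking horizon only serves conduit
    exit_pv = (
        np.isfinite(exit_time)
        & _is_pv(exit_region)
        & (exit_time <= release_time + timing.cycle_length + 1e-12)
    )

    labels = np.full(n, UNATTRIBUTED, dtype=object)
    labels[in_dia & exit_mv & (exit_time <= dia_end + 1e-12)] = CONDUIT
    labels[exit_pv] = PV_BACKFLOW
    labels[lost] = LOST
    return labels


def classify_volume_seeded(traj, timing: CardiacTiming) -> str:
    """Single-trajectory wrapper: classify one volume-seeded particle from
    its recorded crossing events."""
    entry_t, entry_r, exit_t, exit_r = np.nan, -1, np.nan, -1
    lost = traj.status == "lost"
    for ev in traj.events:
        if ev.direction == "enter_LA":
            entry_t, entry_r = ev.time, ev.region
        else:
            exit_t, exit_r = ev.time, ev.region
    labels, _ = classify_volume_seeded_arrays(
        [entry_t], [entry_r], [exit_t], [exit_r], [lost], timing
    )
    return labels[0]


def classify_pv_seeded(traj, timing: CardiacTiming) -> str:
    exit_t, exit_r = np.nan, -1
    for ev in traj.events:
        if ev.direction == "exit_LA":
            exit_t, exit_r = ev.time, ev.region
    labels = classify_pv_seeded_arrays(
        [traj.seed_time], [exit_t], [exit_r], [traj.status == "lost"], timing
    )
    return labels[0]


@dataclass
class ClassifiedSet:
    """A seeded particle set with labels and crossing bookkeeping."""

    origin: str
    labels: np.ndarray  # object array of component names
    volumes_ml: np.ndarray
    release_time: np.ndarray  # seed/release times (absolute)
    entry_time: np.ndarray  # LA entry (NaN when none found)
    exit_time: np.ndarray  # LA exit (NaN when none)
    exit_region: np.ndarray


@dataclass
class ComponentReport:
    """Per-component volumes, normalizations and time decompositions."""

    volumes: dict = dc_field(default_factory=dict)  # label -> mL
    normalized: dict = dc_field(default_factory=dict)  # (label, scheme) -> value
    rate_series: pd.DataFrame | None = None
    volume_series: pd.DataFrame | None = None
    ke_series: pd.DataFrame | None = None
    bias_ml: float = float("nan")
    lost_volume_ml: float = 0.0
    meta: dict = dc_field(default_factory=dict)

    def total_outflow_ml(self) -> float:
        return sum(
            self.volumes.get(c, 0.0)
            for c in (CONDUIT, RESERVOIR, DELAYED_EJECTION, PV_BACKFLOW)
        )


def pv_backflow_counted(pv_set: ClassifiedSet, timing: CardiacTiming) -> np.ndarray:
    """De-duplication filter for vein-seeded vein-returners.

    A vein-seeded particle released before the volume-seed instant that is
    still inside the atrium at that instant also belongs to the volume
    seeding, which will book its vein exit. Count a vein-seeded returner
    only when released at/after the snapshot, or when it both entered and
    returned before the snapshot.
    """
    t0 = timing.t_mv_open
    bf = pv_set.labels == PV_BACKFLOW
    released_after = pv_set.release_time >= t0 - 1e-12
    returned_before = pv_set.exit_time <= t0 + 1e-12
    return bf & (released_after | returned_before)


def merge_components(
    volume_set: ClassifiedSet,
    pv_sets: list[ClassifiedSet],
    timing: CardiacTiming,
) -> ComponentReport:
    """Combine both seeding strategies into per-component volumes.

    Conduit comes exclusively from vein seeding; reservoir, delayed
    ejection, retained inflow and residual volume exclusively from volume
    seeding; PV backflow from both, with the snapshot filter of
    :func:`pv_backflow_counted`. The inflow/outflow bias and lost volume
    are reported, never silently dropped.
    """
    report = ComponentReport()
    vols = {c: 0.0 for c in COMPONENTS}
    vol_breakdown = {}
    for lab in VOLUME_SEEDED_LABELS:
        vol_breakdown[lab] = float(
            volume_set.volumes_ml[volume_set.labels == lab].sum()
        )
    for lab in (RESERVOIR, DELAYED_EJECTION, RETAINED_INFLOW, RESIDUAL_VOLUME, PV_BACKFLOW):
        vols[lab] += vol_breakdown[lab]
    lost_ml = vol_breakdown[LOST]
    report.meta["volume_seeded_components_ml"] = dict(vol_breakdown)

    pv_inflow_total = 0.0
    for ps in pv_sets:
        conduit_sel = ps.labels == CONDUIT
        if np.any(conduit_sel & (ps.release_time < timing.t_mv_open - 1e-12) & timing.in_systole(ps.release_time)):
            raise ConsistencyError(
                "conduit particle released during systole: overlapping attribution"
            )
        vols[CONDUIT] += float(ps.volumes_ml[conduit_sel].sum())
        counted_bf = pv_backflow_counted(ps, timing)
        vols[PV_BACKFLOW] += float(ps.volumes_ml[counted_bf].sum())
        # Lost vein-seeded volume: apply the same snapshot filter so it is
        # not double-booked with the volume-seeded lost volume.
        lost_sel = (ps.labels == LOST) & (
            (ps.release_time >= timing.t_mv_open - 1e-12)
            | (ps.exit_time <= timing.t_mv_open + 1e-12)
        )
        lost_ml += float(ps.volumes_ml[lost_sel].sum())
        pv_inflow_total += float(ps.volumes_ml.sum())

    report.volumes = vols
    report.lost_volume_ml = lost_ml
    outflow = (
        vols[CONDUIT] + vols[RESERVOIR] + vols[DELAYED_EJECTION] + vols[PV_BACKFLOW]
    )
    report.bias_ml = pv_inflow_total - outflow
    report.meta["pv_inflow_total_ml"] = pv_inflow_total
    report.meta["volume_seeded_total_ml"] = float(volume_set.volumes_ml.sum())
    return report


def _bin_events(times, vols, labels, edges, labelset):
    """Sum event volumes per (bin, label)."""
    out = {lab: np.zeros(len(edges) - 1) for lab in labelset}
    ok = np.isfinite(times) & (times >= edges[0]) & (times < edges[-1])
    if np.any(ok):
        idx = np.searchsorted(edges, times[ok], side="right") - 1
        for lab in labelset:
            sel = labels[ok] == lab
            if np.any(sel):
                np.add.at(out[lab], idx[sel], vols[ok][sel])
    return out


def rate_and_volume_series(
    volume_set: ClassifiedSet,
    pv_sets: list[ClassifiedSet],
    timing: CardiacTiming,
    bin_width: float | None = None,
):
    """Temporal decomposition over the displayed two cycles.

    Returns (rate_df, volume_df): per-bin vein and mitral flow rates per
    component (vein exits count negative at the vein), and the in-LA volume
    of every component on the bin-edge grid. The window is
    [t_mv_open − T, t_mv_open + T].
    """
    T = timing.cycle_length
    t0 = timing.t_mv_open
    if bin_width is None:
        bin_width = T / timing.n_frames
    n_bins = int(np.ceil(2 * T / bin_width - 1e-9))
    truncated = abs(n_bins * bin_width - 2 * T) > 1e-9
    edges = t0 - T + bin_width * np.arange(n_bins + 1)
    edges[-1] = t0 + T

    # --- event tables ------------------------------------------------------
    ev_t, ev_v, ev_lab, ev_kind = [], [], [], []
    vs = volume_set
    pv_labels = _is_pv(vs.exit_region)
    for kind, tsel, labsel in (
        ("pv_in", vs.entry_time, None),
        ("mv_out", np.where(vs.exit_region == LV, vs.exit_time, np.nan), None),
        ("pv_out", np.where(pv_labels, vs.exit_time, np.nan), None),
    ):
        ev_t.append(tsel)
        ev_v.append(vs.volumes_ml)
        ev_lab.append(vs.labels)
        ev_kind.append(np.full(vs.labels.size, kind, dtype=object))
    for ps in pv_sets:
        counted_bf = pv_backflow_counted(ps, timing)
        use = (ps.labels == CONDUIT) | counted_bf
        pvx = _is_pv(ps.exit_region)
        for kind, tsel in (
            ("pv_in", np.where(use, ps.entry_time, np.nan)),
            ("mv_out", np.where(use & (ps.exit_region == LV), ps.exit_time, np.nan)),
            ("pv_out", np.where(use & pvx, ps.exit_time, np.nan)),
        ):
            ev_t.append(tsel)
            ev_v.append(ps.volumes_ml)
            ev_lab.append(ps.labels)
            ev_kind.append(np.full(ps.labels.size, kind, dtype=object))
    ev_t = np.concatenate(ev_t)
    ev_v = np.concatenate(ev_v)
    ev_lab = np.concatenate(ev_lab)
    ev_kind = np.concatenate(ev_kind)

    mids = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    rows = []
    for lab in COMPONENTS:
        sel_lab = ev_lab == lab
        pv_in = _bin_events(
            ev_t[sel_lab & (ev_kind == "pv_in")],
            ev_v[sel_lab & (ev_kind == "pv_in")],
            ev_lab[sel_lab & (ev_kind == "pv_in")],
            edges,
            [lab],
        )[lab]
        mv_out = _bin_events(
            ev_t[sel_lab & (ev_kind == "mv_out")],
            ev_v[sel_lab & (ev_kind == "mv_out")],
            ev_lab[sel_lab & (ev_kind == "mv_out")],
            edges,
            [lab],
        )[lab]
        pv_out = _bin_events(
            ev_t[sel_lab & (ev_kind == "pv_out")],
            ev_v[sel_lab & (ev_kind == "pv_out")],
            ev_lab[sel_lab & (ev_kind == "pv_out")],
            edges,
            [lab],
        )[lab]
        rows.append(
            pd.DataFrame(
                {
                    "time_s": mids,
                    "component": lab,
                    "pv_rate_ml_s": (pv_in - pv_out) / widths,
                    "mv_rate_ml_s": mv_out / widths,
                    "pv_in_ml": pv_in,
                    "mv_out_ml": mv_out,
                    "pv_out_ml": pv_out,
                }
            )
        )
    rate_df = pd.concat(rows, ignore_index=True)
    rate_df.attrs["truncated_last_bin"] = truncated
    rate_df.attrs["bin_width_s"] = bin_width

    # --- in-LA volume curves ----------------------------------------------
    grid = edges
    vol_rows = []
    win_lo, win_hi = t0 - T, t0 + T

    def inside_curve(entry, exit_, vols):
        lo = np.where(np.isfinite(entry), entry, win_lo)
        hi = np.where(np.isfinite(exit_), exit_, win_hi + 1.0)
        ins = (grid[None, :] >= lo[:, None]) & (grid[None, :] < hi[:, None])
        return ins.T @ vols

    for lab in COMPONENTS:
        total = np.zeros(grid.size)
        sel = vs.labels == lab
        if np.any(sel):
            total += inside_curve(
                vs.entry_time[sel], vs.exit_time[sel], vs.volumes_ml[sel]
            )
        for ps in pv_sets:
            counted = (ps.labels == CONDUIT) | pv_backflow_counted(ps, timing)
            psel = counted & (ps.labels == lab)
            if np.any(psel):
                entry = ps.entry_time[psel]
                # not inside before entering the atrium
                entry = np.where(np.isfinite(entry), entry, np.inf)
                total += inside_curve(entry, ps.exit_time[psel], ps.volumes_ml[psel])
        vol_rows.append(
            pd.DataFrame({"time_s": grid, "component": lab, "in_la_ml": total})
        )
    volume_df = pd.concat(vol_rows, ignore_index=True)
    return rate_df, volume_df
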