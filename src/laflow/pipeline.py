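"""End-to-end orchestration: seed, advect, classify, decompose, report.

The main path is deterministic: given the same inputs and parameters it
produces identical outputs. Volume seeds are tracked one full cycle
backward and forward from the end-systolic instant; vein seeds are released
over one full cycle and tracked forward 1.5 cycles so late diastolic
releases can still resolve conduit within their own diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import components as comp
from . import metrics
from .advection import EXITED_MV, EXITED_PV, LOST as ST_LOST, advect_ensemble
from .errors import ConfigError
from .fields import LA, InterfacePlane, RegionMaskSeries, VelocityFieldSeries
from .metrics import KeBundle, PhysicalConstants
from .seeding import SeedSpec, seed_plane, seed_volume
from .timing import CardiacTiming


@dataclass
class SubjectMeta:
    """Optional subject metadata."""

    identifier: str = "anonymous"
    bsa: float | None = None  # m^2

    def __post_init__(self):
        if self.bsa is not None and self.bsa <= 0:
            raise ConfigError("BSA must be positive when given")


@dataclass
class AnalysisParams:
    """Tunable numerical parameters of one run."""

    seed_spec: SeedSpec = dc_field(default_factory=SeedSpec)
    constants: PhysicalConstants = dc_field(default_factory=PhysicalConstants)
    dt: float | None = None  # tracking step, default cycle_length / 1000
    bin_width: float | None = None  # default cycle_length / n_frames
    record_every: float = 0.025  # speed-record interval for KE series
    pv_horizon_cycles: float = 1.5
    pv_release_start: float | None = None  # default: mitral-valve closure
    lvsv_ml: float | None = None  # override; default: mitral outflow sum


def _ensemble_to_classified_volume(seeds, fwd, bwd, timing):
    lost = (np.asarray(fwd.status, dtype=object) == ST_LOST) | (
        np.asarray(bwd.status, dtype=object) == ST_LOST
    )
    labels, anomaly = comp.classify_volume_seeded_arrays(
        bwd.exit_time,
        bwd.exit_region,
        fwd.exit_time,
        fwd.exit_region,
        lost,
        timing,
    )
    cs = comp.ClassifiedSet(
        origin="VOLUME",
        labels=labels,
        volumes_ml=seeds.volumes_ml,
        release_time=seeds.times,
        entry_time=bwd.exit_time,  # backward exit == forward entry
        exit_time=fwd.exit_time,
        exit_region=fwd.exit_region,
    )
    return cs, int(anomaly.sum())


def _ensemble_to_classified_pv(seeds, res, timing):
    lost = np.asarray(res.status, dtype=object) == ST_LOST
    labels = comp.classify_pv_seeded_arrays(
        seeds.times, res.exit_time, res.exit_region, lost, timing
    )
    return comp.ClassifiedSet(
        origin=seeds.origin,
        labels=labels,
        volumes_ml=seeds.volumes_ml,
        release_time=seeds.times,
        entry_time=res.entry_time,
        exit_time=res.exit_time,
        exit_region=res.exit_region,
    )


def analyze(
    field: VelocityFieldSeries,
    masks: RegionMaskSeries,
    planes: list[InterfacePlane],
    timing: CardiacTiming,
    params: AnalysisParams | None = None,
    subject: SubjectMeta | None = None,
) -> comp.ComponentReport:
    """Run the full flow component analysis on one case."""
    params = params or AnalysisParams()
    T = timing.cycle_length
    dt = params.dt if params.dt is not None else T / 1000.0
    stride = max(1, int(round(params.record_every / dt)))
    t0 = timing.t_mv_open

    # --- volume seeding ----------------------------------------------------
    vol_seeds = seed_volume(masks, timing, params.seed_spec)
    fwd = advect_ensemble(
        field, masks, vol_seeds.positions, t0, t0 + T, dt,
        planes=planes, record_stride=stride,
    )
    bwd = advect_ensemble(
        field, masks, vol_seeds.positions, t0, t0 - T, dt,
        planes=planes, record_stride=stride,
    )
    vol_set, n_anomaly = _ensemble_to_classified_volume(vol_seeds, fwd, bwd, timing)

    # --- vein seeding ------------------------------------------------------
    pv_planes = [p for p in planes if p.id.startswith("PV")]
    pv_sets, pv_bundles = [], []
    for plane in pv_planes:
        seeds = seed_plane(
            plane, field, timing, params.seed_spec,
            release_start=params.pv_release_start,
        )
        if seeds.n == 0:
            continue
        t_start = (
            params.pv_release_start
            if params.pv_release_start is not None
            else timing.t_mv_close
        )
        t_end = t_start + T + params.pv_horizon_cycles * T
        res = advect_ensemble(
            field, masks, seeds.positions, t_start, t_end, dt,
            release_times=seeds.times, planes=planes, record_stride=stride,
        )
        ps = _ensemble_to_classified_pv(seeds, res, timing)
        pv_sets.append(ps)
        counted = (ps.labels == comp.CONDUIT) | comp.pv_backflow_counted(ps, timing)
        pv_bundles.append(
            KeBundle(
                labels=np.where(counted, ps.labels, comp.UNATTRIBUTED),
                volumes_ml=ps.volumes_ml,
                rec_times=res.rec_times,
                rec_speed=res.rec_speed,
                rec_inside=res.rec_inside,
            )
        )

    # --- merge, series, energies ------------------------------------------
    report = comp.merge_components(vol_set, pv_sets, timing)
    report.meta["n_volume_seeds"] = vol_seeds.n
    report.meta["n_pv_seeds"] = int(sum(ps.labels.size for ps in pv_sets))
    report.meta["mv_exit_anomalies"] = n_anomaly
    rate_df, volume_df = comp.rate_and_volume_series(
        vol_set, pv_sets, timing, params.bin_width
    )
    report.rate_series = rate_df
    report.volume_series = volume_df

    bundles = [
        KeBundle(vol_set.labels, vol_set.volumes_ml, fwd.rec_times,
                 fwd.rec_speed, fwd.rec_inside),
        KeBundle(vol_set.labels, vol_set.volumes_ml, bwd.rec_times,
                 bwd.rec_speed, bwd.rec_inside),
    ] + pv_bundles
    report.ke_series = metrics.component_ke_series(
        bundles, comp.COMPONENTS, params.constants
    )

    # --- normalizations & indices ------------------------------------------
    k_es = int(masks.frame_index(t0))
    la_es = float((masks.labels[k_es] == LA).sum() * masks.grid.voxel_volume_ml)
    lvsv = params.lvsv_ml
    if lvsv is None:
        lvsv = (
            report.volumes[comp.CONDUIT]
            + report.volumes[comp.RESERVOIR]
            + report.volumes[comp.DELAYED_EJECTION]
        )
        report.meta["lvsv_source"] = "mitral outflow sum"
    bsa = subject.bsa if subject is not None else None
    report.normalized = metrics.normalize_components(
        {k: v for k, v in report.volumes.items()},
        la_es_volume=la_es,
        bsa=bsa,
        lvsv=lvsv if lvsv > 0 else None,
    )
    report.meta["la_es_volume_ml"] = la_es
    report.meta["lvsv_ml"] = lvsv
    if subject is not None:
        report.meta["subject"] = subject.identifier
        report.meta["bsa_m2"] = subject.bsa

    la_t, la_v = masks.la_volume_curve()
    try:
        vi = metrics.volumetric_indices(la_t, la_v, timing, lvsv=lvsv)
        report.meta["volumetric_indices"] = {
            k: v for k, v in vars(vi).items()
        }
    except Exception:  # index computation must never sink the flow report
        report.meta["volumetric_indices"] = None
    return report
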