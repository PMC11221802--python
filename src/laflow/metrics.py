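"""Kinetic energy, volumetric atrial-function indices and group statistics.

Per-particle kinetic energy is KE(t) = ½ ρ v(t)² V with blood density ρ
(1060 kg/m³) and represented volume V. Component kinetic energy is the sum
over the component's particles currently inside the atrium, divided by the
volume those particles represent — i.e. a volume-weighted mean of ½ ρ v²,
stored in J/m³ (1 J/m³ = 1e-3 mJ/mL; the writer converts).

The volumetric indices are the echocardiography-style quantities computed
from chamber volume curves: LA ejection fraction, expansion index, passive
and active EF, the absolute passive/active volume changes, and the
volume-based conduit estimate LVSV − LASV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .timing import CardiacTiming


@dataclass(frozen=True)
class PhysicalConstants:
    """Blood properties (viscosity recorded for provenance; unused by KE)."""

    blood_density: float = 1060.0  # kg/m^3
    blood_viscosity: float = 3.5e-3  # Pa.s

    def __post_init__(self):
        if self.blood_density <= 0:
            raise ConfigError("blood density must be positive")


def particle_ke(
    speed, volume_ml, constants: PhysicalConstants = PhysicalConstants()
):
    """Instantaneous particle kinetic energy, J: ½ ρ v² V."""
    speed = np.asarray(speed, dtype=float)
    volume_m3 = np.asarray(volume_ml, dtype=float) * 1e-6
    if np.any(volume_m3 <= 0):
        raise ConfigError("particle volume must be positive")
    return 0.5 * constants.blood_density * speed**2 * volume_m3


@dataclass
class KeBundle:
    """Per-particle speed records for one advected set."""

    labels: np.ndarray  # component per particle
    volumes_ml: np.ndarray
    rec_times: np.ndarray  # (R,)
    rec_speed: np.ndarray  # (N, R) m/s, NaN when not recorded
    rec_inside: np.ndarray  # (N, R) bool


def component_ke_series(
    bundles: list[KeBundle],
    labels_wanted,
    constants: PhysicalConstants = PhysicalConstants(),
    time_decimals: int = 9,
) -> pd.DataFrame:
    """Per-component kinetic energy per volume over time.

    Record grids from several bundles are merged on rounded time keys. At
    each output time a component's value is Σ ½ρv²V over its particles
    inside the LA divided by ΣV; times where no particle of the component
    is inside are absent from the output (undefined, not zero). The
    time-average is the mean over defined times.
    """
    acc: dict[tuple[float, str], list[float]] = {}
    for b in bundles:
        keys = np.round(b.rec_times, time_decimals)
        for lab in labels_wanted:
            sel = b.labels == lab
            if not np.any(sel):
                continue
            ins = b.rec_inside[sel]
            sp = b.rec_speed[sel]
            vol = b.volumes_ml[sel][:, None] * np.ones_like(sp)
            valid = ins & np.isfinite(sp)
            e = np.where(valid, 0.5 * constants.blood_density * sp**2 * vol, 0.0)
            v = np.where(valid, vol, 0.0)
            esum = np.nansum(e, axis=0)
            vsum = v.sum(axis=0)
            for j, key in enumerate(keys):
                if vsum[j] > 0:
                    cur = acc.setdefault((key, lab), [0.0, 0.0])
                    cur[0] += esum[j]
                    cur[1] += vsum[j]
    rows = [
        {
            "time_s": k[0],
            "component": k[1],
            # volume units cancel in the ratio: Σ ½ρv²V / ΣV = ½ρ<v²>, J/m³
            "ke_j_per_m3": ev[0] / ev[1],
            "volume_ml": ev[1],
        }
        for k, ev in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["time_s", "component", "ke_j_per_m3", "volume_ml"])


def time_average_ke(ke_df: pd.DataFrame) -> dict:
    """Mean KE/volume per component over the times it is inside the LA."""
    out = {}
    for lab, grp in ke_df.groupby("component"):
        out[str(lab)] = float(grp["ke_j_per_m3"].mean())
    return out


@dataclass(frozen=True)
class VolumetricIndices:
    """Echo-style indices of atrial function (volumes mL, EF %)."""

    la_max: float
    la_min: float
    la_pre_a: float | None
    la_ef: float
    la_expansion_index: float
    la_passive_ef: float | None
    la_active_ef: float | None
    la_passive_volume_change: float | None
    la_active_volume_change: float | None
    lv_stroke_volume: float | None
    lvsv_minus_lasv: float | None

    @property
    def lasv(self) -> float:
        return self.la_max - self.la_min


def detect_diastasis(
    times: np.ndarray, volumes: np.ndarray, timing: CardiacTiming
) -> float:
    """Default pre-A time: minimum |dV/dt| within mid-diastole.

    The search window is the middle portion of diastole (30–85 % of the
    phase), avoiding the early-filling and atrial-contraction flanks.
    """
    T = timing.cycle_length
    t_open = timing.t_mv_open
    dur = timing.diastole_duration
    lo, hi = t_open + 0.30 * dur, t_open + 0.85 * dur
    tt = np.asarray(times, dtype=float)
    vv = np.asarray(volumes, dtype=float)
    # build a dense periodic spline of the curve and differentiate
    dense_t = np.linspace(lo, hi, 200)
    dense_v = np.interp(dense_t % T, tt, vv, period=T)
    dvdt = np.gradient(dense_v, dense_t)
    return float(dense_t[int(np.argmin(np.abs(dvdt)))] % T)


def volumetric_indices(
    la_times,
    la_volumes,
    timing: CardiacTiming,
    lv_times=None,
    lv_volumes=None,
    lvsv: float | None = None,
    t_pre_a: float | None = None,
    detect_pre_a: bool = True,
) -> VolumetricIndices:
    """Evaluate the volumetric indices from sampled volume curves.

    ``t_pre_a`` falls back to the timing definition and then (when
    ``detect_pre_a``) to :func:`detect_diastasis`; with detection disabled
    and no pre-A time, the passive/active indices are None (unavailable).
    """
    la_times = np.asarray(la_times, dtype=float)
    la_volumes = np.asarray(la_volumes, dtype=float)
    if la_times.size < 2:
        raise InputError("LA volume curve needs at least two samples")
    la_max = float(la_volumes.max())
    la_min = float(la_volumes.min())
    if la_min <= 0:
        raise InputError("LA volume curve must be positive")
    la_ef = (la_max - la_min) / la_max * 100.0
    la_exp = (la_max - la_min) / la_min

    if t_pre_a is None:
        t_pre_a = timing.t_pre_a
    if t_pre_a is None and detect_pre_a:
        t_pre_a = detect_diastasis(la_times, la_volumes, timing)
    if t_pre_a is not None:
        la_pre_a = float(
            np.interp(t_pre_a % timing.cycle_length, la_times, la_volumes,
                      period=timing.cycle_length)
        )
        passive_ef = (la_max - la_pre_a) / la_max * 100.0
        active_ef = (la_pre_a - la_min) / la_pre_a * 100.0
        passive_dv = la_max - la_pre_a
        active_dv = la_pre_a - la_min
    else:
        la_pre_a = passive_ef = active_ef = passive_dv = active_dv = None

    if lvsv is None and lv_volumes is not None:
        lv_volumes = np.asarray(lv_volumes, dtype=float)
        lvsv = float(lv_volumes.max() - lv_volumes.min())
    lvsv_minus_lasv = None if lvsv is None else lvsv - (la_max - la_min)
    return VolumetricIndices(
        la_max,
        la_min,
        la_pre_a,
        la_ef,
        la_exp,
        passive_ef,
        active_ef,
        passive_dv,
        active_dv,
        lvsv,
        lvsv_minus_lasv,
    )


NORMALIZATION_SCHEMES = ("LA_ES", "BSA", "LVSV")


def normalize_components(
    volumes: dict,
    la_es_volume: float | None = None,
    bsa: float | None = None,
    lvsv: float | None = None,
) -> dict:
    """Component volumes under the three normalization schemes.

    LA_ES and LVSV schemes are percentages; BSA is mL/m². Schemes whose
    denominator is missing are absent from the result (never reported as
    zero); nonpositive denominators are configuration errors.
    """
    out = {}
    for scheme, denom, pct in (
        ("LA_ES", la_es_volume, True),
        ("BSA", bsa, False),
        ("LVSV", lvsv, True),
    ):
        if denom is None:
            continue
        if denom <= 0:
            raise ConfigError(f"{scheme} denominator must be positive")
        for lab, v in volumes.items():
            out[(lab, scheme)] = v / denom * (100.0 if pct else 1.0)
    return out


class TTestResult(NamedTuple):
    t: float
    p: float
    df: float
    degenerate: bool = False


def two_sample_t(group_a, group_b, welch: bool = False) -> TTestResult:
    """Two-sample t test (pooled variance by default; Welch by flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, 1.0, a.size + b.size - 2, True)
        return TTestResult(np.inf if np.mean(a) > np.mean(b) else -np.inf, 0.0,
                           a.size + b.size - 2, True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    return TTestResult(float(res.statistic), float(res.pvalue), df)


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares with R² = 1 − SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InputError("regression needs at least three points")
    if np.all(x == x[0]):
        raise InputError("constant predictor: fit undefined")
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))
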