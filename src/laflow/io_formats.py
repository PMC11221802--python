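"""File formats: legacy-VTK ASCII frames, case configuration and reports.

Velocity and mask frames are legacy VTK ASCII ``STRUCTURED_POINTS``
datasets (one file per frame) with the frame time embedded as a
``FIELD``/``TIME`` entry, so a series can be reassembled from files in any
order. Coordinates are millimeters, velocities m/s. A sidecar JSON config
names the files and carries the label map, interface planes, timing and
subject metadata. Reports are CSV tables plus one JSON manifest —
inspectable and diffable; all numeric output uses a fixed repr so reruns
are byte identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .components import COMPONENTS, ComponentReport
from .errors import ConfigError, FormatError, LabelingError, TimingError
from .fields import (
    InterfacePlane,
    RectGrid,
    RegionMaskSeries,
    VelocityFieldSeries,
    region_code,
    region_name,
)
from .pipeline import SubjectMeta
from .timing import CardiacTiming

_FMT = "%.17g"


# --------------------------------------------------------------------------
# legacy VTK structured points
# --------------------------------------------------------------------------


def write_vtk_frame(
    path,
    grid: RectGrid,
    *,
    vectors: np.ndarray | None = None,
    scalars: np.ndarray | None = None,
    name: str = "data",
    time: float | None = None,
    title: str = "laflow frame",
):
    """Write one frame as legacy VTK ASCII STRUCTURED_POINTS.

    ``ORIGIN`` is the first sample point (voxel center). Point data is
    written x-fastest per the VTK convention.
    """
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN " + " ".join(_FMT % v for v in grid.origin),
        "SPACING " + " ".join(_FMT % v for v in grid.spacing),
        f"POINT_DATA {n}",
    ]
    if time is not None:
        lines += ["FIELD FieldData 1", "TIME 1 1 double", _FMT % time]
    if vectors is not None:
        flat = np.asarray(vectors).reshape(nx, ny, nz, 3)
        flat = flat.transpose(2, 1, 0, 3).reshape(-1, 3)  # x fastest
        lines.append(f"VECTORS {name} double")
        lines += [" ".join(_FMT % c for c in row) for row in flat]
    if scalars is not None:
        flat = np.asarray(scalars).reshape(nx, ny, nz)
        flat = flat.transpose(2, 1, 0).reshape(-1)
        lines.append(f"SCALARS {name} int 1")
        lines.append("LOOKUP_TABLE default")
        lines += [str(int(v)) for v in flat]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_frame(path):
    """Parse a legacy VTK ASCII STRUCTURED_POINTS file.

    Returns (grid, arrays, time) where arrays maps name -> ndarray shaped
    (nx, ny, nz[, 3]).
    """
    path = Path(path)
    try:
        tokens = path.read_text().split()
    except OSError as e:
        raise FormatError(f"{path}: {e}") from e
    it = iter(enumerate(tokens))
    pos = {t.upper(): i for i, t in enumerate(tokens)}
    if "STRUCTURED_POINTS" not in pos:
        raise FormatError(f"{path}: not a STRUCTURED_POINTS legacy VTK file")
    try:
        i = pos["DIMENSIONS"]
        shape = tuple(int(tokens[i + k]) for k in (1, 2, 3))
        i = pos["ORIGIN"]
        origin = tuple(float(tokens[i + k]) for k in (1, 2, 3))
        i = pos["SPACING"]
        spacing = tuple(float(tokens[i + k]) for k in (1, 2, 3))
    except (KeyError, ValueError, IndexError) as e:
        raise FormatError(f"{path}: malformed header") from e
    grid = RectGrid(origin, spacing, shape)
    n = shape[0] * shape[1] * shape[2]
    arrays = {}
    time = None
    i = 0
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "TIME":
            # FIELD array: TIME numComp numTuples type value...
            time = float(tokens[i + 4])
            i += 5
        elif tok == "VECTORS":
            name = tokens[i + 1]
            vals = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float)
            if vals.size != 3 * n:
                raise FormatError(f"{path}: truncated VECTORS array {name}")
            arr = vals.reshape(shape[2], shape[1], shape[0], 3).transpose(2, 1, 0, 3)
            arrays[name] = arr
            i += 3 + 3 * n
        elif tok == "SCALARS":
            name = tokens[i + 1]
            j = i + 4
            if tokens[j].upper() == "LOOKUP_TABLE":
                j += 2
            vals = np.array(tokens[j : j + n], dtype=float)
            if vals.size != n:
                raise FormatError(f"{path}: truncated SCALARS array {name}")
            arrays[name] = vals.reshape(shape[2], shape[1], shape[0]).transpose(2, 1, 0)
            i = j + n
        else:
            i += 1
    return grid, arrays, time


def read_field_series(paths, timing: CardiacTiming, periodic: bool = True):
    """Assemble a velocity series from frame files (any order).

    Frame times come from the embedded TIME field; files lacking it are
    assigned uniform times in the given order.
    """
    frames = []
    grid0 = None
    for j, p in enumerate(paths):
        grid, arrays, time = read_vtk_frame(p)
        vec = next((a for a in arrays.values() if a.ndim == 4), None)
        if vec is None:
            raise FormatError(f"{p}: no 3-component vector array found")
        if grid0 is None:
            grid0 = grid
        elif not grid.same_geometry(grid0):
            raise FormatError(f"{p}: grid geometry differs from first frame")
        frames.append((time if time is not None else None, j, vec))
    timing.require_frame_count(len(frames))
    if any(t is None for t, _, _ in frames):
        times = timing.frame_times
        frames = [(times[j], j, v) for t, j, v in frames]
    frames.sort(key=lambda f: f[0])
    data = np.stack([v for _, _, v in frames])
    times = np.array([t for t, _, _ in frames])
    return VelocityFieldSeries(grid0, times, data, timing.cycle_length, periodic)


def read_mask_series(paths, label_map: dict, timing: CardiacTiming):
    """Assemble a region-mask series; raw labels remap via ``label_map``
    (raw value -> canonical region name)."""
    frames = []
    grid0 = None
    lut = {int(k): region_code(v) for k, v in label_map.items()}
    for j, p in enumerate(paths):
        grid, arrays, time = read_vtk_frame(p)
        sca = next((a for a in arrays.values() if a.ndim == 3), None)
        if sca is None:
            raise FormatError(f"{p}: no label scalar array found")
        if grid0 is None:
            grid0 = grid
        elif not grid.same_geometry(grid0):
            raise FormatError(f"{p}: grid geometry differs from first frame")
        raw = sca.astype(int)
        unknown = sorted(set(np.unique(raw)) - set(lut))
        if unknown:
            raise LabelingError(f"{p}: unmapped label values {unknown}")
        remap = np.zeros(max(lut) + 1, dtype=np.uint8)
        for k, v in lut.items():
            remap[k] = v
        frames.append((time if time is not None else None, j, remap[raw]))
    timing.require_frame_count(len(frames))
    if any(t is None for t, _, _ in frames):
        times = timing.frame_times
        frames = [(times[j], j, v) for t, j, v in frames]
    frames.sort(key=lambda f: f[0])
    labels = np.stack([v for _, _, v in frames])
    times = np.array([t for t, _, _ in frames])
    return RegionMaskSeries(grid0, times, labels, timing.cycle_length)


# --------------------------------------------------------------------------
# case configuration
# --------------------------------------------------------------------------


def plane_to_dict(p: InterfacePlane) -> dict:
    d = {
        "id": p.id,
        "origin": list(map(float, p.origin)),
        "normal": list(map(float, p.normal)),
    }
    if p.half_extents is not None:
        d["axis_u"] = list(map(float, p.axis_u))
        d["axis_v"] = list(map(float, p.axis_v))
        d["half_extents"] = list(map(float, p.half_extents))
    else:
        d["radius"] = float(p.radius)
    return d


def plane_from_dict(d: dict) -> InterfacePlane:
    return InterfacePlane(
        id=d["id"],
        origin=np.array(d["origin"], dtype=float),
        normal=np.array(d["normal"], dtype=float),
        axis_u=np.array(d["axis_u"], dtype=float) if "axis_u" in d else None,
        axis_v=np.array(d["axis_v"], dtype=float) if "axis_v" in d else None,
        half_extents=tuple(d["half_extents"]) if "half_extents" in d else None,
        radius=d.get("radius"),
    )


def load_case(config_path):
    """Load a case directory from its JSON config.

    Returns (field, masks, planes, timing, subject, extras).
    """
    config_path = Path(config_path)
    try:
        cfg = json.loads(config_path.read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise ConfigError(f"{config_path}: {e}") from e
    base = config_path.parent
    t = cfg.get("timing")
    if t is None:
        raise ConfigError(f"{config_path}: missing 'timing' section")
    timing = CardiacTiming(
        cycle_length=t["cycle_length"],
        t_mv_open=t["t_mv_open"],
        t_mv_close=t.get("t_mv_close", 0.0),
        t_pre_a=t.get("t_pre_a"),
        n_frames=t.get("n_frames", len(cfg["field_files"])),
    )
    field = read_field_series(
        [base / f for f in cfg["field_files"]], timing,
        periodic=cfg.get("periodic", True),
    )
    masks = read_mask_series(
        [base / f for f in cfg["mask_files"]], cfg["label_map"], timing
    )
    if not field.grid.same_geometry(masks.grid):
        raise ConfigError("field and mask grids differ")
    planes = [plane_from_dict(d) for d in cfg.get("planes", [])]
    subj = cfg.get("subject", {})
    subject = SubjectMeta(subj.get("identifier", "anonymous"), subj.get("bsa"))
    return field, masks, planes, timing, subject, cfg


def write_case(case_dir, field, masks, planes, timing, subject=None, extras=None):
    """Write a self-contained case directory (frames, masks, config)."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    field_files, mask_files = [], []
    for k in range(field.n_frames):
        fname = f"velocity_{k:03d}.vtk"
        write_vtk_frame(
            case_dir / fname, field.grid, vectors=field.data[k],
            name="velocity", time=float(field.frame_times[k]),
        )
        field_files.append(fname)
    for k in range(masks.n_frames):
        fname = f"mask_{k:03d}.vtk"
        write_vtk_frame(
            case_dir / fname, masks.grid, scalars=masks.labels[k],
            name="region", time=float(masks.frame_times[k]),
        )
        mask_files.append(fname)
    label_map = {str(c): region_name(c) for c in masks.region_codes()}
    cfg = {
        "field_files": field_files,
        "mask_files": mask_files,
        "label_map": label_map,
        "planes": [plane_to_dict(p) for p in planes],
        "timing": {
            "cycle_length": timing.cycle_length,
            "t_mv_open": timing.t_mv_open,
            "t_mv_close": timing.t_mv_close,
            "t_pre_a": timing.t_pre_a,
            "n_frames": timing.n_frames,
        },
        "periodic": True,
    }
    if subject is not None:
        cfg["subject"] = {"identifier": subject.identifier, "bsa": subject.bsa}
    if extras:
        cfg.update(extras)
    (case_dir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return case_dir / "config.json"


# --------------------------------------------------------------------------
# component report
# --------------------------------------------------------------------------

_SCHEME_COLS = {
    "LA_ES": "pct_la_es",
    "BSA": "ml_per_m2_bsa",
    "LVSV": "pct_lvsv",
}


def write_component_report(report: ComponentReport, destination) -> Path:
    """Write a report directory: components.csv, series CSVs, manifest.json.

    Normalization columns whose denominator was unavailable are left empty
    (missing, never zero). Field order and float formatting are fixed so
    identical reports are byte identical.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    rows = []
    for lab in COMPONENTS:
        row = {"component": lab, "volume_ml": report.volumes.get(lab, 0.0)}
        for scheme, col in _SCHEME_COLS.items():
            row[col] = report.normalized.get((lab, scheme), np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["component", "volume_ml", *_SCHEME_COLS.values()])
    df.to_csv(dest / "components.csv", index=False, float_format=_FMT)
    if report.rate_series is not None:
        report.rate_series.to_csv(dest / "rates.csv", index=False, float_format=_FMT)
    if report.volume_series is not None:
        report.volume_series.to_csv(
            dest / "volumes_in_la.csv", index=False, float_format=_FMT
        )
    if report.ke_series is not None:
        ke = report.ke_series.copy()
        ke["ke_mj_per_ml"] = ke["ke_j_per_m3"] * 1e-3  # writer-side unit
        ke.to_csv(dest / "kinetic_energy.csv", index=False, float_format=_FMT)
    manifest = {
        "bias_ml": report.bias_ml,
        "lost_volume_ml": report.lost_volume_ml,
        "volumes_ml": {k: report.volumes.get(k, 0.0) for k in COMPONENTS},
        "meta": _jsonable(report.meta),
    }
    (dest / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return dest


def read_component_report(source) -> ComponentReport:
    """Read back a report directory written by :func:`write_component_report`."""
    src = Path(source)
    df = pd.read_csv(src / "components.csv")
    report = ComponentReport()
    report.volumes = dict(zip(df["component"], df["volume_ml"]))
    for scheme, col in _SCHEME_COLS.items():
        for _, row in df.iterrows():
            if col in df.columns and np.isfinite(row[col]):
                report.normalized[(row["component"], scheme)] = float(row[col])
    if (src / "rates.csv").exists():
        report.rate_series = pd.read_csv(src / "rates.csv")
    if (src / "volumes_in_la.csv").exists():
        report.volume_series = pd.read_csv(src / "volumes_in_la.csv")
    if (src / "kinetic_energy.csv").exists():
        report.ke_series = pd.read_csv(src / "kinetic_energy.csv")
    manifest = json.loads((src / "manifest.json").read_text())
    report.bias_ml = manifest["bias_ml"]
    report.lost_volume_ml = manifest["lost_volume_ml"]
    report.meta = manifest.get("meta", {})
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
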