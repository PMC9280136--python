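"""File formats: legacy-VTK structured-points fields, CSV tables, JSON configs.

Velocity and modality fields travel as legacy VTK ASCII STRUCTURED_POINTS
files (the text form of VTK image data), with the frame time and units
carried in a FIELD data block so they are asserted on read rather than
silently assumed.  Tables are RFC-4180 CSV with ``.`` decimals; metadata and
valve configuration are JSON.  Every pipeline run can write a manifest
(config + seed + versions) sufficient to reproduce its outputs byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import GridVelocityField, ModalityFields, ModalityTimeSeries, Structure
from .tensors import FluidProperties
from .timing import PhaseTimings
from .valve import ClipSpec, ScalingSchedule, ValveAxes

__all__ = [
    "write_field",
    "read_field",
    "read_velocity_frames",
    "write_modality_fields",
    "write_time_series_csv",
    "write_structures_csv",
    "write_timings_json",
    "load_valve_config",
    "write_manifest",
]

_FMT = "%.17g"


def _write_structured_points(
    path, dims, spacing, origin, time, scalars: dict, vectors: dict, units: str
):
    lines = [
        "# vtk DataFile Version 3.0",
        f"lvflow field time={_FMT % time} units={units}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        f"ORIGIN {_FMT % origin[0]} {_FMT % origin[1]} {_FMT % origin[2]}",
        f"SPACING {_FMT % spacing[0]} {_FMT % spacing[1]} {_FMT % spacing[2]}",
        f"POINT_DATA {dims[0] * dims[1] * dims[2]}",
        "FIELD FieldData 1",
        "TIME 1 1 double",
        _FMT % time,
    ]
    for name, arr in vectors.items():
        lines.append(f"VECTORS {name} double")
        # x varies fastest in VTK point order
        flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
        lines.extend(" ".join(_FMT % v for v in row) for row in flat)
    for name, arr in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(_FMT % v for v in arr.ravel(order="F"))
    Path(path).write_text("\n".join(lines) + "\n")


def write_field(field: GridVelocityField, path) -> None:
    """Write a velocity frame (plus optional mask) as legacy VTK ASCII."""
    scalars = {}
    if field.mask is not None:
        scalars["mask"] = field.mask.astype(float)
    _write_structured_points(
        path,
        field.dims,
        field.spacing,
        field.origin,
        field.time,
        scalars,
        {"velocity": field.velocity},
        units="m/s",
    )


def write_modality_fields(m: ModalityFields, path) -> None:
    """Write rotation/shear/strain/sss point fields as legacy VTK ASCII."""
    scalars = {
        "rotation": m.rotation,
        "shear": m.shear,
        "strain": m.strain,
        "sss": m.sss,
    }
    _write_structured_points(
        path, m.defined.shape, m.spacing, m.origin, m.time, scalars, {}, units="1/s"
    )


class SchemaError(ValueError):
    """A field file does not match the expected layout."""


def read_field(path) -> GridVelocityField:
    """Read a velocity frame written by :func:`write_field`."""
    path = Path(path)
    tokens = path.read_text().split("\n")
    it = iter(tokens)
    header = {}
    dims = spacing = origin = None
    time = 0.0
    units = None
    arrays: dict[str, np.ndarray] = {}
    try:
        line = next(it)
        if not line.startswith("# vtk DataFile"):
            raise SchemaError(f"{path}: not a legacy VTK file")
        title = next(it)
        for part in title.split():
            if "=" in part:
                k, v = part.split("=", 1)
                header[k] = v
        if next(it).strip() != "ASCII":
            raise SchemaError(f"{path}: only ASCII VTK supported")
        if next(it).strip() != "DATASET STRUCTURED_POINTS":
            raise SchemaError(f"{path}: expected STRUCTURED_POINTS dataset")
        while True:
            line = next(it).split()
            if not line:
                continue
            key = line[0]
            if key == "DIMENSIONS":
                dims = tuple(int(v) for v in line[1:4])
            elif key == "ORIGIN":
                origin = np.array([float(v) for v in line[1:4]])
            elif key == "SPACING":
                spacing = np.array([float(v) for v in line[1:4]])
            elif key == "POINT_DATA":
                npts = int(line[1])
                break
        if dims is None or npts != dims[0] * dims[1] * dims[2]:
            raise SchemaError(f"{path}: POINT_DATA count does not match DIMENSIONS")
        for line in it:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "FIELD":
                nfields = int(parts[2])
                for _ in range(nfields):
                    name, _, ntup, _ = next(it).split()
                    vals = []
                    while len(vals) < int(ntup):
                        vals.extend(float(v) for v in next(it).split())
                    if name == "TIME":
                        time = vals[0]
            elif parts[0] == "VECTORS":
                name = parts[1]
                data = np.empty((npts, 3))
                for i in range(npts):
                    data[i] = [float(v) for v in next(it).split()]
                arrays[name] = data
            elif parts[0] == "SCALARS":
                name = parts[1]
                next(it)  # LOOKUP_TABLE
                vals = []
                while len(vals) < npts:
                    vals.extend(float(v) for v in next(it).split())
                arrays[name] = np.array(vals)
    except StopIteration as exc:
        raise SchemaError(f"{path}: truncated VTK file") from exc
    if "velocity" not in arrays:
        raise SchemaError(f"{path}: missing required point field 'velocity'")
    units = header.get("units")
    if units is not None and units != "m/s":
        raise SchemaError(f"{path}: velocity units declared as {units!r}, expected m/s")
    vel = arrays["velocity"].T.reshape((3,) + dims, order="F")
    vel = np.moveaxis(vel, 0, -1)
    mask = None
    if "mask" in arrays:
        mask = arrays["mask"].reshape(dims, order="F") > 0.5
    return GridVelocityField(
        velocity=vel, spacing=spacing, origin=origin, mask=mask, time=time
    )


def read_velocity_frames(paths) -> list[GridVelocityField]:
    """Read velocity frames and return them sorted by embedded time."""
    frames = [read_field(p) for p in paths]
    if len(frames) == 0:
        raise ValueError("no frames given")
    frames.sort(key=lambda f: f.time)
    times = [f.time for f in frames]
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"frame times are not strictly increasing: {times}")
    for f in frames[1:]:
        if not frames[0].same_geometry(f):
            raise ValueError("inconsistent grid geometry across frames")
    return frames


def write_time_series_csv(series: ModalityTimeSeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False, float_format=_FMT)


def write_structures_csv(structures: list[Structure], path) -> None:
    df = pd.DataFrame(
        [
            {
                "label": s.label,
                "voxels": s.voxels,
                "centroid_x": s.centroid[0],
                "centroid_y": s.centroid[1],
                "centroid_z": s.centroid[2],
            }
            for s in structures
        ],
        columns=["label", "voxels", "centroid_x", "centroid_y", "centroid_z"],
    )
    df.to_csv(path, index=False, float_format=_FMT)


def write_timings_json(timings: PhaseTimings, path, extra: dict | None = None) -> None:
    payload = timings.as_dict()
    payload["missing"] = list(timings.missing)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_valve_config(path):
    """Load a valve configuration JSON.

    Layout: ``axes {l, saa, sap}`` in mm, ``schedule {knots: [[t, saa_scale,
    sap_scale], ...]}``, optional ``clip {s, width_mm}`` and ``fluid
    {density, viscosity}``.  Missing blocks fall back to the defaults.
    """
    cfg = json.loads(Path(path).read_text())
    axes = ValveAxes(**cfg.get("axes", {}))
    sched_cfg = cfg.get("schedule", {})
    if "knots" in sched_cfg:
        sched = ScalingSchedule(knots=tuple(tuple(k) for k in sched_cfg["knots"]))
    else:
        sched = ScalingSchedule()
    clip = None
    if "clip" in cfg:
        c = cfg["clip"]
        clip = ClipSpec(s=c.get("s", 0.0), width=c.get("width_mm", 5.0))
    f = cfg.get("fluid", {})
    fluid = FluidProperties(
        density=f.get("density", FluidProperties().density),
        dynamic_viscosity=f.get("viscosity", FluidProperties().dynamic_viscosity),
    )
    return axes, sched, clip, fluid


def write_manifest(path, config: dict) -> None:
    """Record the run configuration plus library versions for replay."""
    import scipy

    from . import __version__

    manifest = dict(config)
    manifest["versions"] = {
        "lvflow": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
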