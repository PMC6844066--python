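"""Reading and writing the package's on-disk formats.

Flow curves travel as CSV — either one file per vessel with columns
``frame_index, time_ms, flow_ml_s`` (``time_ms`` is the frame start), or long
format with an additional leading ``vessel_id`` column.  Image series travel
as paired NIfTI files (magnitude and velocity, dimensions x, y, frame; pixel
spacing in the header) with a JSON sidecar for venc, RR interval and vessel
id.  Run configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .types import FlowCurve, VesselImageSeries

__all__ = [
    "flow_curves_to_frame",
    "write_flow_curves_csv",
    "read_flow_curves_csv",
    "write_vessel_series",
    "read_vessel_series",
    "load_yaml",
    "dump_yaml",
]

PathLike = Union[str, Path]


def flow_curves_to_frame(curves: Mapping[str, FlowCurve]) -> pd.DataFrame:
    """Long-format DataFrame (vessel_id, frame_index, time_ms, flow_ml_s)."""
    rows = []
    for vessel, curve in curves.items():
        rows.append(
            pd.DataFrame(
                {
                    "vessel_id": vessel,
                    "frame_index": np.arange(curve.n_frames),
                    "time_ms": np.arange(curve.n_frames) * curve.frame_duration,
                    "flow_ml_s": curve.flow,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_flow_curves_csv(curves: Mapping[str, FlowCurve], path: PathLike) -> None:
    """Write curves in long format, one row per vessel-frame."""
    flow_curves_to_frame(curves).to_csv(path, index=False, float_format="%.10g")


def _curve_from_table(df: pd.DataFrame, vessel_id: str) -> FlowCurve:
    df = df.sort_values("frame_index")
    times = df["time_ms"].to_numpy(dtype=float)
    n = len(df)
    if n < 2:
        raise InvalidInputError("flow curve CSV needs at least 2 frames")
    dt = float(np.median(np.diff(times)))
    if dt <= 0 or not np.allclose(np.diff(times), dt, rtol=1e-6, atol=1e-6):
        raise InvalidInputError("time_ms must be uniformly spaced frame starts")
    return FlowCurve(
        vessel_id=vessel_id,
        flow=df["flow_ml_s"].to_numpy(dtype=float),
        frame_duration=dt,
        rr_interval=dt * n,
    )


def read_flow_curves_csv(
    path: PathLike, vessel_id: Optional[str] = None
) -> Dict[str, FlowCurve]:
    """Read flow curves from CSV.

    Long-format files (with a ``vessel_id`` column) return one curve per
    vessel; single-vessel files require ``vessel_id``.  The RR interval is
    inferred as n_frames × frame spacing.
    """
    df = pd.read_csv(path)
    required = {"frame_index", "time_ms", "flow_ml_s"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"flow CSV must have columns {sorted(required)}")
    if "vessel_id" in df.columns:
        return {
            str(v): _curve_from_table(sub, str(v)) for v, sub in df.groupby("vessel_id")
        }
    if vessel_id is None:
        raise InvalidInputError("single-vessel CSV requires an explicit vessel_id")
    return {vessel_id: _curve_from_table(df, vessel_id)}


def write_vessel_series(
    series: VesselImageSeries, magnitude_path: PathLike, velocity_path: PathLike,
    sidecar_path: PathLike,
) -> None:
    """Write a vessel image series as magnitude + velocity NIfTI and a JSON sidecar."""
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    # store as (x, y, frame)
    mag = np.transpose(series.magnitude, (2, 1, 0))
    vel = np.transpose(series.velocity, (2, 1, 0))
    nib.save(nib.Nifti1Image(mag.astype(np.float64), affine), str(magnitude_path))
    nib.save(nib.Nifti1Image(vel.astype(np.float64), affine), str(velocity_path))
    sidecar = {
        "venc_cm_s": series.venc,
        "rr_interval_ms": series.rr_interval,
        "vessel_id": series.vessel_id,
        "pixel_spacing_mm": series.pixel_spacing,
        "eddy_corrected": series.eddy_corrected,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_vessel_series(
    magnitude_path: PathLike, velocity_path: PathLike, sidecar_path: PathLike
) -> VesselImageSeries:
    """Read a vessel image series written by :func:`write_vessel_series`."""
    mag_img = nib.load(str(magnitude_path))
    vel_img = nib.load(str(velocity_path))
    sidecar = json.loads(Path(sidecar_path).read_text())
    mag = np.transpose(np.asarray(mag_img.dataobj, dtype=float), (2, 1, 0))
    vel = np.transpose(np.asarray(vel_img.dataobj, dtype=float), (2, 1, 0))
    pixdim = float(mag_img.header.get_zooms()[0])
    return VesselImageSeries(
        magnitude=mag,
        velocity=vel,
        pixel_spacing=sidecar.get("pixel_spacing_mm", pixdim),
        venc=sidecar["venc_cm_s"],
        rr_interval=sidecar["rr_interval_ms"],
        vessel_id=sidecar.get("vessel_id", "UNKNOWN"),
        eddy_corrected=bool(sidecar.get("eddy_corrected", False)),
    )


def load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: expected a YAML mapping")
    return data


def dump_yaml(data: Mapping, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)
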