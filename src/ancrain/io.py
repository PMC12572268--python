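"""Readers and writers for the pipeline's on-disk formats.

Daily precipitation grids travel as NetCDF (dims time/lat/lon, variable
``precip`` in mm/day) via xarray; tabular artifacts (facilities, panels,
closures, index tables, disruption series, summaries) are comma-separated
UTF-8 CSV with a header row; fitted models and run manifests are JSON.
Every writer's output is re-readable by its paired reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .regression import LogLinearRegression

PRECIP_VAR = "precip"


def validate_precip_grid(grid: xr.DataArray) -> xr.DataArray:
    """Check dims, nonnegativity and daily contiguity of a precipitation cube."""
    missing_dims = {"time", "lat", "lon"} - set(grid.dims)
    if missing_dims:
        raise ValueError(f"precipitation grid lacks dims: {sorted(missing_dims)}")
    values = grid.values
    if np.isnan(values).any():
        raise ValueError("precipitation grid contains NaN values")
    if (values < 0).any():
        raise ValueError("precipitation grid contains negative values")
    time = pd.DatetimeIndex(grid["time"].values)
    if len(time) > 1:
        deltas = np.diff(time.values).astype("timedelta64[D]").astype(int)
        gaps = np.flatnonzero(deltas != 1)
        if len(gaps):
            gap_list = [
                f"{time[i].date()} -> {time[i + 1].date()}" for i in gaps[:5]
            ]
            raise ValueError(
                f"time axis is not contiguous daily; {len(gaps)} gap(s), "
                f"e.g. {gap_list}"
            )
    return grid


def write_precip_netcdf(grid: xr.DataArray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid.rename(PRECIP_VAR).to_netcdf(path)
    return path


def read_precip_netcdf(path: str | Path) -> xr.DataArray:
    with xr.open_dataset(path) as ds:
        if PRECIP_VAR not in ds:
            raise ValueError(
                f"{path}: no {PRECIP_VAR!r} variable (found {list(ds.data_vars)})"
            )
        grid = ds[PRECIP_VAR].load()
    return validate_precip_grid(grid)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_facilities_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"facility_id", "lon", "lat", "zone", "setting", "owner"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: facility table lacks columns {sorted(missing)}")
    return df


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"facility_id", "year", "month", "anc_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: panel lacks columns {sorted(missing)}")
    if "missing_flag" not in df.columns:
        df["missing_flag"] = df["anc_count"].isna()
    df["missing_flag"] = df["missing_flag"].astype(bool)
    return df


def read_closures_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"facility_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: closure registry lacks columns {sorted(missing)}")
    return df


def read_ensemble_manifest(path: str | Path) -> dict[str, dict[str, Path]]:
    """Read a scenario-ensemble manifest CSV (scenario, member, path).

    Relative member paths resolve against the manifest's directory. Returns
    {scenario: {member: path}}; the grids themselves are loaded lazily with
    :func:`read_precip_netcdf`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"scenario", "member", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest lacks columns {sorted(missing)}")
    out: dict[str, dict[str, Path]] = {}
    for row in df.itertuples(index=False):
        member_path = Path(row.path)
        if not member_path.is_absolute():
            member_path = path.parent / member_path
        if not member_path.exists():
            raise FileNotFoundError(f"manifest member file missing: {member_path}")
        out.setdefault(str(row.scenario), {})[str(row.member)] = member_path
    return out


def write_model_json(model: LogLinearRegression, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))
    return path


def read_model_json(path: str | Path) -> LogLinearRegression:
    return LogLinearRegression.from_dict(json.loads(Path(path).read_text()))


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_coerce))
    return path


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
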