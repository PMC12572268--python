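"""Monthly precipitation indices from daily gridded rainfall.

Implements the ETCCDI-informed indices used by the disruption regression:
monthly cumulative precipitation, Rx5day (maximum 5-day consecutive total
within the calendar month), their lags at 1, 2, 3, 4 and 9 months, squares,
cubes and the cumulative-by-Rx5day interaction.

Rx5day windows are confined within the calendar month: the analysis operates
at monthly resolution, so a window is only credited to a month when all five
days fall inside it. Lag columns are computed on each grid cell's own calendar
series and cross year boundaries naturally; months without sufficient lag
history carry NaN, never silent zeros, and are dropped at model-fitting time.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

DEFAULT_LAGS: tuple[int, ...] = (1, 2, 3, 4, 9)

#: Base index columns and their derived expansions, in canonical order.
BASE_INDEX_COLUMNS = ("cumulative_mm", "rx5day_mm")


def index_columns(lags: Sequence[int] = DEFAULT_LAGS) -> list[str]:
    """Canonical column list of a precipitation index table."""
    cols = list(BASE_INDEX_COLUMNS)
    for base in BASE_INDEX_COLUMNS:
        cols.extend(f"{base}_lag{k}" for k in lags)
    for base in BASE_INDEX_COLUMNS:
        cols.extend([f"{base}_sq", f"{base}_cube"])
    cols.append("cumulative_x_rx5day")
    return cols


def _check_full_month(daily: pd.Series) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(daily.index)
    if len(idx) == 0:
        raise ValueError("empty daily series")
    periods = idx.to_period("M")
    if periods.nunique() != 1:
        raise ValueError("series spans more than one calendar month")
    expected = pd.date_range(periods[0].start_time, periods[0].end_time, freq="D")
    missing = expected.difference(idx.normalize())
    if len(missing) > 0:
        raise ValueError(
            "daily series is missing dates: "
            + ", ".join(d.strftime("%Y-%m-%d") for d in missing)
        )
    return idx


def monthly_cumulative(daily: pd.Series) -> float:
    """Total precipitation (mm) over one fully observed calendar month.

    Parameters
    ----------
    daily : pd.Series
        Daily precipitation (mm/day) indexed by date; must cover every day
        of exactly one calendar month.
    """
    _check_full_month(daily)
    return float(np.asarray(daily, dtype=float).sum())


def rx5day(daily: pd.Series | np.ndarray) -> float:
    """Maximum 5-day consecutive precipitation total (mm) within one month.

    All windows lie fully inside the series; series shorter than 5 days are
    rejected rather than padded.
    """
    values = np.asarray(daily, dtype=float)
    if values.size < 5:
        raise ValueError(f"month has {values.size} days; Rx5day needs at least 5")
    window_sums = np.convolve(values, np.ones(5), mode="valid")
    return float(window_sums.max())


def percentile_threshold(monthly_totals: Iterable[float], q: float = 90.0) -> float:
    """Linear-interpolation percentile of pooled monthly precipitation totals.

    Used for the extreme-month threshold (the 90th percentile of historical
    monthly rainfall pooled over cells and months).
    """
    values = np.asarray(list(monthly_totals), dtype=float)
    if values.size == 0:
        raise ValueError("empty vector of monthly totals")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"percentile q={q} outside [0, 100]")
    return float(np.percentile(values, q, method="linear"))


def _monthly_base_indices(grid: xr.DataArray) -> pd.DataFrame:
    """Vectorised per-cell monthly cumulative and Rx5day over a daily cube."""
    time = pd.DatetimeIndex(grid["time"].values)
    month_period = time.to_period("M")
    month_codes = xr.DataArray(month_period.asfreq("M").astype("int64"),
                               dims="time", coords={"time": grid["time"]})

    cumulative = grid.groupby(month_codes.rename("ym")).sum("time")

    rolling = grid.rolling(time=5).sum()
    # A 5-day window ending at t is within-month iff day t-4 shares t's month.
    same_month = np.zeros(len(time), dtype=bool)
    same_month[4:] = month_period[4:] == month_period[:-4]
    rolling = rolling.where(xr.DataArray(same_month, dims="time",
                                         coords={"time": grid["time"]}))
    rx5 = rolling.groupby(month_codes.rename("ym")).max("time")

    nlat, nlon = grid.sizes["lat"], grid.sizes["lon"]
    frames = []
    for name, arr in (("cumulative_mm", cumulative), ("rx5day_mm", rx5)):
        df = (
            arr.stack(cell=("lat", "lon"))
            .to_pandas()
            .rename_axis(index="ym")
        )
        df.columns = np.arange(nlat * nlon)  # row-major cell id
        frames.append(df.stack().rename(name))
    out = pd.concat(frames, axis=1).reset_index()
    out.columns = ["ym", "cell_id", "cumulative_mm", "rx5day_mm"]
    ym = pd.PeriodIndex.from_ordinals(out["ym"].astype("int64"), freq="M")
    out["year"] = ym.year
    out["month"] = ym.month
    return out[["cell_id", "year", "month", "cumulative_mm", "rx5day_mm"]]


def build_index_table(
    grid: xr.DataArray,
    cells: Iterable[int] | None = None,
    lags: Sequence[int] = DEFAULT_LAGS,
) -> pd.DataFrame:
    """Build the full precipitation index table from a daily grid.

    Parameters
    ----------
    grid : xr.DataArray
        Daily precipitation cube with dims (time, lat, lon), mm/day.
    cells : iterable of int, optional
        Row-major cell ids (lat index * n_lon + lon index) to keep; all cells
        by default. Unknown ids raise.
    lags : sequence of int
        Lag set in months for both base indices.

    Returns
    -------
    pd.DataFrame
        One row per (cell_id, year, month); base indices, lag columns
        (NaN where history is unavailable), squares, cubes and the
        cumulative-by-Rx5day product.
    """
    table = _monthly_base_indices(grid)
    n_cells = grid.sizes["lat"] * grid.sizes["lon"]
    if cells is not None:
        cells = sorted(set(int(c) for c in cells))
        bad = [c for c in cells if not 0 <= c < n_cells]
        if bad:
            raise ValueError(f"requested cells outside grid: {bad}")
        table = table[table["cell_id"].isin(cells)]

    table = table.sort_values(["cell_id", "year", "month"]).reset_index(drop=True)
    grouped = table.groupby("cell_id", sort=False)
    for base in BASE_INDEX_COLUMNS:
        for k in lags:
            table[f"{base}_lag{k}"] = grouped[base].shift(k)
    for base in BASE_INDEX_COLUMNS:
        table[f"{base}_sq"] = table[base] ** 2
        table[f"{base}_cube"] = table[base] ** 3
    table["cumulative_x_rx5day"] = table["cumulative_mm"] * table["rx5day_mm"]
    return table
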