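"""Synthetic facility, rainfall and ANC-count generation.

Emulates the three inputs of the disruption analysis so that every pipeline
stage is testable without restricted data:

* a facility table with the study's categorical structure (zone, district,
  urban/rural setting, ownership, type, altitude) and facilities placed
  uniformly over the grid extent;
* a daily precipitation cube on a regular lat/lon grid, drawn as a standard
  stochastic weather generator — Bernoulli wet-day occurrence with
  gamma-distributed wet-day amounts, seasonal means, plus an extreme-event
  mixture that adds a fixed burst over 1-5 consecutive days with a per-month
  probability (so Rx5day responds to it by construction);
* facility-month ANC visit counts drawn from the log-linear model the
  regression assumes, count = round(exp(X beta + noise) - eps) floored at 0,
  with known ground-truth coefficients for recovery tests;
* DHIS2-style missingness: random non-reporting at a fixed rate plus
  closure-linked gaps.

One global seed drives named substreams (facilities / precipitation / counts
/ missingness / closures), so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from . import geo
from .panel import FACILITY_TYPES, PANEL_KEY, covariate_frame, month_range

# substream labels hashed into the seed sequence
_STREAMS = {"facilities": 1, "precip": 2, "counts": 3, "missing": 4,
            "closures": 5, "altitude_mask": 6}

#: Ground-truth coefficients patterned on the study's fitted precipitation
#: model: per-year and per-month trends, urban uplift, zone and ownership
#: contrasts, altitude and distance accessibility effects, and the five
#: precipitation terms that survived selection (mm-scale units).
DEFAULT_TRUE_COEFFICIENTS = {
    "intercept": 0.30,
    "year": 0.0021,
    "month": 0.0048,
    "setting_urban": 1.3039,
    "zone_Central West": 0.1230,
    "zone_Northern": -0.5623,
    "zone_South East": 0.1036,
    "zone_South West": 0.0487,
    "owner_Government": 0.2550,
    "owner_Private": -1.8412,
    "altitude_m": 0.00005,
    "min_distance_m": 0.00003,
    "cumulative_mm": -0.0004,
    "rx5day_mm": 0.0005,
    "cumulative_mm_lag4": -0.0002,
    "cumulative_mm_lag9": -0.00006,
    "rx5day_mm_lag1": 0.0006,
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic data generator.

    Defaults emulate the study setting: 199 reporting facilities over a
    Malawi-sized quarter-degree grid, monthly records January 2011 to
    October 2024, a November-April wet season, and roughly a third of
    facility-months missing at random.
    """

    n_facilities: int = 199
    grid_extent: tuple[float, float, float, float] = (-17.0, -9.2, 32.6, 35.9)
    resolution: float = 0.25
    period: tuple[str, str] = ("2011-01", "2024-10")
    wet_season_months: frozenset[int] = frozenset({11, 12, 1, 2, 3, 4})
    mean_wet_daily_mm: float = 6.0
    mean_dry_daily_mm: float = 0.2
    extreme_event_prob: float = 0.03
    extreme_event_mm: float = 200.0
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    noise_sd: float = 0.3
    missing_rate: float = 0.35
    seed: int = 0

    # internal weather-generator shape constants (documented in the methods
    # note): wet-day occurrence probabilities per season and gamma shape
    wet_day_prob_wet_season: float = 0.65
    wet_day_prob_dry_season: float = 0.15
    gamma_shape: float = 0.9

    def __post_init__(self) -> None:
        lat_min, lat_max, lon_min, lon_max = self.grid_extent
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if lat_min >= lat_max or lon_min >= lon_max:
            raise ValueError("grid extent is degenerate (zero area)")
        for name in ("extreme_event_prob", "missing_rate",
                     "wet_day_prob_wet_season", "wet_day_prob_dry_season"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if pd.Period(self.period[0], "M") > pd.Period(self.period[1], "M"):
            raise ValueError("period start after end")
        if not set(self.wet_season_months) <= set(range(1, 13)):
            raise ValueError("wet_season_months must be month numbers 1-12")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent substream of the global seed."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray]:
        lat_min, lat_max, lon_min, lon_max = self.grid_extent
        lat = np.arange(lat_min, lat_max + 1e-9, self.resolution)
        lon = np.arange(lon_min, lon_max + 1e-9, self.resolution)
        return lat, lon


def _zone_of(lat: np.ndarray, lon: np.ndarray,
             extent: tuple[float, float, float, float]) -> np.ndarray:
    """Latitude-banded zones with an east/west longitude split, giving the
    five administrative zones mild spatial coherence without real geography."""
    lat_min, lat_max, lon_min, lon_max = extent
    lat_frac = (lat - lat_min) / (lat_max - lat_min)
    east = lon > (lon_min + lon_max) / 2
    zone = np.empty(len(lat), dtype=object)
    zone[lat_frac >= 2 / 3] = "Northern"
    mid = (lat_frac >= 1 / 3) & (lat_frac < 2 / 3)
    zone[mid & east] = "Central East"
    zone[mid & ~east] = "Central West"
    south = lat_frac < 1 / 3
    zone[south & east] = "South East"
    zone[south & ~east] = "South West"
    return zone


def generate_facilities(config: SimConfig) -> pd.DataFrame:
    """Generate the synthetic facility table, grid-assigned, with distances."""
    if config.n_facilities < 2:
        raise ValueError("need at least 2 facilities")
    rng = config.rng("facilities")
    lat_min, lat_max, lon_min, lon_max = config.grid_extent
    n = config.n_facilities
    lat = rng.uniform(lat_min, lat_max, n)
    lon = rng.uniform(lon_min, lon_max, n)
    zone = _zone_of(lat, lon, config.grid_extent)
    district = np.array(
        [f"{z} {'AB'[d]}" for z, d in zip(zone, rng.integers(0, 2, n))]
    )
    setting = rng.choice(["urban", "rural"], n, p=[0.2, 0.8])
    owner = rng.choice(["Government", "CHAM", "NGO", "Private"], n,
                       p=[0.55, 0.30, 0.05, 0.10])
    ftype = rng.choice(list(FACILITY_TYPES), n, p=[0.1, 0.5, 0.15, 0.15, 0.1])
    altitude = rng.uniform(50.0, 1600.0, n)

    facilities = pd.DataFrame(
        {
            "facility_id": [f"F{i:04d}" for i in range(n)],
            "lon": lon,
            "lat": lat,
            "zone": zone,
            "district": district,
            "setting": setting,
            "owner": owner,
            "type": ftype,
            "altitude_m": altitude,
        }
    )
    grid_lat, grid_lon = config.grid_axes()
    facilities = geo.assign_cells(facilities, grid_lat, grid_lon)
    facilities = geo.add_min_distance(facilities)
    return facilities


def mask_altitude(facilities: pd.DataFrame, config: SimConfig,
                  rate: float = 0.03) -> pd.DataFrame:
    """Blank a fraction of altitudes, emulating incomplete facility metadata.

    Applied to the *emitted* facility table only; ground-truth counts are
    always generated from complete covariates.
    """
    out = facilities.copy()
    rng = config.rng("altitude_mask")
    out.loc[rng.random(len(out)) < rate, "altitude_m"] = np.nan
    return out


def generate_precip_grid(config: SimConfig, warmup_months: int = 9) -> xr.DataArray:
    """Daily precipitation cube over the configured period plus lag warm-up.

    ``warmup_months`` extends the cube backwards so lagged indices are
    defined from the first analysis month.
    """
    grid_lat, grid_lon = config.grid_axes()
    start = pd.Period(config.period[0], "M") - warmup_months
    end = pd.Period(config.period[1], "M")
    time = pd.date_range(start.start_time, end.end_time.normalize(), freq="D")
    months = time.month
    wet = np.isin(months, list(config.wet_season_months))

    rng = config.rng("precip")
    shape = (len(time), len(grid_lat), len(grid_lon))
    p_occ = np.where(wet, config.wet_day_prob_wet_season,
                     config.wet_day_prob_dry_season)[:, None, None]
    mean_daily = np.where(wet, config.mean_wet_daily_mm,
                          config.mean_dry_daily_mm)[:, None, None]
    occurrence = rng.random(shape) < p_occ
    # gamma scale chosen so E[daily] = p_occ * shape * scale = mean_daily
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(p_occ > 0, mean_daily / (p_occ * config.gamma_shape), 0.0)
    amounts = rng.gamma(config.gamma_shape, 1.0, shape) * scale
    precip = np.where(occurrence, amounts, 0.0)

    # extreme-event mixture: per cell-month burst over 1-5 consecutive days
    if config.extreme_event_prob > 0 and config.extreme_event_mm > 0:
        period_index = pd.PeriodIndex(time, freq="M")
        for p in period_index.unique():
            day_idx = np.flatnonzero(period_index == p)
            ndays = len(day_idx)
            hit = rng.random((len(grid_lat), len(grid_lon))) < config.extreme_event_prob
            dur = rng.integers(1, 6, size=hit.shape)
            start_frac = rng.random(hit.shape)
            for ii, jj in zip(*np.nonzero(hit)):
                d = int(min(dur[ii, jj], ndays))
                s = int(start_frac[ii, jj] * (ndays - d + 1))
                precip[day_idx[s:s + d], ii, jj] += config.extreme_event_mm / d

    return xr.DataArray(
        precip,
        dims=("time", "lat", "lon"),
        coords={"time": time, "lat": grid_lat, "lon": grid_lon},
        name="precip",
        attrs={"units": "mm/day"},
    )


def linear_predictor(
    rows: pd.DataFrame,
    facilities: pd.DataFrame,
    index_table: pd.DataFrame,
    coefficients: dict[str, float],
) -> pd.Series:
    """Evaluate X beta for each key row under the ground-truth coefficients."""
    terms = [t for t in coefficients if t != "intercept"]
    joined = covariate_frame(rows, facilities, index_table, include_ngo=True)
    missing = [t for t in terms if t not in joined.columns]
    if missing:
        raise KeyError(f"true_coefficients name unknown design terms: {missing}")
    lp = pd.Series(coefficients.get("intercept", 0.0), index=joined.index)
    for term in terms:
        lp = lp + coefficients[term] * joined[term].astype(float)
    return lp


def generate_anc_counts(
    facilities: pd.DataFrame,
    index_table: pd.DataFrame,
    config: SimConfig,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Draw the complete (pre-missingness) facility-month ANC count panel.

    count = round(exp(X beta + N(0, noise_sd)) - eps), floored at 0. Raises
    if a coefficient names a term absent from the design, or if any lag term
    is undefined inside the analysis period (generate the precipitation grid
    with sufficient warm-up).
    """
    months = month_range(*config.period)
    rows = pd.DataFrame(
        [
            (fid, ym.year, ym.month)
            for fid in facilities["facility_id"]
            for ym in months
        ],
        columns=PANEL_KEY,
    )
    lp = linear_predictor(rows, facilities, index_table, config.true_coefficients)
    if lp.isna().any():
        n_bad = int(lp.isna().sum())
        raise ValueError(
            f"{n_bad} facility-months have undefined covariates (insufficient "
            "precipitation warm-up for lagged terms?)"
        )
    rng = config.rng("counts")
    noise = rng.normal(0.0, config.noise_sd, len(lp)) if config.noise_sd > 0 else 0.0
    counts = np.maximum(np.round(np.exp(lp.to_numpy() + noise) - eps), 0.0)
    panel = rows.copy()
    panel["anc_count"] = counts
    panel["missing_flag"] = False
    return panel


def generate_closures(
    facilities: pd.DataFrame, config: SimConfig, n_closures: int = 2,
    max_duration: int = 6,
) -> pd.DataFrame:
    """A small registry of confirmed facility closures inside the period."""
    rng = config.rng("closures")
    months = month_range(*config.period)
    rows = []
    n_closures = min(n_closures, len(facilities))
    chosen = rng.choice(len(facilities), size=n_closures, replace=False)
    for i in chosen:
        dur = int(rng.integers(1, max_duration + 1))
        start_i = int(rng.integers(0, len(months) - dur + 1))
        rows.append(
            {
                "facility_id": facilities["facility_id"].iloc[i],
                "start": str(months[start_i]),
                "end": str(months[start_i + dur - 1]),
                "evidence": "synthetic closure record",
            }
        )
    return pd.DataFrame(rows, columns=["facility_id", "start", "end", "evidence"])


def apply_missingness(
    panel: pd.DataFrame,
    closures: pd.DataFrame | None,
    config: SimConfig,
) -> pd.DataFrame:
    """Blank reports at random and during closures; retained values unchanged.

    Closure months become missing here (emulating DHIS2 gaps); the panel
    builder's closure rule later repairs the confirmed ones to zero.
    """
    out = panel.copy()
    rng = config.rng("missing")
    drop = rng.random(len(out)) < config.missing_rate
    if closures is not None and len(closures):
        ym = pd.PeriodIndex(
            pd.to_datetime(dict(year=out["year"], month=out["month"], day=1)),
            freq="M",
        )
        for row in closures.itertuples(index=False):
            in_range = (
                (out["facility_id"] == row.facility_id)
                & (ym >= pd.Period(row.start, "M"))
                & (ym <= pd.Period(row.end, "M"))
            )
            drop |= in_range.to_numpy()
    out.loc[drop, "anc_count"] = np.nan
    out["missing_flag"] = out["missing_flag"] | drop
    return out


def simulate_inputs(config: SimConfig, warmup_months: int = 9):
    """Convenience end-to-end simulation of all pipeline inputs.

    Returns (facilities, precip_grid, index_table, truth_panel, observed_panel,
    closures).
    """
    from .indices import build_index_table

    facilities = generate_facilities(config)
    grid = generate_precip_grid(config, warmup_months=warmup_months)
    index_table = build_index_table(grid, cells=facilities["cell_id"].unique())
    truth = generate_anc_counts(facilities, index_table, config)
    closures = generate_closures(facilities, config)
    observed = apply_missingness(truth, closures, config)
    return facilities, grid, index_table, truth, observed, closures


def scaled_config(config: SimConfig, **overrides) -> SimConfig:
    """A copy of ``config`` with fields replaced (dataclasses.replace sugar)."""
    return replace(config, **overrides)
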