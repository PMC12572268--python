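"""Scenario projection and counterfactual substitution.

The fitted model pair is re-run under substituted precipitation series: an
early-period counterfactual (the study used 1941-1953 reanalysis rainfall in
place of 2011-2024) and future scenario ensembles (SSP pathways, one grid
per ensemble member). To avoid averaging out extremes, each ensemble is
reduced to three members — the ones with the lowest, median-closest ("mean")
and highest mean monthly precipitation over all cells and months.

The extreme-month threshold is always the historical-window percentile and
is never recomputed per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .attribution import disruption_series
from .indices import index_columns
from .panel import PANEL_KEY, DesignMatrix, covariate_frame, month_range
from .regression import LogLinearRegression


@dataclass
class MemberSelection:
    lowest: str
    mean: str
    highest: str
    grand_means: dict[str, float]

    def as_dict(self) -> dict[str, str]:
        return {"lowest": self.lowest, "mean": self.mean, "highest": self.highest}


def member_mean_monthly(grid: xr.DataArray) -> float:
    """A member's mean monthly precipitation over all grid squares."""
    monthly = grid.resample(time="1ME").sum("time")
    return float(monthly.mean())


def select_ensemble_members(
    members: dict[str, xr.DataArray] | dict[str, float],
) -> MemberSelection:
    """Pick the lowest / mean / highest members of a scenario ensemble.

    ``members`` maps member name to a daily grid (or directly to a
    precomputed grand mean). The "mean" member is the one whose grand mean
    is closest to the median of the members' grand means; ties resolve to
    the lexicographically smallest name so selection is order-invariant.
    """
    if not members:
        raise ValueError("empty ensemble")
    means = {
        name: (member_mean_monthly(g) if isinstance(g, xr.DataArray) else float(g))
        for name, g in members.items()
    }
    ordered = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    lowest, highest = ordered[0][0], ordered[-1][0]
    median = float(np.median(list(means.values())))
    mean_member = min(means.items(), key=lambda kv: (abs(kv[1] - median), kv[0]))[0]
    return MemberSelection(lowest=lowest, mean=mean_member, highest=highest,
                           grand_means=means)


def remap_years(analysis_years: list[int], alt_years: list[int]) -> dict[int, int]:
    """Calendar alignment: analysis year k maps to alternative year k mod m.

    Month-of-year is preserved so seasonality survives the substitution; a
    shorter alternative record cycles.
    """
    analysis_years = sorted(set(int(y) for y in analysis_years))
    alt_years = sorted(set(int(y) for y in alt_years))
    if not alt_years:
        raise ValueError("alternative series has no years")
    return {
        y: alt_years[k % len(alt_years)] for k, y in enumerate(analysis_years)
    }


def substitute_indices(
    base_design: DesignMatrix,
    alt_indices: pd.DataFrame,
    remap_calendar: bool = True,
) -> DesignMatrix:
    """Replace every precipitation index column of a design with an
    alternative series, leaving all non-climate covariates untouched.

    Matching is on (cell_id, mapped year, month). Missing coverage raises
    with the list of gaps.
    """
    precip_cols = [c for c in index_columns() if c in base_design.data.columns]
    if not precip_cols:
        raise ValueError("design has no precipitation columns to substitute")
    absent = [c for c in precip_cols if c not in alt_indices.columns]
    if absent:
        raise ValueError(f"alternative index table lacks columns: {absent}")
    data = base_design.data.copy()
    # only lag-defined months can be substituted in; warm-up months at the
    # head of the alternative record (incomplete years) are not mapping
    # targets
    alt_indices = alt_indices.dropna(subset=precip_cols)
    months_per_year = alt_indices.groupby("year")["month"].nunique()
    complete_years = months_per_year.index[months_per_year == 12].tolist()
    if not complete_years:
        complete_years = alt_indices["year"].unique().tolist()
    if remap_calendar:
        year_map = remap_years(data["year"].unique().tolist(), complete_years)
        data["_alt_year"] = data["year"].map(year_map)
    else:
        data["_alt_year"] = data["year"]

    merged = data.merge(
        alt_indices[["cell_id", "year", "month"] + precip_cols],
        left_on=["cell_id", "_alt_year", "month"],
        right_on=["cell_id", "year", "month"],
        how="left",
        suffixes=("", "_alt"),
    )
    gap_mask = merged[[f"{c}_alt" for c in precip_cols]].isna().any(axis=1)
    if gap_mask.any():
        gaps = (
            merged.loc[gap_mask, ["cell_id", "_alt_year", "month"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(
            f"alternative series does not cover {len(gaps)} (cell, year, month) "
            f"combinations, e.g. {gaps[:5]}"
        )
    for c in precip_cols:
        merged[c] = merged[f"{c}_alt"]
    merged = merged.drop(
        columns=[f"{c}_alt" for c in precip_cols] + ["_alt_year", "year_alt"],
        errors="ignore",
    )
    return DesignMatrix(
        data=merged,
        terms=list(base_design.terms),
        response=base_design.response,
        eps=base_design.eps,
        reference_levels=dict(base_design.reference_levels),
    )


def counterfactual_run(
    m0: LogLinearRegression,
    m1: LogLinearRegression,
    alt_indices: pd.DataFrame,
    base_design: DesignMatrix,
    threshold_mm: float,
    remap_calendar: bool = True,
) -> pd.DataFrame:
    """The disruption series with the precipitation record swapped out.

    Substituting the factual series reproduces the factual run bit-for-bit;
    M0 does not see precipitation, so only M1's predictions move.
    """
    alt_design = substitute_indices(base_design, alt_indices,
                                    remap_calendar=remap_calendar)
    return disruption_series(m0, m1, alt_design, threshold_mm)


def prediction_design(
    facilities: pd.DataFrame,
    index_table: pd.DataFrame,
    period: tuple[str, str],
    terms: list[str],
    eps: float = 1.0,
    include_ngo: bool = False,
) -> DesignMatrix:
    """A response-free design over a (possibly future) period, for projection.

    Rows are all facility-months of the period with complete covariates
    (months lacking lag history are dropped, as in fitting).
    """
    months = month_range(*period)
    rows = pd.DataFrame(
        [
            (fid, ym.year, ym.month)
            for fid in facilities["facility_id"]
            for ym in months
        ],
        columns=PANEL_KEY,
    )
    joined = covariate_frame(rows, facilities, index_table, include_ngo=include_ngo)
    missing = [t for t in terms if t not in joined.columns and t not in ("year", "month")]
    if missing:
        raise KeyError(f"projection terms not constructible: {missing}")
    complete = joined.dropna(subset=terms).copy()
    complete["anc_count"] = np.nan
    complete["log_anc"] = np.nan
    keep = list(dict.fromkeys(
        PANEL_KEY + ["cell_id", "anc_count", "log_anc"] + terms
    ))
    if "cumulative_mm" not in keep and "cumulative_mm" in complete.columns:
        keep.append("cumulative_mm")
    return DesignMatrix(data=complete[keep].reset_index(drop=True),
                        terms=list(terms), eps=eps)


def percent_reduction(a: float, b: float) -> float:
    """100 x (1 - a/b): how much smaller a is than the reference b."""
    if b == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (1.0 - a / b)


def fold_change(b: float, a: float) -> float:
    """Fold difference b/a between two cumulative disruption totals."""
    if a == 0:
        raise ZeroDivisionError("denominator value is zero")
    return b / a


def scenario_summary(
    runs: dict[tuple[str, str], pd.DataFrame],
    totals: dict[tuple[str, str], float] | float,
) -> pd.DataFrame:
    """Cumulative Table-2-style summary, one row per scenario x member.

    ``runs`` maps (scenario, member-selection label) to a disruption series;
    ``totals`` supplies each run's denominator services (a scalar applies to
    all rows).
    """
    rows = []
    for (scenario, member), series in runs.items():
        deficit = series.loc[series["is_deficit"], "delta"]
        extreme = series.loc[
            series["is_deficit"] & series["is_extreme_month"], "delta"
        ]
        total = totals[(scenario, member)] if isinstance(totals, dict) else totals
        deficit_sum = float(deficit.sum())
        rows.append(
            {
                "scenario": scenario,
                "member": member,
                "deficit_services": deficit_sum,
                "total_services": float(total),
                "percent_disrupted": (
                    100.0 * deficit_sum / total if total > 0 else np.nan
                ),
                "extreme_deficit_services": float(extreme.sum()),
                "extreme_share_percent": (
                    100.0 * float(extreme.sum()) / deficit_sum
                    if deficit_sum > 0 else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
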