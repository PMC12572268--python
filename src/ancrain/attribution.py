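"""Disruption attribution from paired model predictions.

The disruption statistic is the per-facility-month difference between the
count predictions of the precipitation-free model (M0) and the precipitation
model (M1): delta = y0_hat - y1_hat. Months where M1 predicts fewer services
than M0 (delta > 0) are deficits attributed to precipitation; only those
enter the aggregates. A month is extreme-attributed when its cumulative
precipitation meets the historical percentile threshold.

Deltas are computed on the count scale after the naive exp(.) - eps
back-transform; a smearing correction is available behind a flag but off by
default since the retransformation bias largely cancels in the difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import PANEL_KEY, DesignMatrix
from .regression import LogLinearRegression


def predict_counts(
    model: LogLinearRegression, design: DesignMatrix, smearing: bool = False
) -> np.ndarray:
    """Count-scale predictions, exp(Xb) - eps floored at 0.

    With ``smearing`` the linear predictor is inflated by Duan's
    nonparametric smearing factor before back-transforming (requires the
    model to have been fitted, not deserialised, on this design's response).
    """
    lp = model.predict(design.X)
    if smearing:
        resid = design.y.to_numpy() - model.predict(design.X)
        factor = float(np.mean(np.exp(resid)))
        return np.maximum(np.exp(lp) * factor - design.eps, 0.0)
    return np.maximum(np.exp(lp) - design.eps, 0.0)


def disruption_series(
    m0: LogLinearRegression,
    m1: LogLinearRegression,
    design: DesignMatrix,
    threshold_mm: float,
    smearing: bool = False,
) -> pd.DataFrame:
    """Per-facility-month disruption: delta = y0_hat - y1_hat.

    Returns one row per design row with the panel key, both predictions,
    ``delta``, ``is_deficit`` (delta > 0) and ``is_extreme_month``
    (cumulative monthly precipitation >= threshold_mm).
    """
    if "cumulative_mm" not in design.data.columns:
        raise KeyError("design rows lack the cumulative_mm precipitation column")
    out = design.data[PANEL_KEY].copy()
    out["y0_hat"] = predict_counts(m0, design, smearing=smearing)
    out["y1_hat"] = predict_counts(m1, design, smearing=smearing)
    out["delta"] = out["y0_hat"] - out["y1_hat"]
    out["is_deficit"] = out["delta"] > 0
    out["is_extreme_month"] = (
        design.data["cumulative_mm"].to_numpy() >= threshold_mm
    )
    return out


def deficit_filter(series: pd.DataFrame, mode: str = "drop") -> pd.DataFrame:
    """Restrict the disruption series to deficit months.

    mode='drop' removes surplus rows; mode='zero' keeps them with delta set
    to 0 so monthly coverage is preserved for plotting.
    """
    if mode == "drop":
        return series[series["is_deficit"]].reset_index(drop=True)
    if mode == "zero":
        out = series.copy()
        out.loc[~out["is_deficit"], "delta"] = 0.0
        return out
    raise ValueError(f"unknown deficit filter mode {mode!r}")


def aggregate_disruption(
    series: pd.DataFrame,
    total_services: pd.Series | float,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate deficit services into percentages and extreme-event shares.

    Parameters
    ----------
    series : pd.DataFrame
        A disruption series (filtered or not; only deficit rows count).
    total_services : pd.Series or float
        Denominator services per group (indexed by the group key) or a
        single national total.
    by : list of str, optional
        Grouping columns (e.g. ``["district"]`` after merging facility
        metadata); national aggregate when omitted.

    Returns
    -------
    pd.DataFrame with columns: group key (if any), deficit_services,
    total_services, percent_disrupted, extreme_deficit_services,
    extreme_share_percent. Zero-total groups carry NaN percent and a
    ``percent_undefined`` flag.
    """
    deficits = series[series["is_deficit"]]
    if by:
        grouped = deficits.groupby(by)
        agg = pd.DataFrame(
            {
                "deficit_services": grouped["delta"].sum(),
                "extreme_deficit_services": grouped.apply(
                    lambda g: g.loc[g["is_extreme_month"], "delta"].sum(),
                    include_groups=False,
                ),
            }
        )
        totals = pd.Series(total_services)
        agg["total_services"] = totals.reindex(agg.index)
    else:
        agg = pd.DataFrame(
            {
                "deficit_services": [deficits["delta"].sum()],
                "extreme_deficit_services": [
                    deficits.loc[deficits["is_extreme_month"], "delta"].sum()
                ],
                "total_services": [float(np.sum(total_services))],
            }
        )
    agg["percent_disrupted"] = np.where(
        agg["total_services"] > 0,
        100.0 * agg["deficit_services"] / agg["total_services"],
        np.nan,
    )
    agg["percent_undefined"] = ~(agg["total_services"] > 0)
    agg["extreme_share_percent"] = np.where(
        agg["deficit_services"] > 0,
        100.0 * agg["extreme_deficit_services"] / agg["deficit_services"],
        0.0,
    )
    return agg.reset_index() if by else agg


def affected_pregnancies(
    deficit_services: float,
    visits_per_pregnancy: float = 4.4,
    mode: str = "per-pregnancy",
) -> float:
    """Convert disrupted ANC visits into affected pregnancies.

    mode='per-pregnancy' divides by the visits-per-pregnancy rate (4.4 visits
    per live birth by default); mode='per-visit' counts each disrupted visit
    as one affected pregnancy. Both conventions appear in the literature and
    neither is asserted as canonical; see the methods note.
    """
    if deficit_services < 0:
        raise ValueError("deficit_services must be nonnegative")
    if visits_per_pregnancy <= 0:
        raise ValueError("visits_per_pregnancy must be positive")
    if mode == "per-pregnancy":
        return deficit_services / visits_per_pregnancy
    if mode == "per-visit":
        return float(deficit_services)
    raise ValueError(f"unknown pregnancy conversion mode {mode!r}")
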