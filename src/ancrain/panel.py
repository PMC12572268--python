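"""Panel cleaning and design-matrix assembly for the ANC disruption models.

The facility-month panel of antenatal-care (ANC) visit counts is cleaned with
the study's rules — facilities with more than a sparsity threshold of missing
reports are dropped, confirmed facility closures turn missing reports into
true zeros, remaining missingness is treated as random non-reporting and the
rows excluded from fitting — and joined with facility covariates and the
precipitation index table into the regression design matrix with response
log(count + eps), eps = 1 by default so that zero-count months are usable.

Reference levels follow the study's encoding: rural setting, Central East
zone, CHAM ownership. The NGO ownership level is accepted on input and, by
default, absorbed into the reference along with CHAM; set ``include_ngo`` to
give it its own indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

ZONES = ("Northern", "Central East", "Central West", "South East", "South West")
OWNERS = ("Government", "CHAM", "NGO", "Private")
SETTINGS = ("urban", "rural")
FACILITY_TYPES = (
    "Dispensary", "Health Centre", "Clinic",
    "Rural/Community Hospital", "District Hospital",
)

REFERENCE_LEVELS = {"setting": "rural", "zone": "Central East", "owner": "CHAM"}

#: Covariate terms of the precipitation-free model M0 (plus intercept).
M0_TERMS = [
    "year", "month",
    "setting_urban",
    "zone_Central West", "zone_Northern", "zone_South East", "zone_South West",
    "owner_Government", "owner_Private",
    "altitude_m", "min_distance_m",
]

PANEL_KEY = ["facility_id", "year", "month"]


@dataclass
class DesignMatrix:
    """A fitted-ready design: covariate columns, response, and metadata.

    ``data`` holds one row per retained facility-month with the key columns,
    ``cell_id``, the response, every term column, and ``cumulative_mm``
    (always carried for extreme-month flagging even when not a model term).
    """

    data: pd.DataFrame
    terms: list[str]
    response: str = "log_anc"
    eps: float = 1.0
    reference_levels: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.terms]

    @property
    def y(self) -> pd.Series:
        return self.data[self.response]

    def __len__(self) -> int:
        return len(self.data)


def month_range(start: str, end: str) -> pd.PeriodIndex:
    """Inclusive month range from 'YYYY-MM' strings."""
    start_p, end_p = pd.Period(start, "M"), pd.Period(end, "M")
    if start_p > end_p:
        raise ValueError(f"period start {start} after end {end}")
    return pd.period_range(start_p, end_p, freq="M")


def exclude_sparse_facilities(panel: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Drop facilities whose missing-report fraction strictly exceeds ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = panel.groupby("facility_id")["missing_flag"].mean()
    keep = frac.index[frac <= threshold]
    return panel[panel["facility_id"].isin(keep)].reset_index(drop=True)


def apply_closure_zeros(panel: pd.DataFrame, closures: pd.DataFrame) -> pd.DataFrame:
    """Convert missing reports during confirmed closures into zero counts.

    A missing facility-month inside a confirmed closure range means no
    services were delivered, so it becomes an observed 0; an observed count
    inside a closure is left alone (observed data wins); missing months
    outside any closure stay missing (random non-reporting).
    """
    out = panel.copy()
    if closures is None or len(closures) == 0:
        return out
    known = set(out["facility_id"].unique())
    ym = pd.PeriodIndex(
        pd.to_datetime(dict(year=out["year"], month=out["month"], day=1)), freq="M"
    )
    for row in closures.itertuples(index=False):
        if row.facility_id not in known:
            warnings.warn(
                f"closure for unknown facility {row.facility_id!r} skipped",
                stacklevel=2,
            )
            continue
        start, end = pd.Period(row.start, "M"), pd.Period(row.end, "M")
        mask = (
            (out["facility_id"] == row.facility_id)
            & (ym >= start) & (ym <= end)
            & out["missing_flag"]
        )
        out.loc[mask, "anc_count"] = 0
        out.loc[mask, "missing_flag"] = False
    return out


def impute_altitude(facilities: pd.DataFrame) -> pd.DataFrame:
    """Fill missing altitudes with the mean of the observed altitudes."""
    out = facilities.copy()
    observed = out["altitude_m"].dropna()
    if observed.empty:
        raise ValueError("no facility has an observed altitude")
    out["altitude_m"] = out["altitude_m"].fillna(observed.mean())
    return out


def cramers_v(x: pd.Series, y: pd.Series) -> float:
    """Cramér's V association between two categorical variables."""
    table = pd.crosstab(x, y)
    if table.size == 0:
        return float("nan")
    chi2 = chi2_contingency(table, correction=False)[0]
    n = table.to_numpy().sum()
    r, k = table.shape
    denom = n * (min(r, k) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else 0.0


def _association(facilities: pd.DataFrame, a: str, b: str) -> float:
    xa, xb = facilities[a], facilities[b]
    a_num = pd.api.types.is_numeric_dtype(xa)
    b_num = pd.api.types.is_numeric_dtype(xb)
    if a_num and b_num:
        return float(abs(xa.corr(xb)))
    if not a_num and not b_num:
        return cramers_v(xa, xb)
    cat, num = (xa, xb) if b_num else (xb, xa)
    # correlation ratio (eta) for a categorical-numeric pair
    grand = num.mean()
    between = sum(len(g) * (g.mean() - grand) ** 2 for _, g in num.groupby(cat))
    total = ((num - grand) ** 2).sum()
    return float(np.sqrt(between / total)) if total > 0 else 0.0


def collinearity_screen(
    facilities: pd.DataFrame,
    pairs: list[tuple[str, str]],
    threshold: float = 0.7,
) -> tuple[list[str], dict[tuple[str, str], float]]:
    """Drop the second member of each highly associated covariate pair.

    Mirrors the study's screen: facility type was dropped for its correlation
    with ownership, and district for its nesting within zone. Association is
    Cramér's V for categorical pairs, |Pearson r| for numeric pairs and the
    correlation ratio for mixed pairs.

    Returns the kept covariates (from the union of pair members, order
    preserved) and the measured association per pair.
    """
    associations: dict[tuple[str, str], float] = {}
    dropped: set[str] = set()
    for first, second in pairs:
        v = _association(facilities, first, second)
        associations[(first, second)] = v
        if v > threshold:
            dropped.add(second)
    kept: list[str] = []
    for first, second in pairs:
        for name in (first, second):
            if name not in dropped and name not in kept:
                kept.append(name)
    return kept, associations


def encode_facility_covariates(
    facilities: pd.DataFrame, include_ngo: bool = False
) -> pd.DataFrame:
    """One-hot facility covariates at the study's reference levels.

    Indexed by facility_id; includes cell_id when present so precipitation
    indices can be joined downstream.
    """
    enc = pd.DataFrame(index=facilities["facility_id"])
    enc["setting_urban"] = (
        facilities["setting"].str.lower().eq("urban").astype(float).to_numpy()
    )
    for zone in ZONES:
        if zone == REFERENCE_LEVELS["zone"]:
            continue
        enc[f"zone_{zone}"] = facilities["zone"].eq(zone).astype(float).to_numpy()
    owner_levels = ["Government", "Private"] + (["NGO"] if include_ngo else [])
    for owner in owner_levels:
        enc[f"owner_{owner}"] = facilities["owner"].eq(owner).astype(float).to_numpy()
    enc["altitude_m"] = facilities["altitude_m"].to_numpy(dtype=float)
    enc["min_distance_m"] = facilities["min_distance_m"].to_numpy(dtype=float)
    if "cell_id" in facilities.columns:
        enc["cell_id"] = facilities["cell_id"].to_numpy()
    return enc


def covariate_frame(
    rows: pd.DataFrame,
    facilities: pd.DataFrame,
    index_table: pd.DataFrame,
    include_ngo: bool = False,
) -> pd.DataFrame:
    """Join facility covariates and precipitation indices onto key rows.

    ``rows`` needs the panel key columns; the facility table needs cell_id
    and min_distance_m already assigned.
    """
    if "cell_id" not in facilities.columns:
        raise ValueError("facilities need a cell_id column (run grid assignment first)")
    enc = encode_facility_covariates(facilities, include_ngo=include_ngo)
    out = rows.merge(enc, left_on="facility_id", right_index=True, how="left")
    out = out.merge(index_table, on=["cell_id", "year", "month"], how="left")
    return out


def assemble_design(
    panel: pd.DataFrame,
    facilities: pd.DataFrame,
    index_table: pd.DataFrame,
    precip_terms: list[str] | None = None,
    eps: float = 1.0,
    include_ngo: bool = False,
    fixed_terms: list[str] | None = None,
) -> DesignMatrix:
    """Assemble the regression design from panel, covariates and indices.

    Retains fully observed facility-months only: missing reports and months
    whose lagged precipitation history is undefined are excluded. Response is
    log(anc_count + eps).
    """
    terms = list(M0_TERMS if fixed_terms is None else fixed_terms)
    if include_ngo and "owner_NGO" not in terms:
        terms.append("owner_NGO")
    precip_terms = list(precip_terms or [])
    terms = terms + [t for t in precip_terms if t not in terms]

    observed = panel[~panel["missing_flag"]].copy()
    joined = covariate_frame(observed, facilities, index_table, include_ngo=include_ngo)

    missing_terms = [t for t in terms if t not in joined.columns and t not in ("year", "month")]
    if missing_terms:
        raise KeyError(
            f"terms not constructible from the provided tables: {missing_terms}"
        )
    complete = joined.dropna(subset=terms + ["anc_count"]).copy()
    complete["log_anc"] = np.log(complete["anc_count"].astype(float) + eps)

    # an indicator level with no variation in the retained rows (no facility
    # at that level, or all of them) carries no contrast and is absorbed
    # into the reference
    onehot_prefixes = ("setting_", "zone_", "owner_")
    empty = [
        t for t in terms
        if t.startswith(onehot_prefixes) and complete[t].nunique() < 2
    ]
    if empty:
        warnings.warn(
            f"dropping structurally constant indicator terms: {empty}",
            stacklevel=2,
        )
        terms = [t for t in terms if t not in empty]

    keep_cols = list(dict.fromkeys(
        PANEL_KEY + ["cell_id", "anc_count", "log_anc"] + terms
    ))
    if "cumulative_mm" not in keep_cols and "cumulative_mm" in complete.columns:
        keep_cols.append("cumulative_mm")
    data = complete[keep_cols].reset_index(drop=True)
    return DesignMatrix(data=data, terms=terms, eps=eps)
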