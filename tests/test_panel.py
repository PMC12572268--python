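"""Panel cleaning rules and design-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from ancrain.panel import (
    M0_TERMS,
    apply_closure_zeros,
    assemble_design,
    collinearity_screen,
    exclude_sparse_facilities,
    impute_altitude,
)


def _panel(rows):
    df = pd.DataFrame(rows, columns=["facility_id", "year", "month", "anc_count"])
    df["missing_flag"] = df["anc_count"].isna()
    return df


class TestExcludeSparse:
    def test_fully_missing_dropped(self):
        panel = _panel(
            [("A", 2020, m, np.nan) for m in range(1, 11)]
            + [("B", 2020, m, 5) for m in range(1, 11)]
        )
        out = exclude_sparse_facilities(panel, 0.9)
        assert set(out["facility_id"]) == {"B"}

    def test_exactly_at_threshold_retained(self):
        """The rule is strict: drop only when missing fraction > threshold."""
        rows = [("A", 2020, m, np.nan) for m in range(1, 10)] + [("A", 2020, 10, 5)]
        out = exclude_sparse_facilities(_panel(rows), 0.9)
        assert set(out["facility_id"]) == {"A"}

    def test_known_fractions_hand_count(self, rng):
        rows = []
        missing_per_facility = {f"F{i}": i for i in range(10)}  # i of 10 missing
        for fid, n_missing in missing_per_facility.items():
            for m in range(1, 11):
                rows.append((fid, 2020, m, np.nan if m <= n_missing else 3))
        out = exclude_sparse_facilities(_panel(rows), 0.85)
        survivors = {f for f, n in missing_per_facility.items() if n / 10 <= 0.85}
        assert set(out["facility_id"]) == survivors

    def test_idempotent(self, tiny_world):
        once = exclude_sparse_facilities(tiny_world["observed"], 0.5)
        twice = exclude_sparse_facilities(once, 0.5)
        pd.testing.assert_frame_equal(once, twice)


class TestClosureZeros:
    @pytest.fixture()
    def panel(self):
        return _panel(
            [
                ("A", 2023, 1, 40.0),
                ("A", 2023, 2, np.nan),
                ("A", 2023, 3, np.nan),
                ("A", 2023, 4, np.nan),
                ("B", 2023, 2, np.nan),
            ]
        )

    @pytest.fixture()
    def closures(self):
        return pd.DataFrame(
            [{"facility_id": "A", "start": "2023-01", "end": "2023-03",
              "evidence": "news report"}]
        )

    def test_missing_inside_closure_becomes_zero(self, panel, closures):
        out = apply_closure_zeros(panel, closures)
        feb = out.query("facility_id == 'A' and month == 2")
        assert feb["anc_count"].iloc[0] == 0
        assert not feb["missing_flag"].iloc[0]

    def test_observed_data_wins_inside_closure(self, panel, closures):
        out = apply_closure_zeros(panel, closures)
        jan = out.query("facility_id == 'A' and month == 1")
        assert jan["anc_count"].iloc[0] == 40.0

    def test_missing_outside_closure_stays_missing(self, panel, closures):
        out = apply_closure_zeros(panel, closures)
        assert out.query("facility_id == 'A' and month == 4")["missing_flag"].iloc[0]
        assert out.query("facility_id == 'B'")["missing_flag"].iloc[0]

    def test_unknown_facility_warned_and_skipped(self, panel):
        closures = pd.DataFrame(
            [{"facility_id": "ZZZ", "start": "2023-01", "end": "2023-02",
              "evidence": ""}]
        )
        with pytest.warns(UserWarning, match="ZZZ"):
            out = apply_closure_zeros(panel, closures)
        pd.testing.assert_frame_equal(out, panel)


class TestImputeAltitude:
    def _facilities(self, altitudes):
        return pd.DataFrame(
            {"facility_id": [f"F{i}" for i in range(len(altitudes))],
             "altitude_m": altitudes}
        )

    def test_mean_imputation(self):
        out = impute_altitude(self._facilities([100.0, 300.0, np.nan]))
        assert out["altitude_m"].tolist() == [100.0, 300.0, 200.0]

    def test_no_missing_unchanged(self):
        table = self._facilities([10.0, 20.0])
        pd.testing.assert_frame_equal(impute_altitude(table), table)

    def test_single_observed_fills_all(self):
        out = impute_altitude(self._facilities([500.0, np.nan, np.nan, np.nan]))
        assert (out["altitude_m"] == 500.0).all()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_altitude(self._facilities([np.nan, np.nan]))


class TestCollinearityScreen:
    def test_perfectly_confounded_pair_drops_second(self, rng):
        owners = rng.choice(["Government", "CHAM"], 200)
        table = pd.DataFrame(
            {"owner": owners,
             "type": np.where(owners == "Government", "Health Centre", "Clinic")}
        )
        kept, assoc = collinearity_screen(table, [("owner", "type")])
        assert kept == ["owner"]
        assert assoc[("owner", "type")] == pytest.approx(1.0)

    def test_nested_zone_district_drops_district(self, tiny_world):
        facilities = tiny_world["facilities"]
        kept, assoc = collinearity_screen(facilities, [("zone", "district")])
        assert "district" not in kept
        assert assoc[("zone", "district")] > 0.7

    def test_independent_covariates_kept(self, rng):
        table = pd.DataFrame(
            {"a": rng.choice(["x", "y"], 500), "b": rng.choice(["p", "q"], 500)}
        )
        kept, _ = collinearity_screen(table, [("a", "b")])
        assert kept == ["a", "b"]


class TestAssembleDesign:
    def test_zero_count_gives_zero_response(self, tiny_world):
        panel = tiny_world["truth"].copy()
        panel.loc[0, "anc_count"] = 0.0
        design = assemble_design(
            panel, tiny_world["facilities"], tiny_world["index_table"]
        )
        key = panel.loc[0, ["facility_id", "year", "month"]]
        row = design.data.query(
            "facility_id == @key.facility_id and year == @key.year "
            "and month == @key.month"
        )
        assert row["log_anc"].iloc[0] == 0.0

    def test_one_hot_encoding_of_non_reference_levels(self, tiny_world):
        facilities = tiny_world["facilities"].copy()
        facilities.loc[0, ["setting", "owner", "zone"]] = (
            "urban", "Government", "Northern"
        )
        design = assemble_design(
            tiny_world["truth"], facilities, tiny_world["index_table"]
        )
        fid = facilities.loc[0, "facility_id"]
        rows = design.data[design.data["facility_id"] == fid]
        assert (rows["setting_urban"] == 1.0).all()
        assert (rows["owner_Government"] == 1.0).all()
        assert (rows["zone_Northern"] == 1.0).all()
        assert (rows["zone_Central West"] == 0.0).all()
        # one-hot groups sum to at most one per row
        zone_cols = [c for c in design.terms if c.startswith("zone_")]
        assert (design.data[zone_cols].sum(axis=1) <= 1.0).all()

    def test_back_transform_recovers_counts_exactly(self, tiny_design):
        counts = np.exp(tiny_design.y) - tiny_design.eps
        np.testing.assert_allclose(
            counts, tiny_design.data["anc_count"], atol=1e-9
        )

    def test_row_count_matches_independent_enumeration(self, tiny_world):
        """Design rows = observed reports whose lag history is defined."""
        from ancrain.indices import index_columns

        observed = tiny_world["observed"]
        design = assemble_design(
            observed, tiny_world["facilities"], tiny_world["index_table"],
            precip_terms=index_columns(),
        )
        # independent count: non-missing rows, all months (warm-up covered
        # the lags, so no row is lost to undefined history)
        fac = tiny_world["facilities"][["facility_id", "cell_id"]]
        idx = tiny_world["index_table"].dropna()
        merged = observed[~observed["missing_flag"]].merge(fac).merge(
            idx[["cell_id", "year", "month"]], on=["cell_id", "year", "month"]
        )
        assert len(design) == len(merged)

    def test_lag_undefined_rows_dropped_not_zero_filled(self, tiny_world):
        """Without warm-up months the first max-lag months disappear."""
        grid = tiny_world["grid"]
        from ancrain.indices import build_index_table, index_columns

        # truncate the grid to the analysis period (no warm-up)
        start = "2011-01-01"
        truncated = grid.sel(time=slice(start, None))
        table = build_index_table(truncated)
        design = assemble_design(
            tiny_world["truth"], tiny_world["facilities"], table,
            precip_terms=index_columns(),
        )
        early = design.data.query("year == 2011 and month <= 9")
        assert len(early) == 0

    def test_unknown_term_rejected_by_name(self, tiny_world):
        with pytest.raises(KeyError, match="bogus_term"):
            assemble_design(
                tiny_world["truth"], tiny_world["facilities"],
                tiny_world["index_table"], precip_terms=["bogus_term"],
            )

    def test_m0_terms_present(self, tiny_design):
        assert set(M0_TERMS) <= set(tiny_design.terms)
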