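"""Ensemble member selection, counterfactual substitution, summaries."""

import numpy as np
import pandas as pd
import pytest

from ancrain.attribution import disruption_series

from ancrain.panel import M0_TERMS, assemble_design
from ancrain.regression import LogLinearRegression
from ancrain.scenarios import (
    counterfactual_run,
    fold_change,
    percent_reduction,
    remap_years,
    scenario_summary,
    select_ensemble_members,
    substitute_indices,
)
from ancrain.synthetic import generate_precip_grid, scaled_config


class TestSelectEnsembleMembers:
    def test_single_member_fills_all_roles(self):
        sel = select_ensemble_members({"only": 4.2})
        assert sel.lowest == sel.mean == sel.highest == "only"

    def test_three_members_direct_ordering(self):
        sel = select_ensemble_members({"a": 5.0, "b": 2.0, "c": 9.0})
        assert (sel.lowest, sel.mean, sel.highest) == ("b", "a", "c")

    def test_permutation_invariant(self):
        means = {"m1": 3.0, "m2": 7.5, "m3": 1.2, "m4": 9.9}
        base = select_ensemble_members(means)
        shuffled = select_ensemble_members(dict(reversed(list(means.items()))))
        assert base.as_dict() == shuffled.as_dict()

    def test_grand_mean_from_grid(self, tiny_sim):
        """Member means computed from grids order the same as raw means."""
        wet = generate_precip_grid(
            scaled_config(tiny_sim, mean_wet_daily_mm=12.0), warmup_months=0
        )
        dry = generate_precip_grid(
            scaled_config(tiny_sim, mean_wet_daily_mm=2.0, seed=99),
            warmup_months=0,
        )
        sel = select_ensemble_members({"wet": wet, "dry": dry})
        assert sel.lowest == "dry" and sel.highest == "wet"

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            select_ensemble_members({})


class TestRemapYears:
    def test_cycling_alignment(self):
        mapping = remap_years([2011, 2012, 2013, 2014], [1941, 1942, 1943])
        assert mapping == {2011: 1941, 2012: 1942, 2013: 1943, 2014: 1941}

    def test_identity_when_same_years(self):
        years = [2011, 2012]
        assert remap_years(years, years) == {2011: 2011, 2012: 2012}


@pytest.fixture(scope="module")
def fitted_world(tiny_world):
    """A fitted model pair on the tiny world, with a known M1 term set."""
    precip_terms = ["cumulative_mm", "rx5day_mm", "cumulative_mm_lag1"]
    design = assemble_design(
        tiny_world["observed"], tiny_world["facilities"],
        tiny_world["index_table"], precip_terms=precip_terms,
    )
    m0 = LogLinearRegression().fit(design.X[M0_TERMS], design.y)
    m1 = LogLinearRegression().fit(design.X, design.y)
    return design, m0, m1


class TestSubstitution:
    def test_identity_with_factual_series(self, tiny_world, fitted_world,
                                          extreme_threshold):
        design, m0, m1 = fitted_world
        factual = disruption_series(m0, m1, design, extreme_threshold)
        substituted = counterfactual_run(
            m0, m1, tiny_world["index_table"], design, extreme_threshold
        )
        pd.testing.assert_frame_equal(factual, substituted)

    def test_zero_precipitation_removes_deficits(self, tiny_world, fitted_world,
                                                 extreme_threshold):
        """With all-zero rainfall and deficit-signed coefficients, the
        precipitation model predicts no shortfall."""
        design, m0, _ = fitted_world
        # a model with only a negative cumulative coefficient
        m1_neg = LogLinearRegression.from_dict(
            {
                "eps": 1.0,
                "terms": list(m0.terms_) + ["cumulative_mm"],
                "coef": {**m0.coef_.to_dict(), "cumulative_mm": -0.0004},
                "bse": {**m0.bse_.to_dict(), "cumulative_mm": 0.0},
                "pvalues": {**m0.pvalues_.to_dict(), "cumulative_mm": 0.0},
                "loglik": m0.loglik_, "aic": m0.aic_, "nobs": m0.nobs_,
                "rsquared_adj": m0.rsquared_adj_,
            }
        )
        zero = tiny_world["index_table"].copy()
        numeric = [c for c in zero.columns if c not in ("cell_id", "year", "month")]
        zero[numeric] = 0.0
        series = counterfactual_run(m0, m1_neg, zero, design, extreme_threshold)
        assert not series["is_deficit"].any()
        np.testing.assert_allclose(series["delta"], 0.0, atol=1e-9)

    def test_halved_precipitation_decreases_deficits(self, tiny_world,
                                                     fitted_world,
                                                     extreme_threshold):
        design, m0, _ = fitted_world
        m1_neg = LogLinearRegression.from_dict(
            {
                "eps": 1.0,
                "terms": list(m0.terms_) + ["cumulative_mm"],
                "coef": {**m0.coef_.to_dict(), "cumulative_mm": -0.0004},
                "bse": {**m0.bse_.to_dict(), "cumulative_mm": 0.0},
                "pvalues": {**m0.pvalues_.to_dict(), "cumulative_mm": 0.0},
                "loglik": m0.loglik_, "aic": m0.aic_, "nobs": m0.nobs_,
                "rsquared_adj": m0.rsquared_adj_,
            }
        )
        full = counterfactual_run(
            m0, m1_neg, tiny_world["index_table"], design, extreme_threshold
        )
        halved_table = tiny_world["index_table"].copy()
        numeric = [
            c for c in halved_table.columns
            if c not in ("cell_id", "year", "month")
        ]
        halved_table[numeric] = halved_table[numeric] * 0.5
        halved = counterfactual_run(
            m0, m1_neg, halved_table, design, extreme_threshold
        )
        assert halved["delta"].sum() < full["delta"].sum()
        assert (halved["delta"] <= full["delta"] + 1e-9).all()

    def test_incomplete_coverage_rejected(self, tiny_world, fitted_world,
                                          extreme_threshold):
        design, m0, m1 = fitted_world
        partial = tiny_world["index_table"]
        partial = partial[partial["cell_id"] != design.data["cell_id"].iloc[0]]
        with pytest.raises(ValueError, match="does not cover"):
            substitute_indices(design, partial)


class TestScenarioSummary:
    def _series(self, deltas, extreme):
        return pd.DataFrame(
            {
                "delta": deltas,
                "is_deficit": np.asarray(deltas) > 0,
                "is_extreme_month": extreme,
            }
        )

    def test_reduction_and_fold_change_arithmetic(self):
        """The counterfactual-vs-historical contrast: 414 vs 65,703 deficit
        services is a ~99.4% reduction and a >100-fold difference."""
        reduction = percent_reduction(414.0, 65703.0)
        assert reduction == pytest.approx(99.37, abs=0.01)
        assert fold_change(65703.0, 414.0) == pytest.approx(158.7, abs=0.05)
        assert fold_change(65703.0, 414.0) >= 100.0

    def test_identical_runs_zero_reduction(self):
        assert percent_reduction(123.0, 123.0) == 0.0

    def test_reciprocal_fold_change(self):
        assert fold_change(10.0, 40.0) == pytest.approx(1 / fold_change(40.0, 10.0))

    def test_summary_rows_and_shares(self):
        runs = {
            ("historical", "n/a"): self._series([10.0, -5.0, 6.0],
                                                [True, False, False]),
            ("ssp245", "mean"): self._series([4.0], [True]),
        }
        out = scenario_summary(runs, 1000.0)
        assert len(out) == 2
        hist = out[out["scenario"] == "historical"].iloc[0]
        assert hist["deficit_services"] == 16.0
        assert hist["percent_disrupted"] == pytest.approx(1.6)
        assert hist["extreme_share_percent"] == pytest.approx(100 * 10 / 16)
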