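"""Shared fixtures: a small synthetic world reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ancrain.indices import index_columns, percentile_threshold
from ancrain.panel import M0_TERMS, assemble_design
from ancrain.regression import BackwardStepwiseSelector, LogLinearRegression
from ancrain.synthetic import SimConfig, simulate_inputs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_sim() -> SimConfig:
    """A small but fully featured study configuration."""
    return SimConfig(
        n_facilities=20,
        grid_extent=(-14.0, -12.0, 33.0, 34.5),
        resolution=0.5,
        period=("2011-01", "2013-12"),
        seed=1,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_sim):
    facilities, grid, index_table, truth, observed, closures = simulate_inputs(
        tiny_sim
    )
    return {
        "config": tiny_sim,
        "facilities": facilities,
        "grid": grid,
        "index_table": index_table,
        "truth": truth,
        "observed": observed,
        "closures": closures,
    }


@pytest.fixture(scope="session")
def tiny_design(tiny_world):
    return assemble_design(
        tiny_world["observed"],
        tiny_world["facilities"],
        tiny_world["index_table"],
        precip_terms=index_columns(),
    )


@pytest.fixture(scope="session")
def fitted_pair(tiny_design):
    design = tiny_design
    m0 = LogLinearRegression().fit(design.X[M0_TERMS], design.y)
    selector = BackwardStepwiseSelector(
        fixed_terms=M0_TERMS, candidate_terms=index_columns()
    ).fit(design.X, design.y)
    return m0, selector.model_, selector


@pytest.fixture(scope="session")
def extreme_threshold(tiny_world) -> float:
    return percentile_threshold(
        tiny_world["index_table"]["cumulative_mm"].dropna(), 90.0
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
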