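"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def did_2x2_rows() -> pd.DataFrame:
    """Canonical 2x2 design: treated county drops 1.0 -> 0.7, control
    1.0 -> 0.9; difference-in-differences of means is exactly -0.2."""
    return pd.DataFrame(
        {
            "county_id": ["A", "A", "B", "B"],
            "state_id": ["S1", "S1", "S1", "S1"],
            "year": [1, 2, 1, 2],
            "outcome": [1.0, 0.7, 1.0, 0.9],
            "treat_lag": [0, 1, 0, 0],
            "group_year": [2, 2, 0, 0],
        }
    )


def _random_small_rows(rng: np.random.Generator) -> pd.DataFrame:
    """A small random staggered panel with never-treated counties."""
    n_states = rng.integers(2, 4)
    n_counties = int(rng.integers(4, 9))
    n_years = int(rng.integers(4, 7))
    years = np.arange(2000, 2000 + n_years)
    recs = []
    # at least one never-treated county per draw
    start_years = [0] + [
        int(rng.choice([0, *years[1:]])) for _ in range(n_counties - 1)
    ]
    rng.shuffle(start_years)
    if all(s == 0 for s in start_years):
        start_years[0] = int(years[1])
    if all(s != 0 for s in start_years):
        start_years[0] = 0
    for i in range(n_counties):
        state = f"S{i % n_states}"
        g = start_years[i]
        for y in years:
            recs.append(
                {
                    "county_id": f"C{i}",
                    "state_id": state,
                    "year": int(y),
                    "treat_lag": int(g != 0 and y >= g),
                    "group_year": g,
                    "outcome": float(rng.normal()),
                    "x1": float(rng.normal()),
                    "x2": float(rng.normal()),
                }
            )
    return pd.DataFrame(recs)


@pytest.fixture
def random_rows_factory():
    return _random_small_rows


def dummy_ols(
    rows: pd.DataFrame,
    covariates: list[str],
    county_trends: bool,
) -> dict[str, float]:
    """Brute-force oracle: full dummy-variable OLS for the TWFE models.

    Builds explicit county dummies, state-year dummies and (optionally)
    county x time interactions and solves by least squares.  Independent of
    the absorption path it checks.
    """
    y = rows["outcome"].to_numpy(dtype=float)
    cols = [rows["treat_lag"].to_numpy(dtype=float)]
    names = ["treat_lag"]
    for c in covariates:
        cols.append(rows[c].to_numpy(dtype=float))
        names.append(c)
    county = pd.get_dummies(rows["county_id"], dtype=float)
    sy = pd.get_dummies(
        rows["state_id"].astype(str) + ":" + rows["year"].astype(str), dtype=float
    )
    X = np.column_stack(cols + [county.to_numpy(), sy.to_numpy()])
    if county_trends:
        t = rows["year"].to_numpy(dtype=float)
        t = t - t.min()
        X = np.column_stack([X, county.to_numpy() * t[:, None]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return dict(zip(names, beta[: len(names)]))


@pytest.fixture
def dummy_ols_oracle():
    return dummy_ols


def hc0_vcov(X: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Heteroskedasticity-robust (HC0) covariance, written out directly."""
    bread = np.linalg.inv(X.T @ X)
    meat = (X * resid[:, None] ** 2).T @ X
    return bread @ meat @ bread


@pytest.fixture
def hc0_oracle():
    return hc0_vcov
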