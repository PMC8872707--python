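"""From raw county-year records to analysis-ready regression rows.

Covers rate construction (births per 1,000 women by age), the log(1+R)
outcome transform, one-year lagging of treatment and covariates (a
conception started in the funding year is carried to term the next year),
linear interpolation/extrapolation of the sparsely observed
abortion-provider distance, and the ordered sample-exclusion filters that
define the analytic set of counties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .synthetic_panel import (
    AGES,
    BIRTH_COLUMNS,
    COVARIATE_COLUMNS,
    POP_COLUMNS,
)

__all__ = [
    "FilterCriteria",
    "FilterReport",
    "compute_rate",
    "transform_outcome",
    "interpolate_sparse_covariate",
    "apply_sample_filters",
    "build_analysis_rows",
]

SPARSE_COLUMNS = ("abortion_distance",)


def compute_rate(births: float, population: float) -> float:
    """Births per 1,000 women: ``1000 * births / population``."""
    if population <= 0:
        raise ValueError("population must be positive (zero-population county-years "
                         "are excluded by the sample filters)")
    if births < 0:
        raise ValueError("births must be non-negative")
    return 1000.0 * births / population


def transform_outcome(rate: float) -> float:
    """log(1 + rate): non-negative, monotone, and log(1+0) = 0.

    Adding 1 before taking logs keeps zero-rate county-years in the sample
    while leaving coefficients roughly readable as percent changes.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return math.log1p(rate)


def interpolate_sparse_covariate(
    observations: Mapping[int, float], target_year: int
) -> float:
    """Linear interpolation between observed years, linear extrapolation outside.

    Extrapolation uses the slope of the first (last) observed segment before
    the first (after the last) observation year; values at observed years are
    returned exactly.
    """
    if len(observations) < 2:
        raise ValueError("need at least two observation years to interpolate")
    years = np.array(sorted(observations))
    vals = np.array([observations[int(y)] for y in years], dtype=float)
    if target_year <= years[0]:
        slope = (vals[1] - vals[0]) / (years[1] - years[0])
        return float(vals[0] + slope * (target_year - years[0]))
    if target_year >= years[-1]:
        slope = (vals[-1] - vals[-2]) / (years[-1] - years[-2])
        return float(vals[-1] + slope * (target_year - years[-1]))
    return float(np.interp(target_year, years, vals))


@dataclass(frozen=True)
class FilterCriteria:
    """Inputs to the ordered sample-exclusion rules.

    Rules, applied in order with a county attributed to the first rule it
    fails: (1) any year of zero female population 14-19 or a flagged
    reporting-area change; (2) prior abstinence-only funding; (3) missing at
    least one year of any time-varying covariate after sparse-covariate
    interpolation; (4) funded but outside the configured award cohorts;
    (5) configured excluded states.
    """

    abstinence_counties: frozenset = frozenset()
    reporting_change_counties: frozenset = frozenset()
    allowed_cohort_years: tuple[int, ...] = (2010, 2015)
    excluded_states: frozenset = frozenset()
    sparse_columns: tuple[str, ...] = SPARSE_COLUMNS

    @classmethod
    def make(
        cls,
        abstinence_counties: Iterable[str] = (),
        reporting_change_counties: Iterable[str] = (),
        allowed_cohort_years: Iterable[int] = (2010, 2015),
        excluded_states: Iterable[str] = (),
        sparse_columns: Iterable[str] = SPARSE_COLUMNS,
    ) -> "FilterCriteria":
        return cls(
            frozenset(abstinence_counties),
            frozenset(reporting_change_counties),
            tuple(allowed_cohort_years),
            frozenset(excluded_states),
            tuple(sparse_columns),
        )


@dataclass
class FilterReport:
    """Per-rule exclusion accounting; rules are disjoint by ordered attribution."""

    rule_names: list[str] = field(default_factory=list)
    excluded_ids: list[list[str]] = field(default_factory=list)
    n_input: int = 0
    n_remaining: int = 0

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(ids) for ids in self.excluded_ids)

    def to_dict(self) -> dict:
        return {
            "n_input_counties": self.n_input,
            "n_remaining_counties": self.n_remaining,
            "rules": [
                {"rule": name, "n_excluded": len(ids), "county_ids": ids}
                for name, ids in zip(self.rule_names, self.excluded_ids)
            ],
        }


def _fill_sparse(df: pd.DataFrame, columns: Iterable[str]) -> tuple[pd.DataFrame, set]:
    """Interpolate/extrapolate sparse covariates within each county.

    Counties with fewer than two observed years for some sparse column cannot
    be filled; their ids are returned so the missing-data rule can claim them.
    """
    df = df.copy()
    unfillable: set = set()
    for col in columns:
        if col not in df.columns:
            continue
        for cid, grp in df.groupby("county_id", sort=False):
            obs = grp.dropna(subset=[col])
            if len(obs) == len(grp):
                continue
            if len(obs) < 2:
                unfillable.add(cid)
                continue
            mapping = dict(zip(obs["year"].astype(int), obs[col].astype(float)))
            filled = [
                interpolate_sparse_covariate(mapping, int(y)) for y in grp["year"]
            ]
            df.loc[grp.index, col] = filled
    return df, unfillable


def apply_sample_filters(
    records: pd.DataFrame, criteria: FilterCriteria | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the ordered county-exclusion rules; returns (records, report).

    Sparse covariates are interpolated before the missing-covariate rule, so
    the returned table is fully observed.  Applying the filters twice is a
    no-op (idempotent).
    """
    criteria = criteria or FilterCriteria()
    df, unfillable = _fill_sparse(records, criteria.sparse_columns)
    report = FilterReport(n_input=df["county_id"].nunique())

    def exclude(rule: str, ids: set) -> None:
        remaining = set(df_state["remaining"])
        hit = sorted(ids & remaining)
        report.rule_names.append(rule)
        report.excluded_ids.append(hit)
        df_state["remaining"] = remaining - set(hit)

    df_state = {"remaining": set(df["county_id"].unique())}

    pop_total = df[list(POP_COLUMNS)].sum(axis=1)
    zero_pop = set(df.loc[pop_total <= 0, "county_id"])
    exclude(
        "zero_population_or_reporting_change",
        zero_pop | set(criteria.reporting_change_counties),
    )
    exclude("prior_abstinence_funding", set(criteria.abstinence_counties))

    covariate_missing = set(
        df.loc[df[list(COVARIATE_COLUMNS)].isna().any(axis=1), "county_id"]
    ) | set(unfillable)
    exclude("missing_covariate_year", covariate_missing)

    first_funded = (
        df[df["funded"] == 1].groupby("county_id")["year"].min()
    )
    off_cohort = set(
        first_funded[~first_funded.isin(criteria.allowed_cohort_years)].index
    )
    exclude("funded_outside_main_cohorts", off_cohort)

    in_excluded_state = set(
        df.loc[df["state_id"].isin(criteria.excluded_states), "county_id"]
    )
    exclude("excluded_state", in_excluded_state)

    keep = df_state["remaining"]
    report.n_remaining = len(keep)
    if not keep:
        warnings.warn("all counties excluded by sample filters", stacklevel=2)
    out = df[df["county_id"].isin(keep)].reset_index(drop=True)
    return out, report


def _check_balance(df: pd.DataFrame) -> None:
    years = np.sort(df["year"].unique())
    counts = df.groupby("county_id")["year"].nunique()
    sizes = df.groupby("county_id").size()
    bad = sorted(
        set(counts[counts != len(years)].index) | set(sizes[sizes != len(years)].index)
    )
    if bad:
        raise ValueError(
            f"panel is unbalanced for counties {bad[:10]}"
            + (" ..." if len(bad) > 10 else "")
        )


def build_analysis_rows(
    records: pd.DataFrame,
    age_mode: str = "aggregate",
    lag: int = 1,
) -> pd.DataFrame:
    """Build model-ready rows: outcome log(1+R), lagged treatment and covariates.

    In ``aggregate`` mode R pools births and population over ages 14-19; in
    ``age_specific`` mode one row is produced per (county, year, age) with the
    same right-hand side.  The first ``lag`` panel years are dropped (no lag
    available).  A county first funded in year g first contributes a treated
    row in year ``g + lag``.  The output carries ``group_year``, the first
    analysis year with lagged treatment on (0 for never-treated counties).
    """
    if age_mode not in ("aggregate", "age_specific"):
        raise ValueError(f"unknown age_mode {age_mode!r}")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    _check_balance(records)
    df = records.sort_values(["county_id", "year"], kind="stable").reset_index(drop=True)

    g = df.groupby("county_id", sort=False)
    if lag > 0:
        treat = g["funded"].shift(lag)
        covs = {c: g[c].shift(lag) for c in COVARIATE_COLUMNS}
    else:
        treat = df["funded"].astype(float)
        covs = {c: df[c] for c in COVARIATE_COLUMNS}

    base = pd.DataFrame(
        {
            "county_id": df["county_id"],
            "state_id": df["state_id"],
            "year": df["year"],
            "treat_lag": treat,
        }
    )
    for c, s in covs.items():
        base[c] = s

    pop_total = df[list(POP_COLUMNS)].sum(axis=1).to_numpy()
    births_total = df[list(BIRTH_COLUMNS)].sum(axis=1).to_numpy()
    if (pop_total <= 0).any():
        bad = sorted(df.loc[pop_total <= 0, "county_id"].unique())
        raise ValueError(f"zero teen population in counties {bad}; filter them first")

    if age_mode == "aggregate":
        base["outcome"] = np.log1p(1000.0 * births_total / pop_total)
        rows = base
    else:
        pieces = []
        for a in AGES:
            piece = base.copy()
            pop_a = df[f"pop_age{a}"].to_numpy()
            if (pop_a <= 0).any():
                bad = sorted(df.loc[pop_a <= 0, "county_id"].unique())
                raise ValueError(f"zero age-{a} population in counties {bad}")
            piece["age"] = a
            piece["outcome"] = np.log1p(1000.0 * df[f"births_age{a}"].to_numpy() / pop_a)
            pieces.append(piece)
        rows = pd.concat(pieces, ignore_index=True)

    rows = rows.dropna(subset=["treat_lag"]).reset_index(drop=True)
    rows["treat_lag"] = rows["treat_lag"].astype(int)

    first_on = (
        rows[rows["treat_lag"] == 1].groupby("county_id")["year"].min()
    )
    rows["group_year"] = (
        rows["county_id"].map(first_on).fillna(0).astype(int)
    )
    ordered = ["county_id", "state_id", "year"]
    if age_mode == "age_specific":
        ordered.append("age")
    ordered += ["outcome", "treat_lag", "group_year", *COVARIATE_COLUMNS]
    return rows[ordered]
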