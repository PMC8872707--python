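"""Synthetic county-year teen-birth panels with known ground truth.

Emulates the statistical structure of US county natality panels used in
difference-in-differences evaluations of county-level program funding:
counties nested in states, county fixed effects, state-year shocks,
optional county-specific linear time trends, staggered two-cohort funding
adoption, and a treatment effect on the log(1 + rate) scale that ramps
with time since treatment.  The generator returns both the panel and a
:class:`SimTruth` record of the parameters that produced it, so estimator
recovery can be checked against known targets.

The outcome is built as

    log(1 + R_it) = b0 + a_i + phi_{s(i),t} + d_i (t - t0)
                    + x_{i,t-1}' beta + tau(e_it) 1{treated} + eps_it

where ``R`` is births per 1,000 women aged 14-19, ``a_i`` is a county
intercept, ``phi`` a state-year shock, ``d_i`` a county-specific linear
trend slope, ``tau(e)`` the event-time effect path (event time ``e`` counts
years since the first *lagged*-treatment year, funding year + 1), and
``eps`` idiosyncratic noise.  Covariates enter through their one-year lag,
matching the estimating equations applied downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "assign_cohorts",
    "generate_panel",
    "default_effect_path",
    "write_panel",
    "read_panel",
    "AGES",
    "COVARIATE_COLUMNS",
    "PANEL_COLUMNS",
]

AGES = tuple(range(14, 20))

COVARIATE_COLUMNS = (
    "unemployment",
    "median_income",
    "poverty",
    "pct_16_19",
    "pct_white",
    "pct_black",
    "pct_hispanic",
    "abortion_distance",
)

BIRTH_COLUMNS = tuple(f"births_age{a}" for a in AGES)
POP_COLUMNS = tuple(f"pop_age{a}" for a in AGES)

PANEL_COLUMNS = (
    ("county_id", "state_id", "year")
    + BIRTH_COLUMNS
    + POP_COLUMNS
    + COVARIATE_COLUMNS
    + ("funded",)
)


@dataclass(frozen=True)
class _CovariateProcess:
    """AR(1) county series around a state-level mean."""

    base: float
    state_sd: float
    county_sd: float
    innov_sd: float
    rho: float = 0.85
    lower: float = -np.inf
    upper: float = np.inf


# Levels chosen to sit on the scale of US county statistics over 1996-2017:
# unemployment and poverty in percent, income in dollars, composition
# covariates in percent of teen women, provider distance in miles.
COVARIATE_PROCESSES: Mapping[str, _CovariateProcess] = {
    "unemployment": _CovariateProcess(5.5, 1.0, 0.8, 0.5, lower=0.0, upper=100.0),
    "median_income": _CovariateProcess(52_000.0, 8_000.0, 6_000.0, 900.0, lower=1.0),
    "poverty": _CovariateProcess(14.0, 3.0, 2.5, 0.5, lower=0.0, upper=100.0),
    "pct_16_19": _CovariateProcess(66.0, 2.0, 2.0, 0.8, lower=0.0, upper=100.0),
    "pct_white": _CovariateProcess(75.0, 10.0, 8.0, 0.5, lower=0.0, upper=100.0),
    "pct_black": _CovariateProcess(12.0, 8.0, 5.0, 0.3, lower=0.0, upper=100.0),
    "pct_hispanic": _CovariateProcess(10.0, 6.0, 4.0, 0.3, lower=0.0, upper=100.0),
    "abortion_distance": _CovariateProcess(35.0, 20.0, 12.0, 3.0, lower=0.0),
}


def default_effect_path() -> dict[int, float]:
    """Treatment-effect path on the log(1+R) scale.

    Ramps linearly from -1.5% in the first treated year to -7.0% in the
    fifth, then holds flat for later event times realized by the panel.
    """
    path = {e: -0.015 - (0.07 - 0.015) * e / 4 for e in range(5)}
    path[5] = -0.07
    path[6] = -0.07
    return path


def _default_covariate_effects() -> dict[str, float]:
    # Modest, plausibly-signed coefficients on the log(1+R) scale.
    return {
        "unemployment": 0.010,
        "median_income": -3.0e-6,
        "poverty": 0.008,
        "pct_16_19": 0.004,
        "pct_white": 0.0,
        "pct_black": 0.003,
        "pct_hispanic": 0.002,
        "abortion_distance": 0.0005,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic county-panel data-generating process.

    Defaults reproduce the study design the package targets: a 1996-2017
    panel of 2,927 counties in 49 states with two funding cohorts, 36
    counties first funded in 2010 and 19 more in 2015 (55 funded in total).
    """

    n_states: int = 49
    counties_per_state: int = 60
    total_counties: int | None = 2927
    year_start: int = 1996
    year_end: int = 2017
    cohorts: tuple[tuple[int, int], ...] = ((2010, 36), (2015, 19))
    effect_path: Mapping[int, float] = field(default_factory=default_effect_path)
    sigma_county: float = 0.4
    sigma_stateyear: float = 0.05
    sigma_trend: float = 0.004
    sigma_noise: float = 0.07
    covariate_effects: Mapping[str, float] = field(
        default_factory=_default_covariate_effects
    )
    outcome_mode: str = "gaussian_rate"
    base_rate: float = 40.0
    adoption_trend_bias: float = 0.0
    n_abstinence_counties: int = 0
    sparse_years: tuple[int, ...] = (2000, 2011, 2014)
    pop_log_mean: float = 5.5
    pop_log_sd: float = 1.0
    pop_year_jitter: float = 0.02
    seed: int = 0

    @property
    def n_counties(self) -> int:
        if self.total_counties is not None:
            return int(self.total_counties)
        return self.n_states * self.counties_per_state

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def validate(self) -> None:
        for name in ("sigma_county", "sigma_stateyear", "sigma_trend", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.year_end <= self.year_start:
            raise ValueError("year range must span at least two years")
        if self.n_states < 1 or self.n_counties < 1:
            raise ValueError("need at least one state and one county")
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        if self.pop_log_mean <= 0 and np.exp(self.pop_log_mean) < 1:
            raise ValueError("population scale implies non-positive populations")
        n_treated = sum(n for _, n in self.cohorts)
        if n_treated > self.n_counties:
            raise ValueError("cohort sizes exceed the number of counties")
        for year, n in self.cohorts:
            if not (self.year_start <= year <= self.year_end):
                raise ValueError(f"cohort funding year {year} outside panel years")
            if n < 0:
                raise ValueError("cohort sizes must be non-negative")
        if self.outcome_mode not in ("gaussian_rate", "poisson_births"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.n_abstinence_counties > self.n_counties - n_treated:
            raise ValueError("not enough never-funded counties to flag as abstinence")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_path"] = {int(k): float(v) for k, v in self.effect_path.items()}
        d["covariate_effects"] = dict(self.covariate_effects)
        return d


@dataclass
class SimTruth:
    """Ground truth recorded alongside a generated panel.

    ``att_overall`` is the mean of the event-time effect path over all
    treated county-year cells realized in the analysis window (the cells a
    lagged-treatment analysis actually uses); ``att_overall_group`` weights
    each cohort's time-averaged effect by cohort size, the estimand of the
    default overall aggregation downstream.
    """

    att_overall: float
    att_overall_group: float
    event_time_effects: dict[int, float]
    cohort_assignments: dict[str, int]
    abstinence_counties: list[str]
    county_intercepts: dict[str, float]
    county_trends: dict[str, float]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "att_overall": self.att_overall,
                    "att_overall_group": self.att_overall_group,
                    "event_time_effects": {
                        str(k): v for k, v in self.event_time_effects.items()
                    },
                    "cohort_assignments": self.cohort_assignments,
                    "abstinence_counties": self.abstinence_counties,
                    "county_intercepts": self.county_intercepts,
                    "county_trends": self.county_trends,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )


def assign_cohorts(
    county_ids: Sequence[str],
    cohorts: Sequence[tuple[int, int]],
    seed: int,
    scores: np.ndarray | None = None,
    bias: float = 0.0,
) -> dict[str, int]:
    """Assign counties to staggered funding cohorts.

    Returns a mapping county -> first funding year for treated counties;
    never-treated counties are absent from the mapping.  When ``bias`` is
    non-zero, counties with higher ``scores`` are preferentially selected
    (logistic-perturbation ranking), which lets adoption correlate with
    county characteristics such as trend slopes.
    """
    ids = list(county_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate county ids")
    n_needed = sum(n for _, n in cohorts)
    if n_needed > len(ids):
        raise ValueError(
            f"cohorts request {n_needed} treated counties but only {len(ids)} exist"
        )
    rng = np.random.default_rng(seed)
    if bias != 0.0 and scores is not None:
        s = np.asarray(scores, dtype=float)
        sd = s.std()
        z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
        utility = bias * z + rng.gumbel(size=len(ids))
    else:
        utility = rng.random(len(ids))
    order = np.argsort(-utility, kind="stable")
    assignment: dict[str, int] = {}
    pos = 0
    for year, n in sorted(cohorts):
        for j in order[pos : pos + n]:
            assignment[ids[j]] = int(year)
        pos += n
    return assignment


def _effect_lookup(
    effect_path: Mapping[int, float], event_times: np.ndarray, treated: np.ndarray
) -> np.ndarray:
    realized = np.unique(event_times[treated])
    missing = [int(e) for e in realized if int(e) not in effect_path]
    if missing:
        raise ValueError(f"effect_path missing realized event times {missing}")
    out = np.zeros(event_times.shape)
    for e in realized:
        out[treated & (event_times == e)] = effect_path[int(e)]
    return out


def generate_panel(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a balanced county-year panel and its ground truth.

    The returned table has one row per county-year with birth counts and
    female populations by single year of age 14-19, time-varying covariates
    (``abortion_distance`` observed only in ``config.sparse_years``), and a
    contemporaneous funding indicator.  Treatment is absorbing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    years = config.years
    T = len(years)
    n = config.n_counties
    state_idx = np.arange(n) % config.n_states
    width = max(4, len(str(n)))
    county_ids = np.array([f"C{i:0{width}d}" for i in range(n)])
    state_ids = np.array([f"S{s:02d}" for s in range(config.n_states)])

    alpha = rng.normal(0.0, config.sigma_county, n)
    trend = rng.normal(0.0, config.sigma_trend, n)
    phi = rng.normal(0.0, config.sigma_stateyear, (config.n_states, T))

    assign_seed = int(rng.integers(0, 2**31 - 1))
    assignment = assign_cohorts(
        county_ids,
        config.cohorts,
        seed=assign_seed,
        scores=-trend,  # positive bias selects counties on declining trends
        bias=config.adoption_trend_bias,
    )
    g0 = np.full(n, np.inf)  # first funding year; inf = never
    for cid, year in assignment.items():
        g0[np.where(county_ids == cid)[0][0]] = year

    never_idx = np.where(~np.isfinite(g0))[0]
    abstinence = rng.choice(
        never_idx, size=config.n_abstinence_counties, replace=False
    ) if config.n_abstinence_counties else np.array([], dtype=int)
    abstinence_ids = sorted(county_ids[abstinence])

    # Covariates: AR(1) county series around state-level means.
    X = np.empty((n, T, len(COVARIATE_COLUMNS)))
    for k, name in enumerate(COVARIATE_COLUMNS):
        pr = COVARIATE_PROCESSES[name]
        state_mean = pr.base + rng.normal(0.0, pr.state_sd, config.n_states)
        county_mean = state_mean[state_idx] + rng.normal(0.0, pr.county_sd, n)
        innov = rng.normal(0.0, pr.innov_sd, (n, T))
        u = np.empty((n, T))
        u[:, 0] = innov[:, 0] / np.sqrt(1.0 - pr.rho**2)
        for t in range(1, T):
            u[:, t] = pr.rho * u[:, t - 1] + innov[:, t]
        X[:, :, k] = np.clip(county_mean[:, None] + u, pr.lower, pr.upper)

    # Populations by single age: county scale drawn once, small yearly jitter.
    base_pop = rng.lognormal(config.pop_log_mean, config.pop_log_sd, (n, len(AGES)))
    jitter = np.exp(rng.normal(0.0, config.pop_year_jitter, (n, T, len(AGES))))
    pop = np.maximum(np.round(base_pop[:, None, :] * jitter), 1.0)

    # Treatment, event time, outcome index.
    yr = years[None, :]
    funded = (yr >= g0[:, None]).astype(int)
    treated_out = yr >= (g0 + 1)[:, None]  # one-year conception lag
    event_time = yr - (g0 + 1)[:, None]
    with np.errstate(invalid="ignore"):
        event_int = np.where(np.isfinite(event_time), event_time, 0).astype(int)
    effect = _effect_lookup(config.effect_path, event_int, treated_out)

    beta = np.array([config.covariate_effects.get(c, 0.0) for c in COVARIATE_COLUMNS])
    X_lag = np.concatenate([X[:, :1, :], X[:, :-1, :]], axis=1)
    cov_term = X_lag @ beta

    eta = (
        np.log1p(config.base_rate)
        + alpha[:, None]
        + phi[state_idx, :]
        + trend[:, None] * (yr - config.year_start)
        + cov_term
        + effect
        + rng.normal(0.0, config.sigma_noise, (n, T))
    )
    R = np.clip(np.expm1(eta), 0.0, None)

    if config.outcome_mode == "gaussian_rate":
        # Expected counts: fractional births preserve the rate exactly.
        births = R[:, :, None] * pop / 1000.0
    else:
        births = rng.poisson(R[:, :, None] * pop / 1000.0).astype(float)

    df = pd.DataFrame(
        {
            "county_id": np.repeat(county_ids, T),
            "state_id": np.repeat(state_ids[state_idx], T),
            "year": np.tile(years, n),
        }
    )
    for a_i, col in enumerate(BIRTH_COLUMNS):
        df[col] = births[:, :, a_i].ravel()
    for a_i, col in enumerate(POP_COLUMNS):
        df[col] = pop[:, :, a_i].ravel()
    for k, col in enumerate(COVARIATE_COLUMNS):
        df[col] = X[:, :, k].ravel()
    df["funded"] = funded.ravel()

    # Blank the provider-distance column outside its observation years; if
    # the panel covers fewer than two of them, leave it fully observed so
    # short test panels stay usable.
    sparse_in = [y for y in config.sparse_years if config.year_start <= y <= config.year_end]
    if len(sparse_in) >= 2:
        df.loc[~df["year"].isin(sparse_in), "abortion_distance"] = np.nan

    truth = _build_truth(config, county_ids, assignment, abstinence_ids, alpha, trend)
    return df, truth


def _build_truth(config, county_ids, assignment, abstinence_ids, alpha, trend):
    path = {int(k): float(v) for k, v in config.effect_path.items()}
    cell_effects: list[float] = []
    group_means: dict[int, tuple[int, float]] = {}
    by_year: dict[int, list[str]] = {}
    for cid, year in assignment.items():
        by_year.setdefault(year, []).append(cid)
    for year, members in sorted(by_year.items()):
        es = list(range(0, config.year_end - (year + 1) + 1))
        effs = [path[e] for e in es]
        if effs:
            group_means[year] = (len(members), float(np.mean(effs)))
        cell_effects.extend(effs * len(members))
    realized_e = sorted(
        {e for year in by_year for e in range(0, config.year_end - (year + 1) + 1)}
    )
    att_cell = float(np.mean(cell_effects)) if cell_effects else 0.0
    if group_means:
        sizes = np.array([s for s, _ in group_means.values()], dtype=float)
        means = np.array([m for _, m in group_means.values()])
        att_group = float(np.sum(sizes * means) / sizes.sum())
    else:
        att_group = 0.0
    return SimTruth(
        att_overall=att_cell,
        att_overall_group=att_group,
        event_time_effects={e: path[e] for e in realized_e},
        cohort_assignments=dict(sorted(assignment.items())),
        abstinence_counties=list(abstinence_ids),
        county_intercepts={c: float(a) for c, a in zip(county_ids, alpha)},
        county_trends={c: float(t) for c, t in zip(county_ids, trend)},
        seed=config.seed,
    )


def write_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str, "state_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing columns {missing}")
    return df
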