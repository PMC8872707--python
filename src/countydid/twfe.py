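"""Two-way fixed-effects panel regressions with county-clustered errors.

Implements the three nested specifications used throughout: Model 1 absorbs
county and state-year fixed effects; Model 2 adds lagged time-varying
covariates; Model 3 further adds county-specific linear time trends.  Fixed
effects are absorbed by alternating-projection demeaning (Frisch-Waugh-
Lovell), which reproduces full dummy-variable OLS to numerical precision
while scaling to thousands of counties.  Inference uses the CR1 cluster-
robust sandwich with t(G-1) critical values, G the number of county
clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODEL2_COVARIATES",
    "ModelSpec",
    "TwfeFit",
    "fit_twfe",
    "cluster_robust_vcov",
    "interpret_as_percent",
    "PercentEffect",
]

MODEL2_COVARIATES = (
    "abortion_distance",
    "unemployment",
    "median_income",
    "poverty",
    "pct_16_19",
    "pct_white",
    "pct_black",
    "pct_hispanic",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which of the three nested specifications to fit."""

    model_id: int
    include_covariates: bool
    include_county_trends: bool
    covariates: tuple[str, ...] = MODEL2_COVARIATES
    cluster_col: str = "county_id"

    def __post_init__(self):
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        if self.model_id == 1 and (self.include_covariates or self.include_county_trends):
            raise ValueError("Model 1 has no covariates and no county trends")
        if self.model_id == 2 and self.include_county_trends:
            raise ValueError("Model 2 has no county trends")
        if self.model_id == 3 and not (self.include_covariates and self.include_county_trends):
            raise ValueError("Model 3 requires covariates and county trends")

    @classmethod
    def from_id(cls, model_id: int, covariates: Sequence[str] = MODEL2_COVARIATES) -> "ModelSpec":
        return cls(
            model_id=model_id,
            include_covariates=model_id >= 2,
            include_county_trends=model_id == 3,
            covariates=tuple(covariates),
        )


@dataclass
class TwfeFit:
    """One fitted specification: treatment effect, inference, diagnostics."""

    estimate: float
    se: float
    conf_int: tuple[float, float]
    params: dict[str, float]
    bse: dict[str, float]
    vcov: pd.DataFrame
    n_obs: int
    n_clusters: int
    dropped_columns: list[str]
    r2_within: float
    model_id: int = 0

    @property
    def percent(self) -> "PercentEffect":
        return interpret_as_percent(self.estimate)

    def to_dict(self) -> dict:
        pct = self.percent
        return {
            "model_id": self.model_id,
            "estimate": self.estimate,
            "se": self.se,
            "conf_int": list(self.conf_int),
            "percent_exact": pct.exact,
            "percent_rough": pct.rough,
            "params": self.params,
            "bse": self.bse,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "dropped_columns": self.dropped_columns,
            "r2_within": self.r2_within,
        }


class PercentEffect(NamedTuple):
    """Percent-change reading of a log(1+R) coefficient."""

    exact: float  # 100 * (exp(b) - 1)
    rough: float  # 100 * b


def interpret_as_percent(coefficient: float) -> PercentEffect:
    """Read a log(1+R) coefficient as a percent change in the rate."""
    return PercentEffect(
        exact=100.0 * float(np.expm1(coefficient)),
        rough=100.0 * float(coefficient),
    )


# ----------------------------------------------------------------- absorption

def _fe_absorber(codes: np.ndarray, n_groups: int) -> Callable[[np.ndarray], np.ndarray]:
    counts = np.bincount(codes, minlength=n_groups).astype(float)

    def project(M: np.ndarray) -> np.ndarray:
        sums = np.zeros((n_groups, M.shape[1]))
        np.add.at(sums, codes, M)
        return sums[codes] / counts[codes, None]

    return project


def _trend_absorber(
    codes: np.ndarray, n_groups: int, time: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Project each column, within group, onto span{1, t} (intercept + slope)."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    t_sum = np.bincount(codes, weights=time, minlength=n_groups)
    t_mean = t_sum / counts
    tc = time - t_mean[codes]
    stt = np.bincount(codes, weights=tc * tc, minlength=n_groups)
    safe_stt = np.where(stt > 0, stt, 1.0)

    def project(M: np.ndarray) -> np.ndarray:
        sums = np.zeros((n_groups, M.shape[1]))
        np.add.at(sums, codes, M)
        means = sums / counts[:, None]
        sty = np.zeros((n_groups, M.shape[1]))
        np.add.at(sty, codes, M * tc[:, None])
        slopes = np.where(stt[:, None] > 0, sty / safe_stt[:, None], 0.0)
        return means[codes] + slopes[codes] * tc[:, None]

    return project


def _demean(
    M: np.ndarray,
    absorbers: Sequence[Callable[[np.ndarray], np.ndarray]],
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> np.ndarray:
    """Alternating projections until the largest within-sweep update < tol."""
    M = M.copy()
    scale = max(np.abs(M).max(), 1.0)
    for _ in range(max_iter):
        delta = 0.0
        for project in absorbers:
            fitted = project(M)
            M -= fitted
            step = np.abs(fitted).max()
            if step > delta:
                delta = step
        if delta < tol * scale:
            return M
    warnings.warn("fixed-effect absorption did not fully converge", stacklevel=2)
    return M


def _drop_collinear(
    X: np.ndarray, names: Sequence[str], rtol: float = 1e-8
) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy left-to-right rank filter: keep a column iff it adds rank.

    Deterministic first-kept order, so the treatment column (always first)
    survives whenever it carries any identifying variation.
    """
    kept_idx: list[int] = []
    dropped: list[str] = []
    basis: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        for q in basis:
            v -= (q @ v) * q
        if norm0 < 1e-12 or np.linalg.norm(v) <= rtol * norm0:
            dropped.append(names[j])
        else:
            basis.append(v / np.linalg.norm(v))
            kept_idx.append(j)
    return X[:, kept_idx], [names[j] for j in kept_idx], dropped


# ----------------------------------------------------------------- inference

def cluster_robust_vcov(
    design: np.ndarray,
    residuals: np.ndarray,
    cluster_ids: np.ndarray,
    small_sample: bool = True,
    n_params: int | None = None,
) -> np.ndarray:
    """Cluster-robust sandwich covariance.

    With ``small_sample`` the CR1 correction ``G/(G-1) * (N-1)/(N-K)`` is
    applied, K the number of model parameters (``n_params``; defaults to the
    design's column count).  With every observation its own cluster and the
    correction off, this reduces to HC0.
    """
    X = np.asarray(design, dtype=float)
    e = np.asarray(residuals, dtype=float)
    codes, _ = pd.factorize(cluster_ids)
    G = codes.max() + 1
    if G < 2:
        raise ValueError("cluster-robust covariance requires at least 2 clusters")
    N, k = X.shape
    K = n_params if n_params is not None else k
    bread = np.linalg.inv(X.T @ X)
    U = X * e[:, None]
    S = np.zeros((G, k))
    np.add.at(S, codes, U)
    meat = S.T @ S
    V = bread @ meat @ bread
    if small_sample:
        if N - K <= 0:
            raise ValueError("non-positive residual degrees of freedom for CR1")
        V = V * (G / (G - 1)) * ((N - 1) / (N - K))
    return V


# ----------------------------------------------------------------- main fit

def fit_twfe(rows: pd.DataFrame, spec: ModelSpec) -> TwfeFit:
    """Fit one of Models 1-3 on analysis rows by fixed-effect absorption.

    Point estimates match full dummy-variable OLS (county dummies, state-year
    dummies, optionally county x time interactions) up to the demeaning
    tolerance; perfectly collinear covariate columns are dropped in
    deterministic first-kept order and reported in the fit.
    """
    df = rows
    if df["county_id"].nunique() < 2 or df["year"].nunique() < 2:
        raise ValueError("need at least 2 counties and 2 years")
    if df["treat_lag"].nunique() < 2:
        raise ValueError("treatment does not vary in the sample")

    names = ["treat_lag"]
    if spec.include_covariates:
        names += [c for c in spec.covariates if c in df.columns]
    y = df["outcome"].to_numpy(dtype=float)
    X = df[names].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("analysis rows contain missing values; filter first")

    county_codes, counties = pd.factorize(df["county_id"], sort=True)
    sy_codes, sy_cells = pd.factorize(
        df["state_id"].astype(str) + "::" + df["year"].astype(str), sort=True
    )
    time = df["year"].to_numpy(dtype=float)
    time = time - time.min()

    absorbers = []
    if spec.include_county_trends:
        absorbers.append(_trend_absorber(county_codes, len(counties), time))
    else:
        absorbers.append(_fe_absorber(county_codes, len(counties)))
    absorbers.append(_fe_absorber(sy_codes, len(sy_cells)))

    M = _demean(np.column_stack([y, X]), absorbers)
    yd, Xd = M[:, 0], M[:, 1:]

    if np.linalg.norm(Xd[:, 0]) <= 1e-10 * max(np.linalg.norm(X[:, 0]), 1.0):
        raise ValueError(
            "treatment has no variation after absorbing fixed effects; "
            "no never-treated contrast within any state-year cell"
        )
    Xk, kept, dropped = _drop_collinear(Xd, names)
    if "treat_lag" in dropped:
        raise ValueError("treatment collinear with fixed effects; estimate undefined")

    beta, *_ = np.linalg.lstsq(Xk, yd, rcond=None)
    resid = yd - Xk @ beta

    n_states = df["state_id"].nunique()
    df_absorbed = len(counties) + len(sy_cells) - n_states
    if spec.include_county_trends:
        df_absorbed += len(counties) - n_states
    K = len(kept) + df_absorbed
    N = len(df)
    small_sample = N - K > 0
    if not small_sample:
        warnings.warn(
            "saturated model: no residual degrees of freedom, "
            "CR1 small-sample correction skipped"
        )
    V = cluster_robust_vcov(
        Xk, resid, county_codes, small_sample=small_sample,
        n_params=K if small_sample else None,
    )
    se = np.sqrt(np.diag(V))
    G = len(counties)
    tcrit = stats.t.ppf(0.975, G - 1)

    params = dict(zip(kept, beta))
    bse = dict(zip(kept, se))
    b1 = params["treat_lag"]
    s1 = bse["treat_lag"]
    sst = float(yd @ yd)
    ssr = float(resid @ resid)
    r2w = 1.0 - ssr / sst if sst > 0 else 0.0

    return TwfeFit(
        estimate=float(b1),
        se=float(s1),
        conf_int=(float(b1 - tcrit * s1), float(b1 + tcrit * s1)),
        params={k: float(v) for k, v in params.items()},
        bse={k: float(v) for k, v in bse.items()},
        vcov=pd.DataFrame(V, index=kept, columns=kept),
        n_obs=N,
        n_clusters=G,
        dropped_columns=dropped,
        r2_within=float(r2w),
        model_id=spec.model_id,
    )
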