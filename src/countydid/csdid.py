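"""Group-time average treatment effects under staggered adoption.

A from-scratch implementation of the group-time ATT framework for panels
where cohorts of counties begin treatment in different years.  For cohort g
(first treated analysis year) and calendar year t >= g,

    ATT(g, t) = E[Y_t - Y_{g-1} | G = g] - E[Y_t - Y_{g-1} | never treated],

estimated unconditionally or with a doubly-robust combination of an
outcome-regression model for the never-treated change and inverse-
probability weighting from a logistic group-membership score, both built on
base-period covariates.  Pre-treatment cells (t < g) use a varying base
period (the year-on-year change t-1 -> t) and serve as parallel-trend
diagnostics.  Inference is influence-function based, with county-level
multiplier-bootstrap pointwise and simultaneous bands and a joint Wald test
of zero pre-treatment effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .twfe import MODEL2_COVARIATES

__all__ = [
    "GroupTimeATT",
    "AggregatedResult",
    "att_gt",
    "estimate_all_att_gt",
    "aggregate_overall",
    "aggregate_event_study",
    "multiplier_bootstrap",
    "pretrend_wald",
    "fit_csdid",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class GroupTimeATT:
    """ATT(g, t) with its county-level influence-function contributions.

    ``influence`` is indexed by every county in the panel (zero outside the
    g-vs-never subsample) and scaled so that the estimation error is
    approximately the mean influence; se = ||influence|| / N.
    """

    group: int
    time: int
    estimate: float
    se: float
    influence: pd.Series
    n_treated: int
    n_control: int

    @property
    def event_time(self) -> int:
        return self.time - self.group

    @property
    def is_post(self) -> bool:
        return self.time >= self.group


# ------------------------------------------------------------- preparation

class _Prepared:
    """Wide panel view: one outcome matrix row per county."""

    def __init__(self, rows: pd.DataFrame, covariates: Sequence[str]):
        if rows.duplicated(["county_id", "year"]).any():
            raise ValueError(
                "group-time estimation needs one row per county-year "
                "(aggregate age mode)"
            )
        wide = rows.pivot(index="county_id", columns="year", values="outcome")
        if wide.isna().any().any():
            raise ValueError("panel is unbalanced in the outcome")
        self.counties = wide.index.to_numpy()
        self.years = wide.columns.to_numpy()
        self.Y = wide.to_numpy(dtype=float)
        groups = rows.groupby("county_id")["group_year"].first()
        self.groups = groups.reindex(wide.index).to_numpy()
        self.covariates = list(covariates)
        self._X: dict[int, np.ndarray] = {}
        if self.covariates:
            for year, grp in rows.groupby("year"):
                X = (
                    grp.set_index("county_id")[self.covariates]
                    .reindex(wide.index)
                    .to_numpy(dtype=float)
                )
                self._X[int(year)] = X

    def covariate_matrix(self, year: int) -> np.ndarray:
        X = self._X[int(year)]
        if np.isnan(X).any():
            raise ValueError(f"missing covariate values in year {year}")
        return X

    def membership(self) -> pd.Series:
        return pd.Series(self.groups, index=self.counties)


def _collinear_keep(X: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Column indices of a full-rank subset (greedy, first kept)."""
    kept: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        for q in basis:
            v -= (q @ v) * q
        if norm0 > 1e-12 and np.linalg.norm(v) > rtol * norm0:
            basis.append(v / np.linalg.norm(v))
            kept.append(j)
    return np.array(kept, dtype=int)


# ------------------------------------------------------------- ATT(g, t)

def _att_gt_cell(
    prep: _Prepared,
    g: int,
    t: int,
    mode: str,
    estimand: str = "dr",
) -> GroupTimeATT:
    years = list(prep.years)
    base = g - 1 if t >= g else t - 1
    for y in (base, t):
        if y not in years:
            raise ValueError(f"year {y} not observed; cannot form ATT({g},{t})")
    dy = prep.Y[:, years.index(t)] - prep.Y[:, years.index(base)]

    D = prep.groups == g
    C = prep.groups == 0
    sub = D | C
    nD, nC = int(D.sum()), int(C.sum())
    if nC == 0:
        raise ValueError(
            "no never-treated comparison counties; group-time ATTs undefined"
        )
    if nD == 0:
        raise ValueError(f"no counties in group {g}")
    N = len(prep.counties)
    n = int(sub.sum())

    d = D[sub].astype(float)
    dy_s = dy[sub]

    if mode == "unconditional":
        pbar = d.mean()
        att = dy_s[d == 1].mean() - dy_s[d == 0].mean()
        psi_sub = (d / pbar) * (dy_s - dy_s[d == 1].mean()) - (
            (1 - d) / (1 - pbar)
        ) * (dy_s - dy_s[d == 0].mean())
    elif mode == "conditional":
        att, psi_sub = _dr_att(prep, dy_s, d, base, sub, g, t, estimand)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    psi = np.zeros(N)
    psi[sub] = (N / n) * psi_sub
    se = float(np.linalg.norm(psi) / N)
    return GroupTimeATT(
        group=int(g),
        time=int(t),
        estimate=float(att),
        se=se,
        influence=pd.Series(psi, index=prep.counties),
        n_treated=nD,
        n_control=nC,
    )


def _dr_att(prep, dy, d, base, sub, g, t, estimand):
    """Doubly-robust ATT on the g-vs-never subsample with estimation-effect IF.

    Outcome regression: linear model of the never-treated outcome change on
    base-period covariates.  Propensity: logistic group-membership score on
    the same covariates.  ``estimand`` selects 'dr' (default), 'reg'
    (outcome regression only) or 'ipw' (Hajek IPW only).  The influence
    function includes the delta-method corrections for both estimated
    nuisance models.
    """
    Xraw = prep.covariate_matrix(base)[sub]
    # standardize for numerical stability; constant columns fold into the
    # intercept, so a covariate identical across counties changes nothing
    mu, sd = Xraw.mean(axis=0), Xraw.std(axis=0)
    keep = sd > 1e-12
    Xs = (Xraw[:, keep] - mu[keep]) / sd[keep]
    X = np.column_stack([np.ones(len(dy)), Xs])
    X = X[:, _collinear_keep(X)]
    n = len(dy)

    use_or = estimand in ("dr", "reg")
    use_ipw = estimand in ("dr", "ipw")

    if use_or:
        ctrl = d == 0
        beta, *_ = np.linalg.lstsq(X[ctrl], dy[ctrl], rcond=None)
        m = X @ beta
        beta_if = _or_beta_if(X, dy, m, d)  # n x k, mean ~ (beta_hat - beta)
    else:
        m = np.zeros(n)

    if use_ipw:
        try:
            res = sm.GLM(d, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10
            )
        except Exception as exc:  # pragma: no cover - pathological designs
            raise ValueError(
                f"propensity model failed for ATT({g},{t}): {exc}"
            ) from exc
        p = np.asarray(res.predict())
        high = p >= 1 - 1e-6
        if high.any():
            bad = list(np.asarray(prep.counties)[sub][high][:10])
            raise ValueError(
                f"no covariate overlap for ATT({g},{t}); propensity ~1 for "
                f"counties {bad}"
            )
        w0_raw = p * (1 - d) / (1 - p)
    else:
        w0_raw = 1 - d
        p = np.full(n, d.mean())

    if estimand == "reg":
        w1 = d / d.mean()
        att = float(np.mean(w1 * (dy - m)))
        psi = w1 * (dy - m - att)
        M1 = (w1[:, None] * X).mean(axis=0)
        psi = psi - beta_if @ M1
        return att, psi

    w1 = d / d.mean()
    w0 = w0_raw / w0_raw.mean()
    att1 = float(np.mean(w1 * (dy - m)))
    att0 = float(np.mean(w0 * (dy - m)))
    att = att1 - att0

    psi = w1 * (dy - m - att1) - w0 * (dy - m - att0)

    if use_or:
        M1 = (w1[:, None] * X).mean(axis=0)
        M0 = (w0[:, None] * X).mean(axis=0)
        psi = psi - beta_if @ (M1 - M0)
    if use_ipw:
        M2 = ((w0 * (dy - m - att0))[:, None] * X).mean(axis=0)
        H = X.T @ ((p * (1 - p))[:, None] * X) / n
        score = X * (d - p)[:, None]
        gamma_if = score @ np.linalg.pinv(H)  # n x k, mean ~ (gamma_hat - gamma)
        psi = psi - gamma_if @ M2
    return att, psi


def _or_beta_if(X, dy, m, d):
    """Per-observation influence of the control-group OLS coefficients."""
    A = X.T @ ((1 - d)[:, None] * X) / len(dy)
    resid = (1 - d) * (dy - m)
    return (X * resid[:, None]) @ np.linalg.pinv(A)


def att_gt(
    rows: pd.DataFrame,
    g: int,
    t: int,
    mode: str = "unconditional",
    covariates: Sequence[str] = MODEL2_COVARIATES,
    estimand: str = "dr",
) -> GroupTimeATT:
    """Estimate a single group-time ATT from analysis rows."""
    covs = list(covariates) if mode == "conditional" else []
    prep = _Prepared(rows, covs)
    return _att_gt_cell(prep, g, t, mode, estimand)


def estimate_all_att_gt(
    rows: pd.DataFrame,
    mode: str = "unconditional",
    covariates: Sequence[str] = MODEL2_COVARIATES,
    estimand: str = "dr",
) -> list[GroupTimeATT]:
    """All ATT(g, t) cells: post-treatment (t >= g, base g-1) and
    pre-treatment diagnostics (t < g, varying base t-1)."""
    covs = list(covariates) if mode == "conditional" else []
    prep = _Prepared(rows, covs)
    groups = sorted(set(prep.groups) - {0})
    if not groups:
        raise ValueError("panel has no treated groups")
    ymin, ymax = int(prep.years.min()), int(prep.years.max())
    out: list[GroupTimeATT] = []
    for g in groups:
        g = int(g)
        if g - 1 < ymin:
            warnings.warn(f"group {g} has no pre-treatment base year; skipped")
            continue
        for t in range(ymin + 1, ymax + 1):
            out.append(_att_gt_cell(prep, g, t, mode, estimand))
    return out


# ------------------------------------------------------------- aggregation

@dataclass
class Aggregate:
    """An aggregated ATT with influence-function inference."""

    estimate: float
    se: float
    influence: pd.Series

    @property
    def conf_int(self) -> tuple[float, float]:
        return (
            self.estimate - _Z975 * self.se,
            self.estimate + _Z975 * self.se,
        )


def _combine(
    cells_by_group: dict[int, list[GroupTimeATT]],
    sizes: dict[int, int],
    N: int,
    membership: pd.Series | None,
) -> Aggregate:
    """Cohort-share-weighted mean of per-group time-averaged ATTs.

    Includes the delta-method influence contribution of estimating the
    cohort shares when ``membership`` (county -> group) is supplied.
    """
    groups = sorted(cells_by_group)
    p_g = {g: sizes[g] / N for g in groups}
    P = sum(p_g.values())
    theta_g = {
        g: float(np.mean([c.estimate for c in cells_by_group[g]])) for g in groups
    }
    psi_g = {
        g: sum(c.influence for c in cells_by_group[g]) / len(cells_by_group[g])
        for g in groups
    }
    theta = sum(p_g[g] * theta_g[g] for g in groups) / P
    psi = sum((p_g[g] / P) * psi_g[g] for g in groups)
    if membership is not None:
        mem = membership.to_numpy()
        for g in groups:
            indicator = (mem == g).astype(float)
            psi = psi + (theta_g[g] - theta) / P * pd.Series(
                indicator - p_g[g], index=psi.index
            )
    se = float(np.linalg.norm(psi.to_numpy()) / N)
    return Aggregate(float(theta), se, psi)


def aggregate_overall(
    atts: Sequence[GroupTimeATT],
    membership: pd.Series | None = None,
    weighting: str = "group",
) -> Aggregate:
    """Overall ATT across post-treatment cells.

    ``group`` weighting (default) averages each cohort's post-treatment
    ATT(g, t) over time, then weights cohorts by treated-county share;
    ``cell`` weighting pools all post cells weighted by cohort size.
    Weights sum to one in both cases.
    """
    post = [a for a in atts if a.is_post]
    if not post:
        raise ValueError("no post-treatment (g <= t) cells to aggregate")
    N = len(post[0].influence)
    sizes = {a.group: a.n_treated for a in post}
    if weighting == "group":
        by_group = {g: [a for a in post if a.group == g] for g in sizes}
        return _combine(by_group, sizes, N, membership)
    if weighting == "cell":
        w = np.array([sizes[a.group] for a in post], dtype=float)
        w = w / w.sum()
        theta = float(sum(wi * a.estimate for wi, a in zip(w, post)))
        psi = sum(wi * a.influence for wi, a in zip(w, post))
        se = float(np.linalg.norm(psi.to_numpy()) / N)
        return Aggregate(theta, se, psi)
    raise ValueError(f"unknown weighting {weighting!r}")


def aggregate_event_study(
    atts: Sequence[GroupTimeATT],
    membership: pd.Series | None = None,
) -> dict[int, Aggregate]:
    """Event-study aggregation: event time -> aggregated estimate.

    Post event times (e >= 0) are cohort-size-weighted means of ATT(g, g+e)
    over the groups that observe e; negative event times carry the
    varying-base pre-treatment diagnostics the same way.
    """
    if not atts:
        raise ValueError("no group-time cells to aggregate")
    N = len(atts[0].influence)
    by_e: dict[int, dict[int, list[GroupTimeATT]]] = {}
    for a in atts:
        by_e.setdefault(a.event_time, {}).setdefault(a.group, []).append(a)
    out: dict[int, Aggregate] = {}
    for e, by_group in sorted(by_e.items()):
        sizes = {g: cells[0].n_treated for g, cells in by_group.items()}
        out[e] = _combine(by_group, sizes, N, membership)
    return out


# ------------------------------------------------------------- inference

def multiplier_bootstrap(
    influence: pd.DataFrame | np.ndarray,
    reps: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Rademacher multiplier bootstrap over county-level influence functions.

    Returns pointwise SEs (interquartile-range-based, robust to heavy
    bootstrap tails) and the simultaneous critical value: the (1 - alpha)
    quantile of the max absolute studentized deviation across statistics.
    Statistics with zero influence everywhere get SE 0 and are excluded
    from the max.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    psi = np.asarray(influence, dtype=float)
    if psi.ndim == 1:
        psi = psi[:, None]
    N = psi.shape[0]
    if N < 20:
        warnings.warn("fewer than 20 clusters: bootstrap bands unreliable")
    rng = np.random.default_rng(seed)
    v = rng.choice([-1.0, 1.0], size=(reps, N))
    R = v @ psi / N  # reps x k draws of (theta* - theta)
    q75, q25 = np.quantile(R, [0.75, 0.25], axis=0)
    iqr_norm = stats.norm.ppf(0.75) - stats.norm.ppf(0.25)
    se = (q75 - q25) / iqr_norm
    nonzero = se > 0
    if not nonzero.any():
        return se, 0.0
    ratios = np.abs(R[:, nonzero]) / se[nonzero]
    crit = float(np.quantile(ratios.max(axis=1), 1 - alpha))
    return se, crit


def pretrend_wald(
    pre_estimates: np.ndarray, vcov: np.ndarray
) -> tuple[float, int, float]:
    """Joint Wald test that all pre-treatment ATTs are zero.

    statistic = a' V^{-1} a, chi-square with df = number of pre-period cells;
    a singular covariance falls back to the pseudo-inverse with df = rank.
    """
    a = np.atleast_1d(np.asarray(pre_estimates, dtype=float))
    V = np.atleast_2d(np.asarray(vcov, dtype=float))
    if len(a) == 0:
        raise ValueError("no pre-period estimates to test")
    df = len(a)
    if np.allclose(a, 0.0):
        return 0.0, df, 1.0
    try:
        stat = float(a @ np.linalg.solve(V, a))
        if not np.isfinite(stat) or stat < 0:
            raise np.linalg.LinAlgError("indefinite covariance")
    except np.linalg.LinAlgError:
        rank = int(np.linalg.matrix_rank(V))
        warnings.warn(
            f"singular pre-trend covariance; using pseudo-inverse with df={rank}"
        )
        stat = float(a @ np.linalg.pinv(V) @ a)
        df = rank
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


# ------------------------------------------------------------- front-end

@dataclass
class AggregatedResult:
    """Overall ATT, event-study profile, bands and pre-trend test."""

    mode: str
    overall: float
    overall_se: float
    overall_conf_int: tuple[float, float]
    event_study: pd.DataFrame  # event_time, estimate, se, band_lo, band_hi
    wald_stat: float
    wald_df: int
    wald_p: float
    bootstrap_reps: int
    seed: int | None
    group_time: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "overall": self.overall,
            "overall_se": self.overall_se,
            "overall_conf_int": list(self.overall_conf_int),
            "event_study": self.event_study.to_dict(orient="records"),
            "pretrend_wald": {
                "stat": self.wald_stat,
                "df": self.wald_df,
                "p": self.wald_p,
            },
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
            "group_time": self.group_time.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fit_csdid(
    rows: pd.DataFrame,
    mode: str = "unconditional",
    covariates: Sequence[str] = MODEL2_COVARIATES,
    estimand: str = "dr",
    weighting: str = "group",
    reps: int = 999,
    seed: int | None = 0,
    alpha: float = 0.05,
    bands: bool = True,
    wald_pre_window: int = 5,
) -> AggregatedResult:
    """Full group-time ATT analysis of an analysis-row panel.

    Estimates every ATT(g, t), aggregates to an overall ATT (cohort-size
    weighting by default) and an event-study profile, computes multiplier-
    bootstrap pointwise SEs and a simultaneous band over event times, and
    runs the pre-trend Wald test.

    The Wald test uses the cohort-aggregated event-study estimates at event
    times ``-wald_pre_window .. -1`` rather than every raw (g, t) pre cell:
    with cohorts of a few dozen counties the joint covariance of the full
    pre-period cell set cannot be estimated stably enough to invert, while
    the aggregated near-adoption window (matching the post-treatment horizon
    the event study reports) gives a well-calibrated test.  Pass
    ``wald_pre_window=None`` to test every aggregated pre-period event time.
    """
    atts = estimate_all_att_gt(
        rows, mode=mode, covariates=covariates, estimand=estimand
    )
    membership = (
        rows.groupby("county_id")["group_year"].first().sort_index()
    ).reindex(atts[0].influence.index)

    overall = aggregate_overall(atts, membership=membership, weighting=weighting)
    es = aggregate_event_study(atts, membership=membership)

    e_times = sorted(es)
    est = np.array([es[e].estimate for e in e_times])
    se_analytic = np.array([es[e].se for e in e_times])
    Psi = np.column_stack([es[e].influence.to_numpy() for e in e_times])

    if bands and reps > 0:
        se_boot, crit = multiplier_bootstrap(Psi, reps=reps, seed=seed, alpha=alpha)
        se_band = np.where(se_boot > 0, se_boot, se_analytic)
        if not np.any(se_boot > 0):
            crit = 0.0
    else:
        se_band, crit = se_analytic, _Z975

    es_df = pd.DataFrame(
        {
            "event_time": e_times,
            "estimate": est,
            "se": se_analytic,
            "band_lo": est - crit * se_band,
            "band_hi": est + crit * se_band,
        }
    )

    lo = -np.inf if wald_pre_window is None else -wald_pre_window
    pre_e = [e for e in e_times if lo <= e <= -1]
    if pre_e:
        a_pre = np.array([es[e].estimate for e in pre_e])
        Psi_pre = np.column_stack([es[e].influence.to_numpy() for e in pre_e])
        N = Psi_pre.shape[0]
        V_pre = Psi_pre.T @ Psi_pre / N**2
        wstat, wdf, wp = pretrend_wald(a_pre, V_pre)
    else:
        wstat, wdf, wp = 0.0, 0, 1.0

    gt_df = pd.DataFrame(
        {
            "group": [a.group for a in atts],
            "time": [a.time for a in atts],
            "event_time": [a.event_time for a in atts],
            "estimate": [a.estimate for a in atts],
            "se": [a.se for a in atts],
            "n_treated": [a.n_treated for a in atts],
            "n_control": [a.n_control for a in atts],
        }
    )

    return AggregatedResult(
        mode=mode,
        overall=overall.estimate,
        overall_se=overall.se,
        overall_conf_int=overall.conf_int,
        event_study=es_df,
        wald_stat=wstat,
        wald_df=wdf,
        wald_p=wp,
        bootstrap_reps=reps if bands else 0,
        seed=seed,
        group_time=gt_df,
    )
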