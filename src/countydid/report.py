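"""Pipeline orchestration: simulate -> build -> fit -> compare.

Runs the five estimators (Models 1-3 and the unconditional/conditional
group-time ATT) on a generated panel, emits a comparison table on the log
and percent scales, the event-study profile with uniform bands, and a
Monte Carlo harness for bias / SE / coverage validation of the estimators.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .csdid import AggregatedResult, fit_csdid
from .panel_builder import FilterCriteria, apply_sample_filters, build_analysis_rows
from .synthetic_panel import SimConfig, SimTruth, generate_panel, write_panel
from .twfe import ModelSpec, TwfeFit, fit_twfe, interpret_as_percent

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "monte_carlo_study",
    "summarize_monte_carlo",
    "ALL_ESTIMATORS",
]

logger = logging.getLogger("countydid")

ALL_ESTIMATORS = (
    "model1",
    "model2",
    "model3",
    "cs_unconditional",
    "cs_conditional",
)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: generator settings, estimators, seeds."""

    sim: SimConfig = field(default_factory=SimConfig)
    age_mode: str = "aggregate"
    estimators: tuple[str, ...] = ALL_ESTIMATORS
    bootstrap_reps: int = 999
    seed: int = 0

    def __post_init__(self):
        if not self.estimators:
            raise ValueError("estimator list must be non-empty")
        unknown = set(self.estimators) - set(ALL_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators {sorted(unknown)}")

    @property
    def bootstrap_seed(self) -> int:
        return (self.seed + 500_003) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "effect_path" in sim_raw:
            sim_raw["effect_path"] = {
                int(k): float(v) for k, v in sim_raw["effect_path"].items()
            }
        if "cohorts" in sim_raw:
            sim_raw["cohorts"] = tuple(tuple(c) for c in sim_raw["cohorts"])
        sim = SimConfig(**sim_raw)
        if "estimators" in raw:
            raw["estimators"] = tuple(raw["estimators"])
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "age_mode": self.age_mode,
            "estimators": list(self.estimators),
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    table: pd.DataFrame
    twfe_fits: dict[str, TwfeFit]
    cs_results: dict[str, AggregatedResult]
    filter_report: object
    truth: SimTruth
    n_obs: int
    n_counties: int


def _fit_one(name: str, rows: pd.DataFrame, cfg: RunConfig):
    if name.startswith("model"):
        spec = ModelSpec.from_id(int(name[-1]))
        return fit_twfe(rows, spec)
    mode = "unconditional" if name.endswith("unconditional") else "conditional"
    return fit_csdid(
        rows,
        mode=mode,
        reps=cfg.bootstrap_reps,
        seed=cfg.bootstrap_seed,
    )


def _table_row(name: str, fit, n_obs: int, n_counties: int) -> dict:
    if isinstance(fit, TwfeFit):
        est, se, ci = fit.estimate, fit.se, fit.conf_int
    else:
        est, se, ci = fit.overall, fit.overall_se, fit.overall_conf_int
    pct = interpret_as_percent(est)
    return {
        "estimator": name,
        "estimate": est,
        "se": se,
        "ci_lo": ci[0],
        "ci_hi": ci[1],
        "percent_exact": pct.exact,
        "percent_rough": pct.rough,
        "percent_ci_lo": 100.0 * float(np.expm1(ci[0])),
        "percent_ci_hi": 100.0 * float(np.expm1(ci[1])),
        "n_obs": n_obs,
        "n_counties": n_counties,
    }


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Simulate a panel, build analysis rows, fit the requested estimators.

    Deterministic given the config seeds.  When ``out_dir`` is given, writes
    the panel, filter report, comparison table (CSV + JSON), event-study CSV,
    a manifest with a config hash, and a stage-by-stage log file.
    """
    out = Path(out_dir) if out_dir is not None else None
    handler = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        sim = replace(config.sim, seed=config.seed)
        logger.info("simulate: %d counties x %d years", sim.n_counties, len(sim.years))
        panel, truth = generate_panel(sim)
        if out is not None:
            write_panel(panel, out / "panel.csv")
            truth.to_json(out / "truth.json")

        criteria = FilterCriteria.make(
            abstinence_counties=truth.abstinence_counties,
            allowed_cohort_years=[y for y, _ in sim.cohorts],
        )
        filtered, report = apply_sample_filters(panel, criteria)
        logger.info(
            "filters: %d -> %d counties (%s)",
            report.n_input,
            report.n_remaining,
            dict(zip(report.rule_names, report.counts)),
        )
        if out is not None:
            with open(out / "filter_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=1)

        rows = build_analysis_rows(filtered, age_mode=config.age_mode)
        n_obs = len(rows)
        n_counties = rows["county_id"].nunique()
        logger.info("analysis rows: %d (%d counties)", n_obs, n_counties)

        twfe_fits: dict[str, TwfeFit] = {}
        cs_results: dict[str, AggregatedResult] = {}
        table_rows = []
        for name in config.estimators:
            try:
                fit = _fit_one(name, rows, config)
            except Exception as exc:
                raise RuntimeError(f"estimator stage '{name}' failed: {exc}") from exc
            if isinstance(fit, TwfeFit):
                twfe_fits[name] = fit
                logger.info(
                    "%s: %.5f (se %.5f), dropped=%s",
                    name, fit.estimate, fit.se, fit.dropped_columns,
                )
            else:
                cs_results[name] = fit
                logger.info(
                    "%s: %.5f (se %.5f), Wald p=%.3f",
                    name, fit.overall, fit.overall_se, fit.wald_p,
                )
            table_rows.append(_table_row(name, fit, n_obs, n_counties))

        table = pd.DataFrame(table_rows)
        if out is not None:
            table.to_csv(out / "comparison.csv", index=False)
            table.to_json(out / "comparison.json", orient="records", indent=1)
            preferred = cs_results.get(
                "cs_conditional", cs_results.get("cs_unconditional")
            )
            if preferred is not None:
                preferred.event_study.to_csv(out / "event_study.csv", index=False)
            cfg_json = json.dumps(config.to_dict(), sort_keys=True)
            manifest = {
                "config": config.to_dict(),
                "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "seed": config.seed,
                "bootstrap_seed": config.bootstrap_seed,
                "countydid_version": _pkg_version,
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
            }
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
        return PipelineResult(
            table=table,
            twfe_fits=twfe_fits,
            cs_results=cs_results,
            filter_report=report,
            truth=truth,
            n_obs=n_obs,
            n_counties=n_counties,
        )
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def monte_carlo_study(
    sim: SimConfig,
    n_reps: int,
    estimators: Sequence[str] = ALL_ESTIMATORS,
    seed: int = 0,
    bootstrap_reps: int = 0,
    event_diagnostics: bool = False,
) -> pd.DataFrame:
    """Repeatedly simulate and estimate; one record per (rep, estimator).

    Replication r uses generator seed ``seed + r`` (and bootstrap seed
    ``seed + 500_003 + r`` when bands are requested), so results are exactly
    reproducible.  Records carry the estimate, SE, the matching true
    estimand (cohort-weighted for the group-time estimators, treated-cell-
    weighted for the regression models), CI coverage, and for the group-time
    estimators the pre-trend Wald p-value and, optionally, event-study band
    diagnostics.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    records = []
    for r in range(n_reps):
        sim_r = replace(sim, seed=seed + r)
        panel, truth = generate_panel(sim_r)
        criteria = FilterCriteria.make(
            abstinence_counties=truth.abstinence_counties,
            allowed_cohort_years=[y for y, _ in sim_r.cohorts],
        )
        filtered, _ = apply_sample_filters(panel, criteria)
        rows = build_analysis_rows(filtered)
        for name in estimators:
            rec = {"rep": r, "estimator": name}
            if name.startswith("model"):
                fit = fit_twfe(rows, ModelSpec.from_id(int(name[-1])))
                est, se, ci = fit.estimate, fit.se, fit.conf_int
                truth_val = truth.att_overall
            else:
                mode = (
                    "unconditional" if name.endswith("unconditional") else "conditional"
                )
                use_bands = event_diagnostics and bootstrap_reps > 0
                res = fit_csdid(
                    rows,
                    mode=mode,
                    reps=bootstrap_reps if use_bands else 0,
                    seed=(seed + 500_003 + r) % (2**31 - 1),
                    bands=use_bands,
                )
                est, se, ci = res.overall, res.overall_se, res.overall_conf_int
                truth_val = truth.att_overall_group
                rec["wald_p"] = res.wald_p
                if event_diagnostics:
                    es = res.event_study
                    post = es[es["event_time"] >= 0]
                    true_path = post["event_time"].map(truth.event_time_effects)
                    rec["band_covers_path"] = bool(
                        (
                            (post["band_lo"] <= true_path)
                            & (true_path <= post["band_hi"])
                        ).all()
                    )
                    by_e = post.set_index("event_time")["estimate"]
                    if 0 in by_e.index and 4 in by_e.index:
                        rec["e4_more_negative_than_e0"] = bool(by_e[4] < by_e[0])
            rec.update(
                estimate=est,
                se=se,
                truth=truth_val,
                covered=bool(ci[0] <= truth_val <= ci[1]),
            )
            records.append(rec)
    return pd.DataFrame(records)


def summarize_monte_carlo(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-estimator bias, spread, reported-SE mean, coverage, Wald size."""
    out = []
    for name, grp in records.groupby("estimator", sort=False):
        row = {
            "estimator": name,
            "n_reps": len(grp),
            "mean_estimate": grp["estimate"].mean(),
            "truth": grp["truth"].mean(),
            "bias": (grp["estimate"] - grp["truth"]).mean(),
            "empirical_sd": grp["estimate"].std(ddof=1),
            "mean_se": grp["se"].mean(),
            "coverage": grp["covered"].mean(),
            "mc_se_of_mean": grp["estimate"].std(ddof=1) / np.sqrt(len(grp)),
        }
        if "wald_p" in grp and grp["wald_p"].notna().any():
            row["wald_reject_rate"] = (grp["wald_p"] < alpha).mean()
        if "band_covers_path" in grp and grp["band_covers_path"].notna().any():
            row["band_coverage"] = grp["band_covers_path"].mean()
        if (
            "e4_more_negative_than_e0" in grp
            and grp["e4_more_negative_than_e0"].notna().any()
        ):
            row["e4_more_negative_rate"] = grp["e4_more_negative_than_e0"].mean()
        out.append(row)
    return pd.DataFrame(out)
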