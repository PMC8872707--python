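"""Canonical study configurations.

``full_scale_config`` reproduces the full design the package targets:
2,927 counties in 49 states observed 1996-2017 with funding cohorts of 36
counties (2010) and 19 more (2015).  The ``calibration_*`` variants keep the
cohort sizes and the 22-year window but carry 300 counties in 10 states, a
scale at which repeated Monte Carlo estimation is affordable while every
estimator still has the treated-county counts of the full design.
"""

from __future__ import annotations


from .synthetic_panel import SimConfig, default_effect_path

__all__ = [
    "full_scale_config",
    "calibration_null_config",
    "calibration_ramp_config",
    "confounded_trend_config",
]


def full_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """Full-scale design: 2,927 counties, cohorts (2010, 36) and (2015, 19)."""
    return SimConfig(seed=seed, **overrides)


def _calibration_base(seed: int, **overrides) -> SimConfig:
    defaults = dict(
        n_states=10,
        counties_per_state=30,
        total_counties=300,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def calibration_null_config(seed: int = 0, **overrides) -> SimConfig:
    """No treatment effect, parallel trends: estimator size/coverage checks."""
    zero_path = {e: 0.0 for e in default_effect_path()}
    return _calibration_base(seed, effect_path=zero_path, **overrides)


def calibration_ramp_config(seed: int = 0, **overrides) -> SimConfig:
    """Default ramping effect path at calibration scale: recovery checks."""
    return _calibration_base(seed, **overrides)


def confounded_trend_config(seed: int = 0, effect: float = -0.03, **overrides) -> SimConfig:
    """Adoption correlated with county trend slopes.

    Counties on steeper declining trends are more likely to be funded
    (selection weight 1.5 on the standardized negative slope), and trend
    heterogeneity is doubled, so estimators that ignore county trends
    attribute part of the pre-existing decline to funding.  The true effect
    is a constant ``effect`` at every event time.
    """
    path = {e: effect for e in default_effect_path()}
    defaults = dict(
        effect_path=path,
        sigma_trend=0.008,
        adoption_trend_bias=1.5,
    )
    defaults.update(overrides)
    return _calibration_base(seed, **defaults)
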