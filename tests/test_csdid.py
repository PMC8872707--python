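"""Group-time ATT estimation, aggregation, bootstrap and pre-trend test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from countydid.csdid import (
    GroupTimeATT,
    aggregate_event_study,
    aggregate_overall,
    att_gt,
    estimate_all_att_gt,
    fit_csdid,
    multiplier_bootstrap,
    pretrend_wald,
)
from countydid.twfe import ModelSpec, fit_twfe


def _gt(group, time, estimate, n_treated=5, counties=10):
    idx = [f"C{i}" for i in range(counties)]
    return GroupTimeATT(
        group=group,
        time=time,
        estimate=estimate,
        se=0.0,
        influence=pd.Series(0.0, index=idx),
        n_treated=n_treated,
        n_control=counties - n_treated,
    )


class TestAttGt:
    def test_2x2_equals_twfe_did(self, did_2x2_rows):
        res = att_gt(did_2x2_rows, g=2, t=2, mode="unconditional")
        twfe = fit_twfe(did_2x2_rows, ModelSpec.from_id(1))
        assert res.estimate == pytest.approx(-0.2, abs=1e-12)
        assert res.estimate == pytest.approx(twfe.estimate, abs=1e-12)

    def test_conditional_with_constant_covariate_equals_unconditional(
        self, did_2x2_rows
    ):
        rows = pd.concat(
            [did_2x2_rows] * 12, ignore_index=True
        )  # replicate counties for a non-trivial logit
        rows["county_id"] = rows["county_id"] + (rows.index // 4).astype(str)
        rows["const_cov"] = 3.14
        unc = att_gt(rows, g=2, t=2, mode="unconditional")
        cond = att_gt(rows, g=2, t=2, mode="conditional", covariates=["const_cov"])
        assert cond.estimate == pytest.approx(unc.estimate, abs=1e-8)

    def test_no_never_treated_comparison_rejected(self, did_2x2_rows):
        rows = did_2x2_rows.assign(group_year=2)
        with pytest.raises(ValueError, match="never-treated"):
            att_gt(rows, g=2, t=2)

    def test_pre_period_uses_year_on_year_change(self):
        # three years, treated group starts in year 3; pre cell at t=2
        rows = pd.DataFrame(
            {
                "county_id": list("AAABBB"),
                "state_id": ["S"] * 6,
                "year": [1, 2, 3] * 2,
                "outcome": [1.0, 1.4, 2.0, 1.0, 1.1, 1.2],
                "treat_lag": [0, 0, 1, 0, 0, 0],
                "group_year": [3] * 3 + [0] * 3,
            }
        )
        pre = att_gt(rows, g=3, t=2)
        assert pre.estimate == pytest.approx((1.4 - 1.0) - (1.1 - 1.0), abs=1e-12)


class TestDoublyRobust:
    @staticmethod
    def _dr_rows(rng, pattern, n=500, att=-0.5):
        x = rng.normal(size=n)
        if pattern == "ps_misspecified":
            p = 1 / (1 + np.exp(-(0.5 * x + 0.8 * x**2 - 0.8)))
            delta = 1.0 + 2.0 * x + rng.normal(0, 0.5, n)
        else:  # outcome regression misspecified, propensity correct
            p = 1 / (1 + np.exp(-(0.8 * x - 0.5)))
            delta = x**2 + rng.normal(0, 0.5, n)
        d = rng.random(n) < p
        if d.sum() < 10 or (~d).sum() < 10:
            raise RuntimeError("degenerate draw")
        y0 = 0.1 * x + rng.normal(0, 0.2, n)
        y1 = y0 + delta + att * d
        recs = []
        for i in range(n):
            for year, y in ((2000, y0[i]), (2001, y1[i])):
                recs.append(
                    {
                        "county_id": f"C{i:04d}",
                        "state_id": "S0",
                        "year": year,
                        "outcome": y,
                        "treat_lag": int(d[i] and year == 2001),
                        "group_year": 2001 if d[i] else 0,
                        "x": x[i],
                    }
                )
        return pd.DataFrame(recs)

    @pytest.mark.parametrize("pattern", ["ps_misspecified", "or_misspecified"])
    def test_consistent_when_either_nuisance_model_is_correct(self, pattern):
        rng = np.random.default_rng(42)
        errs, ses = [], []
        for _ in range(40):
            rows = self._dr_rows(rng, pattern)
            res = att_gt(rows, g=2001, t=2001, mode="conditional", covariates=["x"])
            errs.append(res.estimate - (-0.5))
            ses.append(res.se)
        assert abs(np.mean(errs)) < np.mean(ses) / 2


class TestAggregation:
    def test_single_group_overall_is_equal_weight_time_mean(self):
        atts = [_gt(2, 2, -0.01), _gt(2, 3, -0.03)]
        agg = aggregate_overall(atts)
        assert agg.estimate == pytest.approx(-0.02, abs=1e-12)

    def test_two_equal_size_groups_weighted_mean(self):
        atts = [_gt(2, 2, -0.02), _gt(2, 3, -0.02), _gt(3, 3, -0.04)]
        agg = aggregate_overall(atts)
        assert agg.estimate == pytest.approx(-0.03, abs=1e-12)

    def test_unequal_groups_weighted_by_size(self):
        atts = [_gt(2, 2, -0.02, n_treated=3), _gt(3, 3, -0.05, n_treated=1)]
        agg = aggregate_overall(atts)
        assert agg.estimate == pytest.approx((3 * -0.02 + 1 * -0.05) / 4, abs=1e-12)

    def test_no_post_cells_rejected(self):
        with pytest.raises(ValueError, match="post"):
            aggregate_overall([_gt(5, 3, 0.1)])

    def test_single_group_event_study_reindexes_att_sequence(self):
        atts = [_gt(3, t, est) for t, est in [(2, 0.01), (3, -0.02), (4, -0.04)]]
        es = aggregate_event_study(atts)
        assert set(es) == {-1, 0, 1}
        assert es[0].estimate == pytest.approx(-0.02)
        assert es[1].estimate == pytest.approx(-0.04)
        assert es[-1].estimate == pytest.approx(0.01)


class TestMultiplierBootstrap:
    def test_zero_influence_gives_zero_ses_and_degenerate_band(self):
        psi = np.zeros((50, 4))
        se, crit = multiplier_bootstrap(psi, reps=200, seed=0)
        assert np.all(se == 0.0)
        assert crit == 0.0

    def test_single_statistic_critical_value_is_its_own_pointwise_quantile(self):
        rng = np.random.default_rng(3)
        psi = rng.normal(size=(200, 1))
        se1, crit1 = multiplier_bootstrap(psi, reps=2000, seed=5)
        # duplicating the same statistic cannot change the max-based critical value
        se2, crit2 = multiplier_bootstrap(np.column_stack([psi, psi]), reps=2000, seed=5)
        assert crit1 == pytest.approx(crit2, abs=1e-12)
        assert crit1 == pytest.approx(stats.norm.ppf(0.975), rel=0.1)

    def test_normal_influence_recovers_analytic_se(self):
        rng = np.random.default_rng(8)
        psi = rng.normal(0, 2.0, size=(400, 3))
        se, _ = multiplier_bootstrap(psi, reps=9999, seed=17)
        analytic = np.sqrt((psi**2).sum(axis=0)) / psi.shape[0]
        np.testing.assert_allclose(se, analytic, rtol=0.05)

    def test_reproducible_under_fixed_seed(self):
        psi = np.random.default_rng(1).normal(size=(60, 2))
        a = multiplier_bootstrap(psi, reps=500, seed=9)
        b = multiplier_bootstrap(psi, reps=500, seed=9)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_few_clusters_warn(self):
        with pytest.warns(UserWarning, match="20 clusters"):
            multiplier_bootstrap(np.ones((5, 1)), reps=50, seed=0)


class TestPretrendWald:
    def test_all_zero_estimates_give_p_one(self):
        stat, df, p = pretrend_wald(np.zeros(4), np.eye(4))
        assert (stat, df, p) == (0.0, 4, 1.0)

    def test_scalar_case_is_squared_z(self):
        est, se = 0.7, 0.25
        stat, df, p = pretrend_wald([est], [[se**2]])
        z = est / se
        assert stat == pytest.approx(z**2, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-9)

    def test_singular_covariance_uses_pseudo_inverse_with_reduced_df(self):
        V = np.outer([1.0, 1.0], [1.0, 1.0])  # rank 1
        with pytest.warns(UserWarning, match="singular"):
            stat, df, p = pretrend_wald([0.3, 0.3], V)
        assert df == 1
        assert 0 <= p <= 1


@pytest.fixture(scope="module")
def ramp_rows():
    from countydid.panel_builder import apply_sample_filters, build_analysis_rows
    from countydid.presets import calibration_ramp_config
    from countydid.synthetic_panel import generate_panel

    panel, truth = generate_panel(calibration_ramp_config(seed=77))
    filt, _ = apply_sample_filters(panel)
    return build_analysis_rows(filt), truth


class TestFitCsdid:
    def test_simultaneous_band_contains_pointwise_band(self, ramp_rows):
        rows, _ = ramp_rows
        res = fit_csdid(rows, mode="unconditional", reps=499, seed=3)
        es = res.event_study
        point_lo = es["estimate"] - 1.96 * es["se"]
        point_hi = es["estimate"] + 1.96 * es["se"]
        # allow bootstrap-vs-analytic SE wiggle on the comparison
        assert (es["band_lo"] <= point_lo + 0.25 * es["se"]).all()
        assert (es["band_hi"] >= point_hi - 0.25 * es["se"]).all()

    def test_overall_is_group_weighted_mean_of_post_cells(self, ramp_rows):
        rows, _ = ramp_rows
        res = fit_csdid(rows, mode="unconditional", reps=0, bands=False)
        gt = res.group_time
        post = gt[gt["event_time"] >= 0]
        manual = (
            post.groupby("group")
            .agg(theta=("estimate", "mean"), n=("n_treated", "first"))
        )
        expected = (manual["theta"] * manual["n"]).sum() / manual["n"].sum()
        assert res.overall == pytest.approx(expected, abs=1e-12)

    def test_event_study_serialization_round_trip(self, ramp_rows, tmp_path):
        rows, _ = ramp_rows
        res = fit_csdid(rows, mode="unconditional", reps=99, seed=1)
        path = tmp_path / "agg.json"
        res.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["overall"] == pytest.approx(res.overall)
        assert len(loaded["event_study"]) == len(res.event_study)
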