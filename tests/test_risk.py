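"""Logistic/Cox/C-statistic evaluation against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from methylpanel.containers import PanelDefinition
from methylpanel.risk import (
    baseline_subsample, c_statistic, fit_cox, fit_logistic, roc_curve,
    rtl_slope, validate_external, zscale,
)


class TestZscale:
    def test_sample_sd_convention(self):
        np.testing.assert_allclose(zscale([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self, rng):
        x = rng.normal(size=50)
        z = zscale(x)
        np.testing.assert_allclose(zscale(z), z, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(zscale(3.0 * x + 7.0), zscale(x), atol=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            zscale([2.0, 2.0, 2.0])


class TestLogistic:
    def test_two_by_two_matches_cross_product_odds_ratio(self):
        # e4-carrier counts: cases 112 of 146, controls 76 of 324
        y = np.concatenate([np.ones(146), np.zeros(324)])
        x = np.concatenate([np.ones(112), np.zeros(34),
                            np.ones(76), np.zeros(248)])
        res = fit_logistic(y, pd.DataFrame({"e4": x}), z_continuous=False)
        expected = (112 * 248) / (34 * 76)
        assert res.ratio("e4") == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(10.75, abs=0.01)

    def test_null_predictor_or_near_one(self, rng):
        n = 4000
        y = rng.integers(0, 2, size=n)
        x = rng.normal(size=n)
        res = fit_logistic(y, pd.DataFrame({"x": x}))
        assert res.ratio("x") == pytest.approx(1.0, abs=0.12)

    def test_or_invariant_to_raw_units_when_zscored(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        r1 = fit_logistic(y, pd.DataFrame({"x": x}))
        r2 = fit_logistic(y, pd.DataFrame({"x": 1000.0 * x}))
        assert r1.ratio("x") == pytest.approx(r2.ratio("x"), rel=1e-8)

    def test_perfect_separation_flagged(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        x = np.array([0.0] * 10 + [1.0] * 10)
        res = fit_logistic(y, pd.DataFrame({"x": x}), z_continuous=False)
        assert res.flags.get("separation", False)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(5), pd.DataFrame({"x": np.arange(5.0)}))


def cox_partial_likelihood(b, times, events, x):
    """Negative log partial likelihood, no ties (brute-force oracle)."""
    nll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        nll -= b * x[i] - np.log(np.exp(b * x[risk]).sum())
    return nll


class TestCox:
    def test_matches_bruteforce_partial_likelihood(self, rng):
        for _ in range(12):
            n = int(rng.integers(4, 7))
            times = rng.uniform(1, 10, size=n)
            while len(np.unique(times)) < n:
                times = rng.uniform(1, 10, size=n)
            events = rng.integers(0, 2, size=n).astype(float)
            if events.sum() < 2:
                events[:2] = 1.0
            x = rng.normal(size=n)
            res = fit_cox(times, events, pd.DataFrame({"x": x}),
                          z_continuous=False)
            b_opt = optimize.minimize_scalar(
                cox_partial_likelihood, bounds=(-25, 25), method="bounded",
                args=(times, events, x),
                options={"xatol": 1e-10}).x
            if abs(b_opt) > 10:  # monotone likelihood: skip comparison
                continue
            b_fit = float(np.log(res.ratio("x")))
            assert b_fit == pytest.approx(b_opt, abs=1e-5)

    def test_null_covariate_hr_near_one(self, rng):
        n = 3000
        t = rng.exponential(10, size=n)
        e = np.ones(n)
        x = rng.normal(size=n)
        res = fit_cox(t, e, pd.DataFrame({"x": x}))
        assert res.ratio("x") == pytest.approx(1.0, abs=0.08)

    def test_time_scaling_leaves_hr_unchanged(self, rng):
        n = 60
        t = rng.exponential(10, size=n)
        e = (rng.random(n) < 0.7).astype(float)
        x = rng.normal(size=n)
        r1 = fit_cox(t, e, pd.DataFrame({"x": x}))
        r2 = fit_cox(10.0 * t, e, pd.DataFrame({"x": x}))
        assert r1.ratio("x") == pytest.approx(r2.ratio("x"), rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.1, 0.2]}))

    def test_collinearity_flagged(self, rng):
        n = 80
        t = rng.exponential(10, size=n)
        e = (rng.random(n) < 0.6).astype(float)
        x = rng.normal(size=n)
        res = fit_cox(t, e, pd.DataFrame({"a": x, "b": x + 1e-9 * rng.normal(size=n)}))
        assert "collinearity" in res.flags


class TestCStatistic:
    def test_perfect_separation_is_one(self):
        assert c_statistic([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_identical_scores_half(self):
        assert c_statistic([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_pair_counting_examples(self):
        # cases (0.4, 0.8) each beat both controls (0.1, 0.35): 4/4
        assert c_statistic([0.1, 0.4, 0.35, 0.8], [0, 1, 0, 1]) == 1.0
        # 2 cases x 4 controls, case 0.4 loses to control 0.45: 7/8
        scores = [0.1, 0.2, 0.3, 0.45, 0.4, 0.8]
        labels = [0, 0, 0, 0, 1, 1]
        assert c_statistic(scores, labels) == pytest.approx(0.875)

    def test_exhaustive_pair_counting_random(self, rng):
        for _ in range(10):
            n = 30
            scores = rng.normal(size=n).round(1)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            cases = scores[labels == 1]
            ctrls = scores[labels == 0]
            wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
            oracle = wins / (len(cases) * len(ctrls))
            assert c_statistic(scores, labels) == pytest.approx(oracle)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = c_statistic(scores, labels)
        b = c_statistic(np.exp(scores), labels)
        assert a == pytest.approx(b)

    def test_roc_curve_endpoints(self, rng):
        pts = roc_curve(rng.normal(size=20), rng.integers(0, 2, size=20))
        assert pts.fpr.iloc[-1] == 1.0 and pts.tpr.iloc[-1] == 1.0


class TestRtlSlope:
    def test_exact_linear(self):
        sheet = pd.DataFrame({
            "subject_id": ["a"] * 3, "age": [60.0, 65.0, 70.0],
            "rtl": [2 - 0.01 * 60, 2 - 0.01 * 65, 2 - 0.01 * 70],
        })
        assert rtl_slope(sheet)["a"] == pytest.approx(-0.01)

    def test_constant_rtl_zero_slope(self):
        sheet = pd.DataFrame({"subject_id": ["a"] * 3,
                              "age": [60.0, 65.0, 70.0], "rtl": [1.0] * 3})
        assert rtl_slope(sheet)["a"] == pytest.approx(0.0)

    def test_two_points_rise_over_run(self):
        sheet = pd.DataFrame({"subject_id": ["a", "a"], "age": [60.0, 70.0],
                              "rtl": [1.0, 0.8]})
        assert rtl_slope(sheet)["a"] == pytest.approx(-0.02)

    def test_single_visit_missing_with_warning(self):
        sheet = pd.DataFrame({"subject_id": ["a"], "age": [60.0], "rtl": [1.0]})
        assert np.isnan(rtl_slope(sheet)["a"])


def test_baseline_subsample_takes_earliest(small_cohort):
    _, _, sheet, _ = small_cohort
    base = baseline_subsample(sheet)
    assert len(base) == sheet.subject_id.nunique()
    for sid, grp in sheet.groupby("subject_id"):
        assert base.set_index("subject_id").loc[sid, "time"] == grp.time.min()


class TestValidateExternal:
    @pytest.fixture(scope="class")
    def external(self):
        from methylpanel.simulate import CohortConfig, generate_cohort, \
            generate_external_cohort
        cfg = CohortConfig(seed=31, n_pairs=10, n_cpgs=500, n_deconv_cpgs=150,
                           n_stable_effect_cpgs=10, n_clock_cpgs=10,
                           n_interaction_cpgs=0, n_crossover_cpgs=0,
                           n_aging_cpgs=0, effect_size_delta_beta=0.10)
        _, _, truth = generate_cohort(cfg)
        stable = truth.probe_class.index[truth.probe_class == "stable"]
        panel = PanelDefinition(
            probes=list(stable),
            signs={p: int(np.sign(truth.true_delta_beta[p])) for p in stable},
        )
        scan_like = pd.DataFrame(
            {"estimate": truth.true_delta_beta.loc[stable]}, index=stable)
        return cfg, truth, panel, scan_like

    def _run(self, cfg, truth, panel, scan_like, attenuation, n=250, seed=5):
        from methylpanel.simulate import generate_external_cohort
        from methylpanel.deconvolution import estimate_proportions
        m, sheet = generate_external_cohort(cfg, truth, n_controls=n,
                                            n_cases=n, attenuation=attenuation,
                                            seed=seed)
        ref = truth.reference.loc[truth.deconv_probes]
        props = estimate_proportions(m.subset_probes(truth.deconv_probes), ref)
        gran = props["granulocyte"]
        return validate_external(panel, m, sheet, gran, scan_results=scan_like)

    def test_attenuation_zero_gives_null_panel(self, external):
        out = self._run(*external, attenuation=0.0)
        assert out["panel_or_per_sd"] == pytest.approx(1.0, abs=0.35)
        assert abs(out["auc_with_panel"] - out["auc_covariates"]) < 0.05

    def test_full_signal_improves_discrimination(self, external):
        out = self._run(*external, attenuation=1.0)
        assert out["auc_with_panel"] > out["auc_covariates"] + 0.05
        assert out["panel_or_per_sd"] > 1.5

    def test_direction_concordance_counts_planted_signs(self, external):
        out = self._run(*external, attenuation=1.0)
        assert out["n_direction_concordant"] >= 9  # 10 planted CpGs
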