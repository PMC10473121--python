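"""Probe-wise scan, inflation factor, BH adjustment, panel rule and score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methylpanel.containers import BetaMatrix, PanelDefinition
from methylpanel.ewas import (
    bh_adjust, ewas_scan, genomic_lambda, panel_score, select_panel,
)
from methylpanel.lmm import LmmSpec
from methylpanel.simulate import CohortConfig, generate_cohort


def bh_oracle(p):
    """Brute-force step-up definition, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestGenomicLambda:
    def test_all_half_is_exactly_one(self):
        assert genomic_lambda(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_uniform_null(self, rng):
        p = rng.uniform(size=100_000)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.02)

    def test_doubling_statistics_doubles_lambda(self, rng):
        q = rng.chisquare(1, size=50_000)
        p1 = stats.chi2.sf(q, 1)
        p2 = stats.chi2.sf(2 * q, 1)
        lam1 = genomic_lambda(p1)
        lam2 = genomic_lambda(p2)
        assert lam2 / lam1 == pytest.approx(2.0, rel=0.02)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            genomic_lambda([0.5, 0.0])


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_identical_values_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_and_bounds(self, pvals):
        adj = bh_adjust(pvals)
        np.testing.assert_allclose(adj, bh_oracle(pvals), atol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestSelectPanel:
    def _results(self, rows):
        return pd.DataFrame(rows, index=[f"cg{i:08d}" for i in range(len(rows))])

    def test_composite_rule(self):
        res = self._results([
            # selected: significant, large, consistent sign
            {"estimate": 0.06, "p": 5e-4, "diff_at_tmin": 0.05, "diff_at_tmax": 0.07},
            # rejected: effect below threshold
            {"estimate": 0.04, "p": 5e-4, "diff_at_tmin": 0.03, "diff_at_tmax": 0.05},
            # rejected: crossover (sign flip between time extremes)
            {"estimate": -0.06, "p": 5e-4, "diff_at_tmin": -0.1, "diff_at_tmax": 0.02},
            # rejected: not significant
            {"estimate": 0.08, "p": 0.01, "diff_at_tmin": 0.07, "diff_at_tmax": 0.09},
        ])
        panel = select_panel(res)
        assert panel.probes == ["cg00000000"]
        assert panel.signs["cg00000000"] == 1
        assert panel.weights["cg00000000"] == pytest.approx(0.06)

    def test_negative_effect_gets_negative_sign(self):
        res = self._results([{"estimate": -0.07, "p": 1e-5,
                              "diff_at_tmin": -0.06, "diff_at_tmax": -0.08}])
        panel = select_panel(res)
        assert panel.signs[panel.probes[0]] == -1

    def test_empty_selection_is_valid(self):
        res = self._results([{"estimate": 0.01, "p": 0.5,
                              "diff_at_tmin": 0.0, "diff_at_tmax": 0.02}])
        panel = select_panel(res)
        assert len(panel) == 0


class TestPanelScore:
    def _matrix(self, vals):
        v = pd.DataFrame(vals, index=[f"cg{i:08d}" for i in range(len(vals))],
                         columns=["s0"])
        return BetaMatrix(values=v)

    def test_signed_sum(self):
        m = self._matrix([[0.6], [0.4]])
        panel = PanelDefinition(probes=list(m.probes),
                                signs={m.probes[0]: 1, m.probes[1]: -1})
        assert panel_score(m, panel).iloc[0] == pytest.approx(0.2)

    def test_zero_beta_zero_score(self):
        m = self._matrix([[0.0], [0.0]])
        panel = PanelDefinition(probes=list(m.probes),
                                signs={p: 1 for p in m.probes})
        assert panel_score(m, panel).iloc[0] == 0.0

    def test_weighted_with_sign_weights_equals_unweighted(self):
        m = self._matrix([[0.6], [0.4], [0.3]])
        signs = {m.probes[0]: 1, m.probes[1]: -1, m.probes[2]: 1}
        panel = PanelDefinition(probes=list(m.probes), signs=signs,
                                weights={p: float(s) for p, s in signs.items()})
        assert (panel_score(m, panel, weighted=True).iloc[0]
                == pytest.approx(panel_score(m, panel).iloc[0]))

    def test_probe_order_invariance(self, rng):
        vals = rng.uniform(size=(6, 4))
        m = self._matrix(vals[:, :1])
        m = BetaMatrix(values=pd.DataFrame(
            vals, index=m.probes, columns=[f"s{j}" for j in range(4)]))
        signs = {p: int(s) for p, s in zip(m.probes, rng.choice([-1, 1], 6))}
        panel = PanelDefinition(probes=list(m.probes), signs=signs)
        perm = rng.permutation(list(m.probes)).tolist()
        panel2 = PanelDefinition(probes=perm, signs=signs)
        pd.testing.assert_series_equal(panel_score(m, panel),
                                       panel_score(m, panel2))

    def test_missing_probe_errors(self):
        m = self._matrix([[0.6]])
        panel = PanelDefinition(probes=["cg99999999"], signs={"cg99999999": 1})
        with pytest.raises(KeyError, match="cg99999999"):
            panel_score(m, panel)


@pytest.fixture(scope="module")
def scan_cohort():
    cfg = CohortConfig(seed=21, n_pairs=20, n_cpgs=220, n_deconv_cpgs=60,
                       n_stable_effect_cpgs=6, n_interaction_cpgs=0,
                       n_crossover_cpgs=6, n_aging_cpgs=0, n_clock_cpgs=0,
                       effect_size_delta_beta=0.08, missing_rate=0.0)
    m, sheet, truth = generate_cohort(cfg)
    spec = LmmSpec(include_apoe=True, include_smoking=False,
                   include_granulocyte=False)
    results = ewas_scan(m, sheet, spec)
    return m, sheet, truth, results


class TestEwasScan:
    def test_planted_effect_recovered(self, scan_cohort):
        _, _, truth, results = scan_cohort
        stable = truth.probe_class.index[truth.probe_class == "stable"]
        est = results.loc[stable, "estimate"].to_numpy()
        signed = est * np.sign(truth.true_delta_beta.loc[stable].to_numpy())
        assert np.abs(signed - 0.08).max() < 0.03
        assert signed.mean() == pytest.approx(0.08, abs=0.02)

    def test_crossover_flips_sign_at_time_extremes(self, scan_cohort):
        _, _, truth, results = scan_cohort
        cross = truth.probe_class.index[truth.probe_class == "crossover"]
        flips = (np.sign(results.loc[cross, "diff_at_tmin"])
                 != np.sign(results.loc[cross, "diff_at_tmax"]))
        assert flips.mean() >= 0.8

    def test_zero_variance_probe_recorded_not_fatal(self, scan_cohort):
        m, sheet, _, _ = scan_cohort
        vals = m.values.iloc[:5].copy()
        vals.iloc[0] = 0.5  # constant probe
        bad = BetaMatrix(values=vals)
        spec = LmmSpec(include_apoe=False, include_smoking=False,
                       include_granulocyte=False)
        res = ewas_scan(bad, sheet, spec)
        assert res.iloc[0]["error"] == "zero variance"
        assert np.isnan(res.iloc[0]["p"])
        assert res.iloc[1:]["p"].notna().all()

    def test_q_values_present_and_bounded(self, scan_cohort):
        _, _, _, results = scan_cohort
        ok = results["p"].notna()
        assert (results.loc[ok, "q"] >= results.loc[ok, "p"] - 1e-12).all()
        assert (results.loc[ok, "q"] <= 1.0).all()
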