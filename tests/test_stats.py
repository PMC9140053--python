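"""Tests of velocity series, period alignment, and the statistical tests.

The RM-ANOVA / Greenhouse-Geisser, paired-t, and Pearson implementations are
checked against independent oracles: direct textbook formulas evaluated from
their definitions, and (where available) pingouin.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from renulm.stats import (
    PeriodWindows,
    align_to_injection,
    gg_epsilon,
    lowest_map_window,
    moving_average_series,
    paired_t,
    pearson_log,
    rm_anova_gg,
    transform_speeds,
    tukey_hsd,
)
from renulm.synthetic import HemodynamicsParams, map_model


def box_epsilon_oracle(data):
    """Greenhouse-Geisser epsilon straight from the Box (1954) sums formula."""
    data = np.asarray(data, float)
    k = data.shape[1]
    S = np.cov(data, rowvar=False, ddof=1)
    s_bar = S.mean()
    s_diag = np.trace(S) / k
    s_row = S.mean(axis=1)
    num = (k * (s_diag - s_bar)) ** 2
    den = (k - 1) * (np.sum(S ** 2) - 2 * k * np.sum(s_row ** 2) + k ** 2 * s_bar ** 2)
    return num / den


class TestMovingAverage:
    def test_constant_samples_give_constant_series(self):
        s = pd.DataFrame({"t": np.linspace(0, 60, 500), "speed": 1.0})
        out = moving_average_series(s, window=30.0)
        assert np.allclose(out["mean"].dropna(), 1.0)

    def test_no_samples_all_missing(self):
        s = pd.DataFrame({"t": [], "speed": []})
        out = moving_average_series(s, window=30.0, t_start=0, t_end=10)
        assert out["mean"].isna().all()
        assert (out["n"] == 0).all()

    def test_step_change_reads_midpoint_at_the_step(self):
        t = np.arange(0, 120, 0.1)
        v = np.where(t < 60.0, 1.0, 2.0)
        out = moving_average_series(pd.DataFrame({"t": t, "speed": v}))
        at_step = out.loc[out["t"] == 60.0, "mean"].iloc[0]
        assert at_step == pytest.approx(1.5, abs=0.02)

    def test_window_is_centered(self):
        # single sample at t=10 contributes to windows centered 10 +/- 15 s
        s = pd.DataFrame({"t": [10.0], "speed": [2.0]})
        out = moving_average_series(s, t_start=0, t_end=40)
        covered = out.loc[out["n"] > 0, "t"]
        assert covered.min() == 0.0 and covered.max() == 25.0


class TestAlignment:
    def test_min_paper_injection_time(self):
        win = align_to_injection(51.0, scan2_duration=600.0)
        assert win.scan2_span == (1.0, 461.0)
        assert win.span_length == 460.0

    def test_max_paper_injection_time(self):
        win = align_to_injection(184.0, scan2_duration=600.0)
        assert win.scan2_mean_window == (184.0, 594.0)

    def test_scan13_window_is_first_410_s(self):
        for t_inj in (51.0, 100.0, 184.0):
            win = align_to_injection(t_inj, scan2_duration=600.0)
            assert win.scan13_window == (0.0, 410.0)

    def test_whole_paper_injection_range_exact(self):
        for t_inj in np.arange(51.0, 184.5, 0.5):
            win = align_to_injection(t_inj, scan2_duration=600.0)
            lo, hi = win.scan2_span
            assert hi - lo == pytest.approx(460.0, abs=1e-12)
            assert lo == pytest.approx(t_inj - 50.0, abs=1e-12)

    def test_too_short_scan_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            align_to_injection(200.0, scan2_duration=600.0)


class TestLowestMapWindow:
    def test_trough_centered_window(self):
        t = np.arange(0, 300.0)
        v = np.abs(t - 150.0)  # V-shaped trough at 150
        start = lowest_map_window(t, v, t_inj=50.0)
        assert start == pytest.approx(135.0, abs=1.0)

    def test_constant_trace_earliest_tie(self):
        t = np.arange(0, 200.0)
        start = lowest_map_window(t, np.full_like(t, 80.0), t_inj=60.0)
        assert start == 60.0

    def test_default_synthetic_trace_in_derived_interval(self):
        # brute-force minimization over the analytic noise-free trace: the
        # window start must fall 37-67 s after injection (trough 52-82 s)
        hemo = HemodynamicsParams()
        t = np.arange(0.0, 470.0)
        v = map_model(t, hemo, t_inj=60.0)
        start = lowest_map_window(t, v, t_inj=60.0)
        assert 60.0 + 37.0 <= start <= 60.0 + 67.0


class TestTransforms:
    def test_cortex_log(self):
        assert transform_speeds([1.0], "cortex")[0] == 0.0

    def test_medulla_sqrt(self):
        assert transform_speeds([4.0], "outer_medulla")[0] == 2.0

    def test_round_trip(self, rng):
        v = rng.uniform(0.1, 5.0, 100)
        np.testing.assert_allclose(np.exp(transform_speeds(v, "cortex")), v,
                                   rtol=1e-12)
        np.testing.assert_allclose(transform_speeds(v, "inner_medulla") ** 2, v,
                                   rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            transform_speeds([0.0], "cortex")
        with pytest.raises(ValueError):
            transform_speeds([-1.0], "outer_medulla")


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.p == 0.0

    def test_matches_textbook_formula(self):
        x = np.array([1.2, 0.9, 1.5, 1.1, 1.3])
        y = np.array([1.0, 1.1, 1.2, 0.8, 1.2])
        res = paired_t(x, y)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 4)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)
        assert res.df == (4,)

    def test_matches_scipy(self, rng):
        x = rng.normal(1.0, 0.3, 8)
        y = rng.normal(0.8, 0.3, 8)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestRmAnovaGG:
    def test_two_conditions_epsilon_is_one(self, rng):
        data = rng.normal(size=(8, 2))
        res = rm_anova_gg(data)
        assert res.extra["epsilon"] == pytest.approx(1.0, abs=1e-12)

    def test_compound_symmetry_epsilon_one(self, rng):
        # exchangeable covariance satisfies sphericity -> epsilon ~ 1
        n = 4000
        subj = rng.normal(0, 1.0, size=(n, 1))
        data = subj + rng.normal(0, 1.0, size=(n, 3))
        res = rm_anova_gg(data)
        assert res.extra["epsilon"] == pytest.approx(1.0, abs=0.01)

    def test_epsilon_bounds(self, rng):
        for _ in range(20):
            data = rng.normal(size=(6, 4))
            eps = gg_epsilon(data)
            assert 1.0 / 3.0 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_matches_box_formula_oracle(self, rng):
        data = rng.normal(size=(7, 3)) + np.array([0.0, 0.5, 0.2])
        res = rm_anova_gg(data)
        assert res.extra["epsilon"] == pytest.approx(box_epsilon_oracle(data),
                                                     abs=1e-8)
        # F from the definition sums
        n, k = data.shape
        grand = data.mean()
        ss_cond = n * ((data.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((data.mean(1) - grand) ** 2).sum()
        ss_err = ((data - grand) ** 2).sum() - ss_cond - ss_subj
        F_oracle = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert res.statistic == pytest.approx(F_oracle, abs=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(size=(7, 3)) + np.array([0.0, 0.4, 0.1])
        res = rm_anova_gg(data)
        df = pd.DataFrame({
            "y": data.ravel(),
            "subject": np.repeat(np.arange(7), 3),
            "cond": np.tile(np.arange(3), 7)})
        ref = pg.rm_anova(data=df, dv="y", within="cond", subject="subject",
                          correction=True)
        assert res.statistic == pytest.approx(ref["F"].iloc[0], rel=1e-6)
        assert res.extra["epsilon"] == pytest.approx(ref["eps"].iloc[0], rel=1e-6)
        assert res.p == pytest.approx(ref["p_GG_corr"].iloc[0], rel=1e-6)

    def test_constant_data_flagged(self):
        res = rm_anova_gg(np.ones((5, 3)))
        assert res.degenerate


class TestTukey:
    def test_two_conditions_single_pair(self, rng):
        data = rng.normal(size=(6, 2))
        out = tukey_hsd(data)
        assert len(out) == 1

    def test_null_familywise_error_controlled(self):
        rng = np.random.default_rng(99)
        false_pos = 0
        n_sims = 200
        for _ in range(n_sims):
            data = rng.normal(size=(7, 3))  # identical condition means
            out = tukey_hsd(data)
            if (out["p_adj"] < 0.05).any():
                false_pos += 1
        assert false_pos / n_sims <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_large_effect_always_detected(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            data = rng.normal(0, 1.0, size=(7, 3))
            data[:, 1] += 10.0  # ten-sigma shift
            out = tukey_hsd(data)
            pair = out[(out["i"] == 0) & (out["j"] == 1)]
            assert float(pair["p_adj"].iloc[0]) < 0.001


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_log(x, 2.0 * x + 1.0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_three_point_hand_computation(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([0.5, 0.9, 1.2])
        res = pearson_log(x, y)
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert res.statistic == pytest.approx(r_oracle ** 2, abs=1e-12)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(40):
            res = pearson_log(rng.normal(size=1000), rng.normal(size=1000))
            if res.statistic < 0.01:
                hits += 1
        assert hits >= 38  # >= 95% of seeds

    def test_zero_variance_flagged(self):
        res = pearson_log([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        assert res.degenerate
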