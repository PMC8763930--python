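"""Diagnostic statistics: 2x2 performance, score model, tests, bootstrap."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

import thyropet.riskmodel as rm


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive enumeration of all tables
    with the observed margins (exact binomial-coefficient arithmetic)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = comb(r1, k) * comb(r2, c1 - k)
        if p_k <= p_obs:
            total += p_k
    return total / denom


class TestDiagnosticPerformance:
    def test_rs_univariate_reference_table(self):
        p = rm.diagnostic_performance(rm.ContingencyTable2x2(15, 8, 8, 34))
        assert p.or_point == pytest.approx(7.97, abs=0.005)
        assert p.or_ci_low == pytest.approx(2.52, abs=0.005)
        assert p.or_ci_high == pytest.approx(25.2, abs=0.05)
        assert p.sensitivity == pytest.approx(65.2, abs=0.05)
        assert p.specificity == pytest.approx(81.0, abs=0.05)
        assert not p.continuity_corrected

    def test_cytology_reference_table(self):
        p = rm.diagnostic_performance(rm.ContingencyTable2x2(18, 17, 5, 25))
        assert p.or_point == pytest.approx(5.29, abs=0.005)
        assert p.or_ci_low == pytest.approx(1.65, abs=0.01)
        assert p.or_ci_high == pytest.approx(17.0, abs=0.05)

    def test_symmetric_table_or_is_ratio_squared(self):
        p = rm.diagnostic_performance(rm.ContingencyTable2x2(20, 5, 5, 20))
        assert p.or_point == pytest.approx((20 / 5) ** 2)
        # symmetric CI in log space
        assert math.log(p.or_ci_high / p.or_point) == pytest.approx(
            math.log(p.or_point / p.or_ci_low)
        )

    def test_zero_cell_triggers_continuity_flag(self):
        p = rm.diagnostic_performance(rm.ContingencyTable2x2(10, 0, 5, 20))
        assert p.continuity_corrected
        assert np.isfinite(p.or_point)


class TestCombinedScoreModel:
    @staticmethod
    def records_from_groups(counts):
        """counts: {score: (n_malignant, n_total)} -> patient records."""
        rows = []
        for score, (m, n) in counts.items():
            rs = 1 if score >= 1 else 0
            beth = 1 if score == 2 else 0
            if score == 1:
                rs, beth = 1, 0
            for i in range(n):
                rows.append({
                    "rs_positive": rs, "bethesda_iv": beth,
                    "malignant": 1 if i < m else 0,
                })
        return pd.DataFrame(rows)

    def test_non_hurthle_reference_groups(self):
        res = rm.combined_score_model(
            self.records_from_groups({0: (1, 21), 1: (11, 30), 2: (11, 14)})
        )
        assert res["groups"][1]["or_vs_score0"] == pytest.approx(11.6, abs=0.05)
        assert res["groups"][2]["or_vs_score0"] == pytest.approx(73.3, abs=0.05)
        assert res["groups"][0]["prevalence_pct"] == pytest.approx(4.8, abs=0.05)
        assert res["groups"][1]["prevalence_pct"] == pytest.approx(36.7, abs=0.05)
        assert res["groups"][2]["prevalence_pct"] == pytest.approx(78.6, abs=0.05)
        assert res["npv_score0_pct"] == pytest.approx(95.2, abs=0.05)
        assert res["ppv_score2_pct"] == pytest.approx(78.6, abs=0.05)

    def test_all_lesions_reference_groups(self):
        res = rm.combined_score_model(
            self.records_from_groups({0: (1, 26), 1: (12, 33), 2: (11, 19)})
        )
        assert res["groups"][1]["or_vs_score0"] == pytest.approx(14.3, abs=0.05)
        assert res["groups"][2]["or_vs_score0"] == pytest.approx(34.4, abs=0.05)

    def test_equal_prevalence_gives_unit_odds_ratios(self):
        res = rm.combined_score_model(
            self.records_from_groups({0: (5, 20), 1: (5, 20), 2: (5, 20)})
        )
        assert res["groups"][1]["or_vs_score0"] == pytest.approx(1.0)
        assert res["groups"][2]["or_vs_score0"] == pytest.approx(1.0)

    def test_score_is_biomarker_count(self):
        score = rm.combined_score(np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1]))
        assert score.tolist() == [0, 1, 1, 2]


class TestLogisticFit:
    def test_single_binary_predictor_matches_cross_product(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 78)
        y = (rng.random(78) < 0.15 + 0.4 * x).astype(int)
        df = pd.DataFrame({"x": x, "malignant": y})
        fit = rm.logistic_fit(df, ["x"])
        t = rm.ContingencyTable2x2.from_flags(x == 1, y == 1)
        assert fit["or"][0] == pytest.approx(t.a * t.d / (t.b * t.c), abs=1e-6)

    def test_confounding_attenuates_multivariate_or(self):
        # two positively associated predictors, only x1 causal
        rng = np.random.default_rng(7)
        n = 400
        x1 = rng.integers(0, 2, n)
        x2 = ((x1 + (rng.random(n) < 0.3)) >= 1).astype(int)  # correlated with x1
        y = (rng.random(n) < 0.1 + 0.5 * x1).astype(int)
        df = pd.DataFrame({"x1": x1, "x2": x2, "malignant": y})
        uni = rm.logistic_fit(df, ["x2"])["or"][0]
        multi = rm.logistic_fit(df, ["x1", "x2"]).set_index("predictor")["or"]["x2"]
        assert multi < uni

    def test_wald_ci_coverage_under_null(self):
        rng = np.random.default_rng(11)
        covered = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.integers(0, 2, 78)
            y = rng.integers(0, 2, 78)
            df = pd.DataFrame({"x": x, "malignant": y})
            try:
                fit = rm.logistic_fit(df, ["x"])
            except ValueError:
                continue
            covered += fit["or_ci_low"][0] <= 1.0 <= fit["or_ci_high"][0]
        assert covered / n_sim == pytest.approx(0.95, abs=0.04)


class TestAssociationTests:
    def test_chi_square_hand_value(self):
        out = rm.association_tests(table=np.array([[5, 30], [18, 25]]))
        # n(ad-bc)^2 / (row and column products)
        n, a, b, c, d = 78, 5, 30, 18, 25
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert out["chi_square"]["statistic"] == pytest.approx(expected)
        assert out["chi_square"]["p"] == pytest.approx(0.0079, abs=0.0005)

    def test_trend_on_reference_groups_significant(self):
        out = rm.association_tests(score_groups=([1, 11, 11], [21, 30, 14]))
        assert out["chi_square_trend"]["p"] < 0.0001

    @pytest.mark.parametrize("table", [
        (3, 7, 9, 2), (0, 10, 5, 12), (8, 2, 2, 8), (1, 1, 18, 17), (6, 0, 0, 9),
    ])
    def test_fisher_matches_exhaustive_enumeration(self, table):
        a, b, c, d = table
        out = rm.association_tests(table=np.array([[a, b], [c, d]]))
        assert out["fisher_exact"]["p"] == pytest.approx(
            fisher_enumeration(a, b, c, d), rel=1e-9
        )

    def test_mann_whitney_detects_shift(self):
        rng = np.random.default_rng(13)
        out = rm.association_tests(
            continuous=(rng.normal(0, 1, 50), rng.normal(1.2, 1, 30))
        )
        assert out["mann_whitney"]["p"] < 0.001

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            rm.association_tests(table=np.array([[0, 0], [5, 7]]))


class TestBootstrapOptimism:
    def test_null_corrected_auc_near_half(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({
            "a": rng.normal(size=78), "b": rng.normal(size=78),
            "malignant": rng.integers(0, 2, 78),
        })
        res = rm.bootstrap_optimism_auc(df, ["a", "b"], n_boot=200, seed=1)
        assert res["corrected_auc"] == pytest.approx(0.5, abs=0.05)
        assert res["optimism"] > 0  # two fitted predictors always overfit some

    def test_separable_data_correction_bounded(self):
        x = np.concatenate([np.zeros(30), np.ones(30)])
        df = pd.DataFrame({"x": x + 0.01 * np.arange(60), "malignant": x.astype(int)})
        res = rm.bootstrap_optimism_auc(df, ["x"], n_boot=50, seed=2)
        assert res["apparent_auc"] == 1.0
        assert res["apparent_auc"] - 0.05 <= res["corrected_auc"] <= 1.0

    def test_single_resample_manual_oracle(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({
            "x": rng.normal(size=40),
            "malignant": rng.integers(0, 2, 40),
        })
        res = rm.bootstrap_optimism_auc(df, ["x"], n_boot=1, seed=99)
        # replay the same resample by consuming the generator identically
        import statsmodels.api as sm
        from thyropet.selection import rank_auc

        rng2 = np.random.default_rng(99)
        idx = rng2.integers(0, 40, size=40)
        X, y = df[["x"]].to_numpy(), df["malignant"].to_numpy()
        fit_full = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        apparent = rank_auc(fit_full.predict(sm.add_constant(X)), y)
        fit_b = sm.Logit(y[idx], sm.add_constant(X[idx])).fit(disp=0)
        auc_b = rank_auc(fit_b.predict(sm.add_constant(X[idx])), y[idx])
        auc_t = rank_auc(fit_b.predict(sm.add_constant(X)), y)
        assert res["apparent_auc"] == pytest.approx(apparent)
        assert res["corrected_auc"] == pytest.approx(apparent - (auc_b - auc_t))

    def test_missing_class_raises(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "malignant": [1, 1]})
        with pytest.raises(ValueError, match="class"):
            rm.bootstrap_optimism_auc(df, ["x"], n_boot=5, seed=0)
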