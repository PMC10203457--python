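"""Descriptive statistics, ANOVA + LSD letters, correlation matrix."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenodrought import (
    anova_lsd,
    correlation_long_table,
    correlation_matrix,
    cv_band,
    describe_trait,
    lsd_letters,
    significance_code,
    summarize_trial,
)


class TestDescribe:
    def test_constant_sample_zero_cv(self):
        mn, mx, mean, se, cv = describe_trait([5, 5, 5])
        assert (mn, mx, mean, cv) == (5, 5, 5, 0)
        assert se == 0

    def test_hand_computation(self):
        mn, mx, mean, se, cv = describe_trait([1, 2, 3])
        assert (mn, mx, mean) == (1, 3, 2)
        assert se == pytest.approx(1 / math.sqrt(3))
        assert cv == pytest.approx(50.0)

    def test_single_value_undefined_dispersion(self):
        mn, mx, mean, se, cv = describe_trait([7])
        assert (mn, mx, mean) == (7, 7, 7)
        assert math.isnan(se) and math.isnan(cv)

    def test_cv_scale_invariant(self):
        x = [1.2, 3.4, 2.2, 5.1]
        cv1 = describe_trait(x)[4]
        cv2 = describe_trait([7.5 * v for v in x])[4]
        assert cv1 == pytest.approx(cv2, rel=1e-12)


class TestCvBand:
    @pytest.mark.parametrize("cv,band", [
        (53.83, "high"), (21.2, "medium"), (7.57, "low"),
        (15.0, "medium"), (30.0, "medium"), (30.01, "high"), (14.99, "low"),
    ])
    def test_published_cvs_band_correctly(self, cv, band):
        assert cv_band(cv) == band

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            cv_band(-1.0)


class TestSignificanceCode:
    @pytest.mark.parametrize("p,code", [
        (0.2, "ns"), (0.03, "p05"), (0.0005, "p001"), (0.005, "p01"),
        (0.05, "ns"), (1.0, "ns"), (0.0, "p001"),
    ])
    def test_thresholds(self, p, code):
        assert significance_code(p) == code

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_code(1.5)


class TestAnovaLSD:
    def test_zero_within_variance_distinct_means(self):
        res = anova_lsd({"A": [1, 1], "B": [3, 3]})
        assert math.isinf(res.F) and res.p == 0.0
        assert res.letters["A"] != res.letters["B"]

    def test_two_group_f_equals_pooled_t_squared(self):
        res = anova_lsd({"A": [1, 2], "B": [2, 3]})
        t, p = sps.ttest_ind([1, 2], [2, 3])
        assert res.F == pytest.approx(t ** 2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_all_identical_single_letter(self):
        res = anova_lsd({"A": [2, 2], "B": [2, 2], "C": [2, 2]})
        assert math.isnan(res.F)
        assert set(res.letters.values()) == {"a"}

    def test_unbalanced_design_accepted(self):
        res = anova_lsd({"A": [1, 2, 3], "B": [4, 5]})
        assert res.df_error == 3
        assert res.lsd > 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_letters_match_brute_force_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        groups = {f"G{i}": rng.normal(rng.uniform(0, 5), 1.0, 4)
                  for i in range(k)}
        res = anova_lsd(groups)
        for a, b in itertools.combinations(groups, 2):
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            close = abs(res.means[a] - res.means[b]) <= res.lsd
            assert share == close, (a, b, res.means, res.lsd, res.letters)

    def test_letter_display_standalone(self):
        letters = lsd_letters({"A": 10.0, "B": 9.5, "C": 8.0}, lsd=1.0)
        assert set(letters["A"]) & set(letters["B"])
        assert not set(letters["A"]) & set(letters["C"])


class TestCorrelation:
    @staticmethod
    def _frame(seed=0, n=10, traits=("T1", "T2", "T3", "T4")):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, len(traits))) + rng.uniform(1, 5, len(traits)),
            index=[f"L{i}" for i in range(n)], columns=list(traits))

    def test_unit_diagonal_and_symmetry(self):
        frame = self._frame()
        corr = correlation_matrix(frame, list(frame.columns))
        np.testing.assert_allclose(np.diag(corr.r), 1.0)
        np.testing.assert_allclose(corr.r, corr.r.T, atol=1e-15)
        assert (corr.r.abs().to_numpy() <= 1 + 1e-12).all()

    def test_perfect_linearity(self):
        frame = pd.DataFrame({"x": [1, 2, 3, 4, 5.0]})
        frame["y"] = 2 * frame["x"]
        corr = correlation_matrix(frame, ["x", "y"])
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.p.loc["x", "y"] < 0.001

    def test_matches_direct_covariance_formula(self):
        frame = self._frame(seed=3)
        corr = correlation_matrix(frame, list(frame.columns))
        x = frame.to_numpy()
        for i, a in enumerate(frame.columns):
            for j, b in enumerate(frame.columns):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                r = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
                assert corr.r.loc[a, b] == pytest.approx(r, abs=1e-12)

    def test_p_values_match_t_transform(self):
        frame = self._frame(seed=4)
        corr = correlation_matrix(frame, list(frame.columns))
        n = corr.n
        a, b = frame.columns[0], frame.columns[1]
        r = corr.r.loc[a, b]
        t = r * math.sqrt((n - 2) / (1 - r ** 2))
        assert corr.p.loc[a, b] == pytest.approx(2 * sps.t.sf(abs(t), n - 2),
                                                 abs=1e-12)

    def test_affine_rescaling_invariance(self):
        frame = self._frame(seed=5)
        corr1 = correlation_matrix(frame, list(frame.columns))
        scaled = frame.copy()
        scaled["T1"] = -3.0 * scaled["T1"] + 7.0
        corr2 = correlation_matrix(scaled, list(frame.columns))
        np.testing.assert_allclose(
            corr2.r.loc["T1", "T2"], -corr1.r.loc["T1", "T2"], atol=1e-12)
        np.testing.assert_allclose(
            corr2.r.loc["T2", "T3"], corr1.r.loc["T2", "T3"], atol=1e-14)

    def test_zero_variance_trait_flagged_nan(self):
        frame = self._frame(seed=6)
        frame["T1"] = 2.5
        corr = correlation_matrix(frame, list(frame.columns))
        assert corr.r.loc["T1"].isna().all()
        assert not corr.r.loc["T2", "T3"] != corr.r.loc["T2", "T3"]

    def test_long_table_stars(self):
        frame = pd.DataFrame({"x": [1, 2, 3, 4, 5.0]})
        frame["y"] = 2 * frame["x"]
        corr = correlation_matrix(frame, ["x", "y"])
        long = correlation_long_table(corr)
        assert long.loc[0, "stars"] == "***"


class TestSummary:
    def test_trial_summary_shape_and_bands(self, default_trial):
        obs, _ = default_trial
        summary = summarize_trial(obs)
        assert set(summary["cv_band"]) <= {"low", "medium", "high", ""}
        # 17 traits under both treatments + WU under stress only
        assert len(summary) == 17 * 2 + 1
        row = summary[(summary["trait"] == "WU")]
        assert list(row["treatment"]) == ["WS"]
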