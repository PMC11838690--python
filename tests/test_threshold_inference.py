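"""Depth-1 threshold extraction, 2x2 odds ratios, Rubin pooling and the
rank correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mddpredict.threshold_inference import (
    ThresholdExtractionError,
    extract_threshold,
    odds_ratio_2x2,
    pool_rubin,
    spearman_rho,
    subgroup_ors,
)

from .conftest import stack_from_frames


def _frame_with_cut(cut, n=60, seed=0):
    """Improvement iff gad7 < cut (perfect separation -> split at cut-0.5)."""
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 22, n)
    return pd.DataFrame({"gad7": g, "outcome": (g < cut).astype(int), "arm": "EVO"})


class TestExtractThreshold:
    def test_forced_separation_yields_cut_11(self):
        stack = stack_from_frames([_frame_with_cut(11)])
        rule = extract_threshold(stack, "gad7")
        assert rule.cut_value == 11
        assert rule.per_imputation_cuts == [11]

    def test_median_across_imputations(self):
        frames = [_frame_with_cut(c, seed=i) for i, c in enumerate([11, 11, 12, 10, 11])]
        stack = stack_from_frames(frames)
        rule = extract_threshold(stack, "gad7")
        assert rule.per_imputation_cuts == [11, 11, 12, 10, 11]
        assert rule.cut_value == 11

    def test_lower_median_on_even_count(self):
        frames = [_frame_with_cut(c, seed=i) for i, c in enumerate([10, 11, 12, 13])]
        assert extract_threshold(stack_from_frames(frames), "gad7").cut_value == 11

    def test_constant_feature_names_imputation(self):
        good = _frame_with_cut(11)
        bad = good.copy()
        bad["gad7"] = 7
        bad["outcome"] = [0, 1] * (len(bad) // 2)
        with pytest.raises(ThresholdExtractionError, match="imputation 1"):
            extract_threshold(stack_from_frames([good, bad]), "gad7")


class TestOddsRatio:
    def test_symmetric_table(self):
        or_, log_or, var = odds_ratio_2x2(10, 10, 10, 10)
        assert or_ == 1.0 and log_or == 0.0 and var == pytest.approx(0.4)

    def test_worked_example(self):
        or_, _, var = odds_ratio_2x2(5, 20, 20, 10)
        assert or_ == pytest.approx(0.125)
        assert var == pytest.approx(1 / 5 + 1 / 20 + 1 / 20 + 1 / 10)

    def test_haldane_anscombe_zero_cell(self):
        or_, log_or, _ = odds_ratio_2x2(0, 10, 10, 10)
        assert or_ == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_absent_group_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 0, 5, 5)
        with pytest.raises(ValueError):
            odds_ratio_2x2(5, 5, -1, 5)


class TestPoolRubin:
    def test_degenerate_b_zero(self):
        pooled = pool_rubin([-1.7, -1.7, -1.7], [0.04, 0.04, 0.04])
        assert pooled.b == 0.0 and pooled.t == pytest.approx(0.04)
        assert math.isinf(pooled.df)
        half = stats.norm.ppf(0.975) * math.sqrt(0.04)
        assert pooled.ci95 == pytest.approx(
            (math.exp(-1.7 - half), math.exp(-1.7 + half)), rel=1e-12
        )

    def test_hand_computed_components(self):
        pooled = pool_rubin([-1.6, -1.7, -1.8], [0.04, 0.04, 0.04])
        assert pooled.q_bar == pytest.approx(-1.7, abs=1e-12)
        assert pooled.u_bar == pytest.approx(0.04, abs=1e-12)
        assert pooled.b == pytest.approx(0.01, abs=1e-12)
        assert pooled.t == pytest.approx(0.04 + (4 / 3) * 0.01, abs=1e-12)
        # df = (M-1) (1 + U/( (1+1/M) B ))^2 = 2 * (1 + 3)^2
        assert pooled.df == pytest.approx(32.0, abs=1e-9)
        assert pooled.t >= pooled.u_bar
        assert pooled.ci95[0] < pooled.point < pooled.ci95[1]

    def test_doubling_variances_widens_ci(self):
        a = pool_rubin([-1.6, -1.8], [0.04, 0.04])
        b = pool_rubin([-1.6, -1.8], [0.08, 0.08])
        assert (b.ci95[1] - b.ci95[0]) > (a.ci95[1] - a.ci95[0])

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([-1.7], [0.04])


class TestSubgroupORs:
    def _stack(self, n=3000, seed=1, m=2):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 22, n)
        p = 1 / (1 + np.exp(-(0.3 + math.log(0.18) * (g >= 11))))
        y = (rng.random(n) < p).astype(int)
        arm = rng.choice(["EVO", "iPST", "HealthTips"], n)
        df = pd.DataFrame({"gad7": g, "outcome": y, "arm": arm})
        return stack_from_frames([df.copy() for _ in range(m)])

    def test_identical_imputations_reduce_to_single_table_wald(self):
        stack = self._stack()
        rule = extract_threshold(stack, "gad7")
        pooled = subgroup_ors(stack, rule)["overall"]
        a, b, c, d = (
            int(((stack.tables[0]["gad7"] >= rule.cut_value) & (stack.tables[0]["outcome"] == 1)).sum()),
            int(((stack.tables[0]["gad7"] >= rule.cut_value) & (stack.tables[0]["outcome"] == 0)).sum()),
            int(((stack.tables[0]["gad7"] < rule.cut_value) & (stack.tables[0]["outcome"] == 1)).sum()),
            int(((stack.tables[0]["gad7"] < rule.cut_value) & (stack.tables[0]["outcome"] == 0)).sum()),
        )
        or_, log_or, var = odds_ratio_2x2(a, b, c, d)
        assert pooled.point == pytest.approx(or_, rel=1e-12)
        assert pooled.t == pytest.approx(var, rel=1e-12)
        half = stats.norm.ppf(0.975) * math.sqrt(var)
        assert pooled.ci95 == pytest.approx(
            (math.exp(log_or - half), math.exp(log_or + half)), rel=1e-10
        )

    def test_uniform_effect_gives_overlapping_arm_cis(self):
        ors = subgroup_ors(self._stack(n=6000, seed=3), extract_threshold(self._stack(n=6000, seed=3), "gad7"))
        arms = [v for k, v in ors.items() if k != "overall"]
        for i in range(3):
            for j in range(i + 1, 3):
                lo = max(arms[i].ci95[0], arms[j].ci95[0])
                hi = min(arms[i].ci95[1], arms[j].ci95[1])
                assert lo <= hi
        assert 0.18 / 1.6 < ors["overall"].point < 0.18 * 1.6

    def test_zero_cell_arm_uses_correction(self):
        df = pd.DataFrame(
            {
                "gad7": [15, 15, 15, 5, 5, 5, 15, 5],
                "outcome": [0, 0, 0, 1, 1, 0, 0, 1],
                "arm": ["EVO"] * 8,
            }
        )
        stack = stack_from_frames([df, df.copy()])
        rule = extract_threshold(stack, "gad7")
        pooled = subgroup_ors(stack, rule)["EVO"]
        assert math.isfinite(pooled.q_bar) and pooled.point > 0


class TestSpearman:
    def test_monotone_vectors(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 2 * x + 1).rho == pytest.approx(1.0)
        assert spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_worked_example(self):
        res = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)

    def test_fisher_ci_and_bootstrap_agree_roughly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = 0.7 * x + rng.normal(size=300) * 0.7
        fisher = spearman_rho(x, y)
        boot = spearman_rho(x, y, method="bootstrap", n_bootstrap=400, rng_seed=1)
        assert fisher.ci95[0] < fisher.rho < fisher.ci95[1]
        assert abs(fisher.ci95[0] - boot.ci95[0]) < 0.1
        assert abs(fisher.ci95[1] - boot.ci95[1]) < 0.1

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2, 3, 4, np.nan, 6])
        y = np.array([1.0, 2, 3, 4, 5, np.nan])
        assert spearman_rho(x, y).n == 4

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [2, 1])
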