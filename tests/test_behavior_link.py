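"""Brain-behavior linking: merging, change scores, Olkin-Pratt pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tractplast as tp
from tractplast.behavior_link import (interval_change_scores,
                                      merge_adjacent_segments,
                                      pool_point_estimate, pooled_ci_p,
                                      spearman)


class TestIntervalChanges:
    def test_arithmetic(self):
        scores = pd.DataFrame([[0.2, 0.3, -0.5]], index=["S01"],
                              columns=["MRI1", "MRI2", "MRI3"])
        d = interval_change_scores(scores)
        assert d.loc["S01", "delta_13"] == pytest.approx(-0.7)
        assert d.loc["S01", "delta_23"] == pytest.approx(-0.8)

    def test_constant_scores_zero_deltas(self):
        scores = pd.DataFrame(np.ones((5, 3)),
                              columns=["MRI1", "MRI2", "MRI3"])
        assert (interval_change_scores(scores) == 0).all().all()


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]) == -1.0

    def test_null_calibration(self, rng):
        rs = [spearman(rng.standard_normal(24), rng.standard_normal(24))
              for _ in range(2000)]
        assert abs(np.mean(rs)) < 0.02

    def test_zero_variance_is_nan(self):
        assert np.isnan(spearman([1, 1, 1, 1], [1, 2, 3, 4]))


class TestPooling:
    def test_zero_passthrough(self):
        assert pool_point_estimate([0.0], [24]) == 0.0

    def test_unbiased_correction_value(self):
        # G = r * (1 + (1 - r^2)/(2(n-3))) at r = 0.5, n = 24
        assert pool_point_estimate([0.5], [24]) == pytest.approx(0.5089,
                                                                 abs=5e-5)

    def test_equal_weight_invariance(self):
        single = pool_point_estimate([0.4], [24])
        double = pool_point_estimate([0.4, 0.4], [24, 24])
        assert double == pytest.approx(single, abs=1e-12)

    @pytest.mark.parametrize("G,lo,hi", [
        (-0.38, -0.63, -0.13),
        (-0.31, -0.57, -0.05),
    ])
    def test_ci_reproduces_published_bounds(self, G, lo, hi):
        ci_lo, ci_hi, p1, _ = pooled_ci_p(G, [24, 24], direction=-1)
        assert round(ci_lo, 2) == lo
        assert round(ci_hi, 2) == hi

    def test_one_sided_p_for_strong_negative_pooled_estimate(self):
        _, _, p1, p2 = pooled_ci_p(-0.38, [24, 24], direction=-1)
        assert p1 == pytest.approx(0.001, abs=0.0005)
        assert p2 == pytest.approx(2 * p1, rel=1e-9)

    def test_null_estimate_symmetric(self):
        lo, hi, p1, p2 = pooled_ci_p(0.0, [24, 24], direction=-1)
        assert lo == pytest.approx(-hi)
        assert p2 == pytest.approx(1.0)
        assert p1 == pytest.approx(0.5)

    def test_two_studies_shrink_ci_by_sqrt2(self):
        lo1, hi1, *_ = pooled_ci_p(0.2, [24], direction=1)
        lo2, hi2, *_ = pooled_ci_p(0.2, [24, 24], direction=1)
        assert (hi2 - lo2) / (hi1 - lo1) == pytest.approx(1 / np.sqrt(2),
                                                          rel=1e-9)

    def test_observed_coverage_documented(self, rng):
        # fixed-effect pooling of two dependent interval correlations is
        # anti-conservative; observed coverage at n=24, interval corr 0.5,
        # true Spearman 0.4 sits well below the nominal 95%
        rho_s = 0.4
        rho_p = 2 * np.sin(np.pi * rho_s / 6)
        cov = np.array([[1, 0.5, rho_p], [0.5, 1, rho_p], [rho_p, rho_p, 1]])
        L = np.linalg.cholesky(cov)
        hits = 0
        N = 400
        for _ in range(N):
            X = rng.standard_normal((24, 3)) @ L.T
            r13 = stats.spearmanr(X[:, 0], X[:, 2]).statistic
            r23 = stats.spearmanr(X[:, 1], X[:, 2]).statistic
            G = pool_point_estimate([r13, r23], [24, 24])
            lo, hi, *_ = pooled_ci_p(G, [24, 24])
            hits += lo <= rho_s <= hi
        assert 0.80 <= hits / N <= 0.97


class TestPooledCorrelation:
    def test_direction_set_from_group_trajectory(self, rng):
        n = 24
        lr = pd.Series(rng.standard_normal(n),
                       index=[f"S{i:02d}" for i in range(n)])
        d = pd.DataFrame({
            "delta_13": -lr + 0.5 * rng.standard_normal(n),
            "delta_23": -lr + 0.5 * rng.standard_normal(n),
        }, index=lr.index) - 1.0          # negative mean change
        pc = tp.pooled_correlation(d, lr)
        assert pc.direction == -1
        assert pc.G_pooled < -0.5
        assert pc.p_one_sided < 0.01
        assert pc.ci_low <= pc.G_pooled <= pc.ci_high


class TestMergeAdjacent:
    def _fit_segments(self, cfg, tract, segments, B=150):
        panel, _ = tp.generate_tract_profiles(cfg)
        return panel, {s: tp.SegmentASCA(panel, tract, s).fit(B=B, seed=s)
                       for s in segments}

    def test_identical_loading_run_merged(self):
        cfg = tp.CohortConfig(
            tracts=("ATR_right",), n_segments=8, sigma_subject=0.3,
            sigma_resid=0.25, ar_phi=0.0,
            effects=[tp.EffectTemplate("ATR_right", (4, 5, 6),
                                       {"FISO": -0.8, "FICVF": -0.6},
                                       group_magnitude=1.5)], seed=21)
        panel, models = self._fit_segments(cfg, "ATR_right", range(1, 9))
        merged = merge_adjacent_segments(models, panel, "ATR_right",
                                         B=150, seed=0)
        labels = [g["label"] for g in merged]
        assert "4-6" in labels
        grp = merged[labels.index("4-6")]
        assert grp["segments"] == (4, 5, 6)
        assert grp["model"].plastic

    def test_isolated_plastic_segment_is_singleton(self):
        cfg = tp.CohortConfig(
            tracts=("FPT_right",), n_segments=6, sigma_subject=0.3,
            sigma_resid=0.25,
            effects=[tp.EffectTemplate("FPT_right", (3,),
                                       {"GRATIO": -0.9, "MT": 0.44},
                                       group_magnitude=1.5)], seed=22)
        panel, models = self._fit_segments(cfg, "FPT_right", range(1, 7))
        merged = merge_adjacent_segments(models, panel, "FPT_right",
                                         B=150, seed=0)
        assert [g["label"] for g in merged] == ["3"]

    def test_orthogonal_neighbors_not_merged(self):
        cfg = tp.CohortConfig(
            tracts=("CST_left",), n_segments=4, sigma_subject=0.3,
            sigma_resid=0.2, ar_phi=0.0,
            effects=[
                tp.EffectTemplate("CST_left", (2,), {"FISO": 1.0},
                                  group_magnitude=2.0),
                tp.EffectTemplate("CST_left", (3,), {"R2star": 1.0},
                                  group_magnitude=2.0),
            ], seed=23)
        panel, models = self._fit_segments(cfg, "CST_left", range(1, 5))
        merged = merge_adjacent_segments(models, panel, "CST_left",
                                         B=150, seed=0)
        labels = sorted(g["label"] for g in merged)
        assert labels == ["2", "3"]
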