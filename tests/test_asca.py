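"""Per-segment repeated-measures ASCA: LMM effects, PCA, bootstrap, flags."""

import numpy as np
import pandas as pd
import pytest

import tractplast as tp
from tractplast.asca import (SegmentASCA, classify_segment, decompose_effects,
                             fit_segment_lmm, standardize_panel)


def balanced_long(n=10, session_effects=(0.0, 0.1, 0.4), subject_sd=0.5,
                  resid_sd=0.2, seed=0, metric="MT"):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        u = rng.normal(0, subject_sd)
        for j, s in enumerate(("MRI1", "MRI2", "MRI3")):
            rows.append((f"S{i:02d}", s, metric,
                         u + session_effects[j] + rng.normal(0, resid_sd)))
    return pd.DataFrame(rows, columns=["subject_id", "session", "metric",
                                       "value"])


class TestStandardize:
    def test_zscore_contract_and_inverse(self, small_effect_config):
        panel, _ = tp.generate_tract_profiles(small_effect_config(seed=2))
        z, subjects, sessions, mets, means, sds = standardize_panel(
            panel, "ATR_right", 4)
        flat = z.reshape(-1, z.shape[2])
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(flat.std(axis=0, ddof=1), 1.0, atol=1e-12)
        # inverse transform reproduces the raw values
        arr, *_ = panel.segment_array("ATR_right", 4, mets)
        assert np.allclose(z * sds + means, arr, atol=1e-12)

    def test_constant_metric_excluded_with_warning(self, null_config):
        panel, _ = tp.generate_tract_profiles(null_config(seed=3))
        df = panel.data.copy()
        df.loc[df["metric"] == "MT", "value"] = 1.23
        panel2 = tp.TractProfilePanel(df, validate=False)
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _, _, mets, _, _ = standardize_panel(panel2, "CST_left", 1)
        assert "MT" not in mets


class TestSegmentLmm:
    def test_balanced_beta_equals_session_mean_differences(self):
        # GLS fixed effects = OLS session-mean contrasts on balanced data
        df = balanced_long(n=12, seed=1)
        beta, vs, vr, singular = fit_segment_lmm(df, "MT")
        means = df.groupby("session")["value"].mean()
        assert beta["MRI2"] == pytest.approx(means["MRI2"] - means["MRI1"],
                                             abs=1e-8)
        assert beta["MRI3"] == pytest.approx(means["MRI3"] - means["MRI1"],
                                             abs=1e-8)
        assert not singular

    def test_zero_subject_variance_boundary(self):
        df = balanced_long(n=12, subject_sd=0.0, resid_sd=0.3, seed=2)
        _, vs, _, singular = fit_segment_lmm(df, "MT")
        assert vs < 0.02

    def test_variance_component_recovery(self):
        vss, vrs = [], []
        for rep in range(300):
            df = balanced_long(n=24, subject_sd=0.5, resid_sd=0.2, seed=rep)
            _, vs, vr, _ = fit_segment_lmm(df, "MT")
            vss.append(vs)
            vrs.append(vr)
        assert np.mean(vss) == pytest.approx(0.25, rel=0.10)
        assert np.mean(vrs) == pytest.approx(0.04, rel=0.10)


class TestDecomposeEffects:
    def test_single_nonzero_column(self):
        R = np.zeros((3, 4))
        R[:, 2] = [0.0, 0.5, 1.0]
        scores, loadings, ev = decompose_effects(R)
        assert ev[0] == pytest.approx(1.0)
        assert np.allclose(np.abs(loadings[:, 0]), [0, 0, 1, 0])
        assert loadings[2, 0] == 1.0          # sign convention
        assert np.allclose(scores[:, 0], [0.0, 0.5, 1.0])

    def test_two_identical_trajectories_symmetric_loadings(self):
        R = np.zeros((3, 2))
        R[:, 0] = [0, 0.2, 0.8]
        R[:, 1] = [0, 0.2, 0.8]
        scores, loadings, ev = decompose_effects(R)
        assert ev[0] == pytest.approx(1.0)
        assert np.allclose(np.abs(loadings[:, 0]), 1 / np.sqrt(2))

    def test_orthogonal_equal_norm_patterns_split_variance(self):
        R = np.zeros((3, 2))
        R[:, 0] = [0, 1.0, 0.0]
        R[:, 1] = [0, 0.0, 1.0]
        _, _, ev = decompose_effects(R)
        assert np.allclose(sorted(ev), [0.5, 0.5])

    def test_all_zero_matrix_flagged(self):
        scores, loadings, ev = decompose_effects(np.zeros((3, 4)))
        assert not ev.any() and not loadings.any()

    def test_explained_variance_sums_to_one(self, rng):
        R = np.vstack([np.zeros(5), rng.standard_normal((2, 5))])
        _, _, ev = decompose_effects(R)
        assert ev.sum() == pytest.approx(1.0)
        assert np.all(np.diff(ev) <= 1e-12)


class TestClassifySegment:
    def test_printed_decrease_pattern_is_plastic(self):
        # stable control CIs, clearly separated post-training CI
        flags = classify_segment({"MRI1": (-0.07, 0.56), "MRI2": (-0.08, 0.52),
                                  "MRI3": (-0.81, -0.17)})
        assert flags["plastic"]

    def test_control_overlap_rescues_increase_pattern(self):
        # MRI1 and MRI2 CIs overlap on [-0.38, -0.12] although MRI2 excludes 0
        flags = classify_segment({"MRI1": (-0.38, 0.24), "MRI2": (-0.68, -0.12),
                                  "MRI3": (0.26, 0.79)})
        assert flags["stable_control"] and flags["plastic"]

    def test_identical_cis_not_plastic(self):
        ci = (-0.2, 0.4)
        flags = classify_segment({"MRI1": ci, "MRI2": ci, "MRI3": ci})
        assert not flags["plastic"]

    def test_unstable_control_blocks_plasticity(self):
        flags = classify_segment({"MRI1": (0.3, 0.6), "MRI2": (-0.6, -0.3),
                                  "MRI3": (-2.0, -1.5)})
        assert flags["change_13"] and flags["change_23"]
        assert not flags["plastic"]


class TestSegmentModel:
    def test_effect_matrix_structure_balanced(self, small_effect_config):
        panel, _ = tp.generate_tract_profiles(small_effect_config(seed=4))
        res = SegmentASCA(panel, "ATR_right", 4).fit(B=0)
        # 3 unique session rows, baseline all zero
        assert res.beta.shape == (3, 8)
        assert np.allclose(res.beta.loc["MRI1"], 0.0)
        M = res.beta.loc[np.repeat(["MRI1", "MRI2", "MRI3"], 24)].to_numpy()
        assert M.shape == (72, 8)
        assert len(np.unique(M, axis=0)) == 3

    def test_loading_recovery_cosine(self):
        # injected pattern recovered by PC1 up to sign, cosine >= 0.99
        pattern = {"FISO": -0.8, "FICVF": -0.6}
        cfg = tp.CohortConfig(
            tracts=("ATR_right",), n_segments=2, sigma_subject=0.3,
            sigma_resid=0.05,
            effects=[tp.EffectTemplate("ATR_right", (1,), dict(pattern),
                                       group_magnitude=1.0)], seed=5)
        panel, _ = tp.generate_tract_profiles(cfg)
        res = SegmentASCA(panel, "ATR_right", 1).fit(B=0)
        truth = np.array([pattern.get(m, 0.0) for m in res.metrics])
        truth /= np.linalg.norm(truth)
        pc1 = res.loadings["PC1"].to_numpy()
        cosine = abs(truth @ pc1) / np.linalg.norm(pc1)
        assert cosine >= 0.99

    def test_bootstrap_deterministic_given_seed(self, small_effect_config):
        panel, _ = tp.generate_tract_profiles(small_effect_config(seed=6))
        r1 = SegmentASCA(panel, "ATR_right", 4).fit(B=100, seed=42)
        r2 = SegmentASCA(panel, "ATR_right", 4).fit(B=100, seed=42)
        assert r1.score_cis.equals(r2.score_cis)
        assert r1.loading_cis.equals(r2.loading_cis)

    def test_near_zero_noise_cis_collapse_on_point(self,
                                                   small_effect_config):
        # no noise and no subject-level effect variability: resampling
        # subjects cannot move the estimate, so intervals collapse.
        # (metrics without signal are excluded: z-scoring would rescale
        # their vanishing noise back to unit variance)
        cfg = small_effect_config(
            seed=7, sigma_subject=1e-4, sigma_resid=1e-4,
            metrics=("FISO", "FICVF"),
            effects=[tp.EffectTemplate("ATR_right", (4, 5),
                                       {"FISO": -0.8, "FICVF": -0.6},
                                       group_magnitude=1.0,
                                       subject_sd=0.0)])
        panel, _ = tp.generate_tract_profiles(cfg)
        res = SegmentASCA(panel, "ATR_right", 4).fit(B=100, seed=0)
        for s in ("MRI2", "MRI3"):
            lo, hi = res.score_cis.loc[s]
            point = res.scores.loc[s, "PC1"]
            assert hi - lo < 0.05
            assert lo - 0.02 <= point <= hi + 0.02

    def test_baseline_score_anchored_at_origin(self, small_effect_config):
        panel, _ = tp.generate_tract_profiles(small_effect_config(seed=8))
        res = SegmentASCA(panel, "ATR_right", 4).fit(B=50, seed=0)
        assert res.scores.loc["MRI1", "PC1"] == 0.0
        assert tuple(res.score_cis.loc["MRI1"]) == (0.0, 0.0)

    def test_predict_scores_projection_consistency(self, small_effect_config):
        panel, _ = tp.generate_tract_profiles(small_effect_config(seed=9))
        res = SegmentASCA(panel, "ATR_right", 4).fit(B=0)
        scores = res.predict_scores()
        assert scores.shape == (24, 3)
        # group means of subject scores track the model's session scores:
        # mean standardized vector at session t is the effect row plus the
        # (session-constant) grand offset, so differences match exactly
        d23 = scores["MRI3"].mean() - scores["MRI2"].mean()
        model_d23 = (res.scores.loc["MRI3", "PC1"]
                     - res.scores.loc["MRI2", "PC1"])
        assert d23 == pytest.approx(model_d23, abs=1e-10)

    def test_predicted_change_recovers_subject_magnitudes(self):
        # Spearman between predicted interval changes and injected subject
        # magnitudes under a strong, subject-variable effect
        cfg = tp.CohortConfig(
            tracts=("ATR_right",), n_segments=2, sigma_subject=0.4,
            sigma_resid=0.15,
            effects=[tp.EffectTemplate("ATR_right", (1,),
                                       {"FISO": -0.8, "FICVF": -0.6},
                                       group_magnitude=1.5, subject_sd=0.75)],
            seed=10)
        panel, mags = tp.generate_tract_profiles(cfg)
        res = SegmentASCA(panel, "ATR_right", 1).fit(B=0)
        deltas = tp.interval_change_scores(res.predict_scores())
        rho = tp.spearman(deltas["delta_23"], mags)
        assert abs(rho) > 0.8

    def test_unbalanced_panel_uses_mixedlm_and_matches_balanced(self,
                                                                null_config):
        cfg = null_config(seed=11, n_subjects=8, n_segments=2,
                          metrics=("MT", "R1"))
        panel, _ = tp.generate_tract_profiles(cfg)
        res_bal = SegmentASCA(panel, "CST_left", 1).fit(B=0)
        # drop one unrelated observation to force the REML path
        df = panel.data.drop(panel.data[
            (panel.data["subject_id"] == "S01")
            & (panel.data["session"] == "MRI2")
            & (panel.data["segment"] == 2)].index)
        res_unb = SegmentASCA(tp.TractProfilePanel(df, validate=False),
                              "CST_left", 1).fit(B=0)
        # segment 1 data identical, so effects agree to numerical precision
        assert np.allclose(res_unb.beta.to_numpy(), res_bal.beta.to_numpy(),
                           atol=1e-6)
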