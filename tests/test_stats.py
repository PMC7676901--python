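"""Mixed models, Tukey post-hoc comparisons, AIC bookkeeping, stepwise
selection and exam z-score arithmetic."""

import numpy as np
import pandas as pd
import pytest

from eeglisten.stats import (ModelSpec, compare_models, exam_zscores,
                             fit_lmm, pivot_subregion_scores, predict_exam,
                             stepwise_backward, tukey_posthoc)


def _mixed_data(seed=0, n_p=23, n_obs=30, beta_la=0.5, re_sd=0.3,
                noise=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_p):
        u = rng.normal(0, re_sd)
        for i in range(n_obs):
            task = ("LA", "BA", "BUA")[i % 3]
            rows.append({"participant": f"P{p:02d}", "task": task,
                         "y": 1.0 + beta_la * (task == "LA") + u
                         + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_aic_identity_and_edf(self):
        df = _mixed_data()
        fit = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df))
        assert fit.edf == 3 + 2  # 3 fixed coefs + RE variance + residual
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.edf, abs=1e-12)
        ols = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df,
                                random_intercept=None))
        assert ols.edf == 3 + 1
        assert ols.aic == pytest.approx(-2 * ols.llf + 2 * ols.edf, abs=1e-12)

    def test_recovers_planted_coefficients(self):
        hits = 0
        for s in range(5):
            df = _mixed_data(seed=s)
            fit = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df))
            beta = fit.params["task[T.LA]"]
            se = fit.bse["task[T.LA]"]
            hits += abs(beta - 0.5) <= 1.96 * se
        assert hits >= 4

    def test_zero_between_participant_variance_flagged(self):
        df = _mixed_data(seed=1, re_sd=0.0)
        fit = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df))
        assert fit.random_variance < 0.01

    def test_grouping_needs_two_levels(self):
        df = _mixed_data().query("participant == 'P00'")
        with pytest.raises(ValueError, match="2 levels"):
            ModelSpec(response="y", fixed=["task"], data=df)


class TestTukey:
    def test_strong_separation_detected(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(10):
            for g, mu in (("a", 0.0), ("b", 5.0)):  # 5 pooled SDs apart
                for _ in range(5):
                    rows.append({"participant": f"P{p}", "g": g,
                                 "y": mu + rng.normal()})
        df = pd.DataFrame(rows)
        fit = fit_lmm(ModelSpec(response="y", fixed=["g"], data=df))
        tk = tukey_posthoc(fit, "g")
        assert tk.pairs["p_adj"].iloc[0] < 0.001
        assert tk.max_level == "b"

    def test_emmean_differences_antisymmetric(self):
        df = _mixed_data(seed=4)
        fit = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df))
        tk = tukey_posthoc(fit, "task")
        # estimate(a,b) equals emmean difference; swapping roles flips sign
        for _, row in tk.pairs.iterrows():
            diff = tk.emmeans[row["level_a"]] - tk.emmeans[row["level_b"]]
            assert row["estimate"] == pytest.approx(diff, abs=1e-10)

    def test_triangular_layout(self):
        df = _mixed_data(seed=5)
        fit = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df))
        tri = tukey_posthoc(fit, "task").to_triangular()
        assert set(tri.index) == {"LA", "BA", "BUA"}
        diag = [tri.iloc[i, i] for i in range(3)]
        assert "max" in diag and "min" in diag


class TestCompareAndStepwise:
    def test_identical_models_give_p_one(self):
        df = _mixed_data(seed=6)
        a = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df))
        b = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df))
        out = compare_models(a, b)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-6)
        assert out["p"] == pytest.approx(1.0, abs=1e-6)

    def test_delta_aic_hand_arithmetic(self):
        df = _mixed_data(seed=7)
        a = fit_lmm(ModelSpec(response="y", fixed=[], data=df,
                              random_intercept=None))
        b = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df,
                              random_intercept=None))
        out = compare_models(a, b)
        exp = (-2 * b.llf + 2 * b.edf) - (-2 * a.llf + 2 * a.edf)
        assert out["delta_aic"] == pytest.approx(exp, abs=1e-12)

    def test_non_nested_refused(self):
        df = _mixed_data(seed=8)
        df["x"] = np.random.default_rng(0).normal(size=len(df))
        a = fit_lmm(ModelSpec(response="y", fixed=["task"], data=df,
                              random_intercept=None))
        b = fit_lmm(ModelSpec(response="y", fixed=["x"], data=df,
                              random_intercept=None))
        out = compare_models(a, b)
        assert out["chi2"] is None and not out["nested"]

    def test_stepwise_drops_noise_keeps_signal(self):
        kept_signal, dropped_noise = 0, 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            n = 300
            df = pd.DataFrame({
                "x1": rng.normal(size=n), "x2": rng.normal(size=n),
                "noise": rng.normal(size=n)})
            df["y"] = 1 + 0.8 * df.x1 - 0.6 * df.x2 + rng.normal(0, 1, n)
            full = fit_lmm(ModelSpec(response="y",
                                     fixed=["x1", "x2", "noise"], data=df,
                                     random_intercept=None))
            red, kept = stepwise_backward(full)
            kept_signal += {"x1", "x2"} <= set(kept)
            dropped_noise += "noise" not in kept
            assert red.aic <= full.aic + 1e-9
        assert kept_signal == 5
        assert dropped_noise >= 4


class TestExamZ:
    def test_hand_checked_case(self):
        # pink keyword counts {1, 3, 5} -> mu = 3, sigma = 2
        exam = pd.DataFrame({
            "participant": ["a", "b", "c", "a"],
            "topic": ["t1"] * 4,
            "background": ["PK", "PK", "PK", "MT"],
            "keywords_correct": [1, 3, 5, 5]})
        ez = exam_zscores(exam)
        assert ez.attrs["pink_stats"]["t1"]["mu_pink"] == 3.0
        assert ez.attrs["pink_stats"]["t1"]["sigma_pink"] == 2.0
        np.testing.assert_allclose(ez["z"], [-1.0, 0.0, 1.0, 1.0])

    def test_pink_rows_standardized_exactly(self, rng):
        rows = []
        for t in ("t1", "t2"):
            for p in range(6):
                rows.append({"participant": f"P{p}", "topic": t,
                             "background": "PK",
                             "keywords_correct": int(rng.integers(0, 20))})
        ez = exam_zscores(pd.DataFrame(rows))
        for _, grp in ez.groupby("topic"):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_row_order_invariance(self, rng):
        rows = pd.DataFrame({
            "participant": list("abcdef"), "topic": ["t"] * 6,
            "background": ["PK", "PK", "MT", "HW", "PK", "FT"],
            "keywords_correct": [4, 8, 2, 9, 6, 5]})
        z1 = exam_zscores(rows)["z"].to_numpy()
        perm = rows.sample(frac=1, random_state=1)
        z2 = exam_zscores(perm)["z"]
        np.testing.assert_allclose(z2.sort_index().to_numpy(), z1)

    def test_degenerate_sigma_and_missing_pink(self):
        same = pd.DataFrame({
            "participant": ["a", "b", "c"], "topic": ["t"] * 3,
            "background": ["PK", "PK", "MT"], "keywords_correct": [4, 4, 9]})
        ez = exam_zscores(same)
        assert ez.attrs["pink_stats"]["t"]["degenerate"]
        assert ez["z"].isna().all()
        nopink = same.assign(background=["MT", "HW", "MT"])
        with pytest.raises(ValueError, match="pink"):
            exam_zscores(nopink)


class TestScoreModels:
    def _frame(self, seed=0, beta_la=0.8):
        rng = np.random.default_rng(seed)
        rows = []
        subregions = ("frontal", "central", "left_temporal",
                      "right_temporal", "parietal", "occipital")
        for p in range(10):
            u = rng.normal(0, 0.3)
            f = 0
            for task in ("LA", "BA", "BUA"):
                for bg in ("MT", "HW"):
                    for _ in range(2):
                        for sr in subregions:
                            rows.append({
                                "participant": f"P{p}", "task": task,
                                "background": bg, "topic": None,
                                "fragment": f, "subregion": sr,
                                "PC1": beta_la * (task == "LA") + u
                                + rng.normal(0, 0.5),
                                "PC2": rng.normal()})
                        f += 1
        return pd.DataFrame(rows)

    def test_one_fit_per_pc_and_level_with_tukey(self):
        from eeglisten.stats import score_models

        out = score_models(self._frame(), by="background", k=2)
        # 2 PCs x 2 backgrounds
        assert set(out) == {(f"PC{i}", bg) for i in (1, 2)
                            for bg in ("MT", "HW")}
        for bg in ("MT", "HW"):
            tk = out[("PC1", bg)]["tukey"]
            assert tk.max_level == "LA"
            la_pairs = tk.pairs[(tk.pairs.level_a == "LA")
                                | (tk.pairs.level_b == "LA")]
            assert (la_pairs["p_adj"] < 0.05).all()
        # null component: no consistent direction expected
        fit = out[("PC2", "MT")]["fit"]
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.edf)

    def test_within_task_family(self):
        from eeglisten.stats import score_models

        out = score_models(self._frame(), by="task", k=1)
        assert set(out) == {("PC1", t) for t in ("LA", "BA", "BUA")}
        assert out[("PC1", "LA")]["tukey"].factor == "background"


class TestPredictExam:
    def _inputs(self, seed=0, n_p=8, n_topics=6, weight=-1.0):
        """Subregion scores with one informative predictor planted into the
        exam response."""
        rng = np.random.default_rng(seed)
        sub_rows, exam_rows = [], []
        subregions = ("frontal", "central", "left_temporal",
                      "right_temporal", "parietal", "occipital")
        for p in range(n_p):
            for t in range(n_topics):
                bg = ("PK", "MT")[(p + t) % 2]
                signal = rng.normal()
                for sr in subregions:
                    sub_rows.append({
                        "participant": f"P{p}", "topic": f"T{t}",
                        "task": "LA", "background": bg, "subregion": sr,
                        "PC1": signal if sr == "parietal" else rng.normal(),
                        "PC2": rng.normal()})
                kw = 10 + weight * 2 * signal + rng.normal(0, 0.5)
                exam_rows.append({"participant": f"P{p}", "topic": f"T{t}",
                                  "background": bg,
                                  "keywords_correct": max(0, round(kw))})
        examz = exam_zscores(pd.DataFrame(exam_rows))
        return examz, pd.DataFrame(sub_rows)

    def test_pivot_shape(self):
        examz, sub = self._inputs()
        wide = pivot_subregion_scores(sub, k=2)
        assert {"parietal_PC1", "frontal_PC2"} <= set(wide.columns)
        assert len(wide) == 8 * 6

    def test_recovers_planted_predictor_fixed_mode(self):
        examz, sub = self._inputs(seed=2)
        out = predict_exam(examz, sub, mode="fixed", k=2)
        assert "parietal_PC1" in out["retained"]
        assert out["fits"]["stepwise_eeg"].params["parietal_PC1"] < 0
        fits = out["fits"]
        assert fits["stepwise_eeg"].aic < fits["background"].aic

    def test_mixed_mode_runs_and_orders_models(self):
        examz, sub = self._inputs(seed=3)
        out = predict_exam(examz, sub, mode="mixed", k=2)
        assert set(out["fits"]) == {"constant", "background", "full_eeg",
                                    "stepwise_eeg"}
        comp = out["comparisons"]
        nested = comp[(comp.model_a == "constant")
                      & (comp.model_b == "background")]
        assert nested["nested"].iloc[0]
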