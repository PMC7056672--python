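import numpy as np
import pandas as pd
import pytest

from microgdm.gdm_classifier import (
    ClassifierModel,
    compare_models,
    evaluate_external,
    fit_lda,
    forward_select,
    genus_feature_frame,
    loocv_performance,
    roc_auc_ci,
)
from microgdm.io_formats import OtuTable, ValidationError


class TestFitLda:
    def test_direction_toward_case(self, rng):
        x = np.r_[rng.normal(1, 1, 50), rng.normal(-1, 1, 50)][:, None]
        y = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        w, b = fit_lda(x, y)
        assert w[0] > 0

    def test_hand_two_feature_solution(self):
        # pooled covariance and mean difference computed by hand
        x1 = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, -1.0], [2.0, 0.0]])
        x0 = np.array([[-1.0, 0.5], [-2.0, -0.5], [-3.0, 0.0], [-2.0, 0.0]])
        X = np.vstack([x1, x0])
        y = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        Z = (X - mean) / sd
        m1, m0 = Z[:4].mean(axis=0), Z[4:].mean(axis=0)
        S = ((Z[:4] - m1).T @ (Z[:4] - m1) + (Z[4:] - m0).T @ (Z[4:] - m0)) / 6
        S += 1e-6 * np.trace(S) * np.eye(2)
        w_std = np.linalg.solve(S, m1 - m0)
        w_hand = w_std / sd
        b_hand = -w_std @ (m1 + m0) / 2 - w_hand @ mean
        w, b = fit_lda(X, y)
        assert np.allclose(w, w_hand, atol=1e-8)
        assert b == pytest.approx(b_hand, abs=1e-8)

    def test_duplicated_columns_error(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        with pytest.raises(ValidationError, match="collinear"):
            fit_lda(X, y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_lda(rng.normal(size=(5, 2)), np.ones(5, bool))


class TestLoocv:
    def test_perfect_separation_auc_one(self):
        x = np.r_[np.ones(10), np.zeros(10)][:, None] * 10
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        auc, acc = loocv_performance(x, y)
        assert auc == pytest.approx(1.0)
        assert acc == pytest.approx(1.0)

    def test_noise_feature_near_half(self):
        # LOOCV AUC of a null feature is pessimistically biased (sign-flip
        # artifact), so the median sits just below 0.5 with wide spread; the
        # property that matters is the absence of optimistic inflation.
        aucs = []
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(140, 1))
            y = np.r_[np.ones(70, bool), np.zeros(70, bool)]
            auc, _ = loocv_performance(x, y)
            aucs.append(auc)
        assert 0.4 <= np.median(aucs) <= 0.6
        assert sum(a > 0.7 for a in aucs) <= 2

    def test_too_few_samples(self, rng):
        with pytest.raises(ValidationError):
            loocv_performance(rng.normal(size=(6, 1)),
                              np.r_[np.ones(3, bool), np.zeros(3, bool)])


class TestRocAucCi:
    def test_hand_pair_count(self):
        res = roc_auc_ci([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_scores_equal_labels(self):
        res = roc_auc_ci([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_all_ties_half(self):
        res = roc_auc_ci([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert res.auc == pytest.approx(0.5)

    def test_curve_endpoints_monotone(self, rng):
        scores = rng.normal(size=40)
        y = rng.random(40) < 0.5
        y[0], y[1] = True, False
        res = roc_auc_ci(scores, y)
        fpr = np.array([p[0] for p in res.curve])
        tpr = np.array([p[1] for p in res.curve])
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0)

    def test_ci_contains_auc_and_shrinks(self, rng):
        def width(n):
            ws = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                y = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
                scores = r.normal(size=n) + y
                res = roc_auc_ci(scores, y)
                assert res.ci_low <= res.auc <= res.ci_high
                ws.append(res.ci_high - res.ci_low)
            return np.mean(ws)

        assert width(140) < width(56)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=30)
        y = rng.random(30) < 0.5
        y[:2] = [True, False]
        a1 = roc_auc_ci(scores, y).auc
        a2 = roc_auc_ci(np.exp(scores), y).auc
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc_ci([1.0, 2.0], [1, 1])


class TestForwardSelect:
    def _frame(self, rng, n=100, p_noise=20, effect=3.0):
        y = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
        cols = {"signal": rng.normal(size=n) + effect * y}
        for j in range(p_noise):
            cols[f"noise{j}"] = rng.normal(size=n)
        return pd.DataFrame(cols), y

    def test_informative_selected_first(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X, y = self._frame(rng)
            model = forward_select(X, y, list(X.columns), max_features=3)
            if model.training_summary[0]["feature"] == "signal":
                hits += 1
        assert hits >= int(0.95 * n_seeds) - 1

    def test_deterministic(self, rng):
        X, y = self._frame(rng)
        m1 = forward_select(X, y, list(X.columns), max_features=4)
        m2 = forward_select(X, y, list(X.columns), max_features=4)
        assert m1.selected_features == m2.selected_features
        assert m1.weights == m2.weights

    def test_empty_candidates_rejected(self, rng):
        X, y = self._frame(rng)
        with pytest.raises(ValidationError):
            forward_select(X, y, [])

    def test_bad_max_features(self, rng):
        X, y = self._frame(rng)
        with pytest.raises(ValidationError):
            forward_select(X, y, ["signal"], max_features=0)

    def test_final_beats_every_single_candidate(self, rng):
        X, y = self._frame(rng, n=60, p_noise=6)
        model = forward_select(X, y, list(X.columns), max_features=5)
        best = max(step["auc"] for step in model.training_summary)
        for c in X.columns:
            auc, _ = loocv_performance(X, y, [c])
            assert best >= auc - 1e-12

    def test_model_json_round_trip(self, rng, tmp_path):
        X, y = self._frame(rng, n=40, p_noise=3)
        model = forward_select(X, y, list(X.columns), max_features=3)
        p = tmp_path / "model.json"
        model.to_json(p)
        m2 = ClassifierModel.from_json(p)
        assert m2.selected_features == model.selected_features
        assert m2.weights == pytest.approx(model.weights)
        assert np.allclose(m2.score(X), model.score(X))


class TestEvaluateExternal:
    def test_shuffled_validation_near_half(self, rng):
        X, y = TestForwardSelect()._frame(rng, n=120)
        model = forward_select(X, y, list(X.columns), max_features=3)
        Xv, yv = TestForwardSelect()._frame(np.random.default_rng(99), n=120)
        yv = np.random.default_rng(1).permutation(yv)
        res = evaluate_external(model, Xv, yv)
        assert 0.3 <= res.auc <= 0.7

    def test_missing_feature_rejected(self, rng):
        X, y = TestForwardSelect()._frame(rng, n=40, p_noise=2)
        model = forward_select(X, y, list(X.columns), max_features=2)
        Xv = X.drop(columns=model.selected_features[:1])
        with pytest.raises(ValidationError):
            evaluate_external(model, Xv, y)

    def test_train_validation_optimism(self):
        # in-sample score of the final model is on average >= validation
        diffs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X, y = TestForwardSelect()._frame(rng, n=80, p_noise=10,
                                              effect=1.0)
            Xv, yv = TestForwardSelect()._frame(
                np.random.default_rng(seed + 500), n=80, p_noise=10,
                effect=1.0)
            model = forward_select(X, y, list(X.columns), max_features=5)
            train_roc = roc_auc_ci(model.score(X), y)
            val_roc = evaluate_external(model, Xv, yv)
            diffs.append(train_roc.auc - val_roc.auc)
        assert np.mean(diffs) >= 0


class TestCompareModels:
    def test_signal_only_in_genus_block(self, rng):
        n = 80
        y = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]

        def make(r):
            return pd.DataFrame({
                "g1": r.normal(size=n) + 2.0 * y,
                "g2": r.normal(size=n),
                "c1": r.normal(size=n),
                "c2": r.normal(size=n),
            })

        X, Xv = make(rng), make(np.random.default_rng(7))
        res = compare_models(X, y, Xv, y, ["g1", "g2"], ["c1", "c2"],
                             max_features=2)
        assert res["genus_only"]["validation"].auc > \
            res["clinical_only"]["validation"].auc + 0.1
        assert abs(res["combined"]["validation"].auc
                   - res["genus_only"]["validation"].auc) < 0.1


class TestGenusFeatureFrame:
    def test_prevalence_filter_and_log_scale(self):
        counts = np.array([[10, 0, 5], [20, 0, 0], [30, 1, 0], [40, 0, 0]])
        t = OtuTable([f"s{i}" for i in range(4)], ["a", "b", "c"], counts)
        f = genus_feature_frame(t, min_prevalence=0.5)
        assert list(f.columns) == ["a"]
        rel = counts[:, 0] / counts.sum(axis=1)
        assert np.allclose(f["a"], np.log10(rel + 1e-6))
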