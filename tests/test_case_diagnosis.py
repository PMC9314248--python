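"""Case aggregation, UIP scoring, ROC/AUC, bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mixture import case_diagnosis as cd
from mixture import integration as integ


def _scheme20():
    return integ.FindingScheme("20x", ("dense fibrosis", "fat", "other"))


class TestAggregateCase:
    def test_single_finding_proportion_one(self):
        pred = pd.DataFrame({"case_id": ["c1"] * 10,
                             "label": ["dense fibrosis"] * 10})
        (p,) = cd.aggregate_case(pred, "20x", _scheme20())
        assert p.proportions["dense fibrosis"] == 1.0
        assert p.n_tiles_retained == 10

    def test_complete_normal_excluded_from_denominator_at_5x(self):
        scheme = integ.default_scheme("5x")
        labels = (["complete normal"] * 4 + ["acellular fibrosis"] * 3
                  + ["edge"] * 3)
        pred = pd.DataFrame({"case_id": ["c1"] * 10, "label": labels})
        (p,) = cd.aggregate_case(pred, "5x", scheme)
        assert p.counts["complete normal"] == 4
        assert p.proportions["acellular fibrosis"] == pytest.approx(0.5)
        assert p.proportions["edge"] == pytest.approx(0.5)
        assert "complete normal" not in p.proportions
        assert p.n_tiles_total == 10 and p.n_tiles_retained == 6

    def test_multi_slide_counts_add(self):
        pred = pd.DataFrame({
            "case_id": ["c"] * 6,
            "slide_id": ["s1"] * 5 + ["s2"],
            "label": ["dense fibrosis"] * 2 + ["fat"] * 3 + ["dense fibrosis"]})
        (p,) = cd.aggregate_case(pred, "20x", _scheme20())
        assert p.counts == {"dense fibrosis": 3, "fat": 3, "other": 0}

    def test_slide_order_invariance(self):
        rows = [("c", "dense fibrosis"), ("c", "fat"), ("c", "fat")]
        a = cd.aggregate_case(pd.DataFrame(rows, columns=["case_id", "label"]),
                              "20x", _scheme20())[0]
        b = cd.aggregate_case(pd.DataFrame(rows[::-1],
                                           columns=["case_id", "label"]),
                              "20x", _scheme20())[0]
        assert a.proportions == b.proportions

    def test_zero_retained_flagged_invalid(self):
        scheme = integ.default_scheme("5x")
        pred = pd.DataFrame({"case_id": ["c"] * 3,
                             "label": ["complete normal"] * 3})
        (p,) = cd.aggregate_case(pred, "5x", scheme)
        assert not p.valid
        assert cd.profiles_to_features([p]).empty


class TestSplitCases:
    def test_180_cases_give_126_54(self):
        labels = np.array([1] * 110 + [0] * 70)
        cfg = cd.DiagnosisConfig(seed=0)
        tr, va = cd.split_cases(labels, cfg)
        assert len(tr) == 126 and len(va) == 54
        # prevalence balanced to within one case
        assert abs(labels[tr].sum() / 126 - labels[va].sum() / 54) < 0.02

    def test_small_stratification_bound(self):
        labels = np.array([1] * 5 + [0] * 5)
        cfg = cd.DiagnosisConfig(train_fraction=0.5, seed=3)
        tr, va = cd.split_cases(labels, cfg)
        assert labels[tr].sum() in (2, 3)

    def test_seeded_partition_reproducible(self):
        labels = np.random.default_rng(0).integers(0, 2, 50)
        cfg = cd.DiagnosisConfig(seed=9)
        a = cd.split_cases(labels, cfg)
        b = cd.split_cases(labels, cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cd.split_cases(np.ones(10), cd.DiagnosisConfig())


class TestUipModels:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        x = rng.standard_normal((n, 4)) * 0.3
        x[:, 0] += 2.0 * y
        return pd.DataFrame(x, columns=list("abcd")), y

    @pytest.mark.parametrize("algorithm", ["random_forest", "svm"])
    def test_separable_profiles_high_auc(self, algorithm):
        X, y = self._separable()
        cfg = cd.DiagnosisConfig(algorithm=algorithm, n_trees=200, seed=1)
        tr, va = cd.split_cases(y, cfg)
        scorer = cd.train_uip_model(X.iloc[tr], y[tr], cfg)
        scores = cd.predict_scores(scorer, X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert cd.roc_auc(scores[va], y[va]).auc >= 0.95

    def test_shuffled_labels_chance_auc(self):
        X, y = self._separable(n=200, seed=2)
        rng = np.random.default_rng(3)
        y_shuf = rng.permutation(y)
        cfg = cd.DiagnosisConfig(n_trees=200, seed=4)
        tr, va = cd.split_cases(y_shuf, cfg)
        scorer = cd.train_uip_model(X.iloc[tr], y_shuf[tr], cfg)
        auc = cd.roc_auc(cd.predict_scores(scorer, X)[va], y_shuf[va]).auc
        assert 0.4 <= auc <= 0.6 or abs(auc - 0.5) <= 0.1

    def test_feature_importance_semantics(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        X = pd.DataFrame({"label_copy": y.astype(float),
                          "noise1": rng.standard_normal(300),
                          "noise2": rng.standard_normal(300)})
        noise_means = []
        for seed in range(10):
            cfg = cd.DiagnosisConfig(n_trees=100, seed=seed)
            scorer = cd.train_uip_model(X, y, cfg)
            imp = cd.feature_importance(scorer)
            assert (imp >= 0).all()
            assert imp.idxmax() == "label_copy"
            noise_means.append(imp[["noise1", "noise2"]].mean())
        assert np.mean(noise_means) < 0.2

    def test_feature_importance_requires_forest(self):
        X, y = self._separable(n=50)
        cfg = cd.DiagnosisConfig(algorithm="svm", seed=0)
        scorer = cd.train_uip_model(X, y, cfg)
        with pytest.raises(NotImplementedError):
            cd.feature_importance(scorer)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cd.train_uip_model(np.ones((5, 2)), np.ones(4),
                               cd.DiagnosisConfig())


class TestRocAuc:
    def test_perfect_separation(self):
        assert cd.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auc == 1.0

    def test_all_ties_give_half(self):
        assert cd.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_matches_pairwise_concordance_brute_force(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.random(200), 2)      # induce ties
        labels = rng.integers(0, 2, 200)
        res = cd.roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        brute = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                         for p in pos for n in neg])
        assert res.auc == pytest.approx(brute, abs=1e-12)
        assert res.ci_lower <= res.auc <= res.ci_upper

    def test_bootstrap_ci_contains_auc(self):
        rng = np.random.default_rng(8)
        scores, labels = rng.random(60), rng.integers(0, 2, 60)
        res = cd.roc_auc(scores, labels, ci_method="bootstrap", seed=0)
        assert res.ci_lower <= res.auc <= res.ci_upper

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cd.roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = np.r_[rng.integers(0, 2, 28), 0, 1]  # both classes present
        a = cd.roc_auc(scores, labels).auc
        b = cd.roc_auc(np.exp(3 * scores) - 0.5, labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestCompareAucBootstrap:
    def test_identical_scorers_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.random(40)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        p, delta, _ = cd.compare_auc_bootstrap(s, s, y, n_bootstrap=200, seed=1)
        assert p == 1.0 and delta == 0.0

    def test_seeded_p_reproducible(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(25), np.zeros(25)].astype(int)
        a, b = rng.random(50), rng.random(50)
        p1, _, _ = cd.compare_auc_bootstrap(a, b, y, n_bootstrap=300, seed=7)
        p2, _, _ = cd.compare_auc_bootstrap(a, b, y, n_bootstrap=300, seed=7)
        assert p1 == p2

    def test_clearly_better_scorer_detected(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 120)
        good = y + 0.1 * rng.standard_normal(120)
        bad = rng.random(120)
        p, delta, _ = cd.compare_auc_bootstrap(good, bad, y,
                                               n_bootstrap=500, seed=3)
        assert delta > 0.2 and p < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cd.compare_auc_bootstrap([0.1], [0.1, 0.2], [0, 1])


class TestThresholdMetrics:
    def test_perfect_scorer(self):
        sens, spec = cd.threshold_metrics([0.9, 0.8, 0.1], [1, 1, 0], 0.5)
        assert (sens, spec) == (1.0, 1.0)

    def test_constant_score_above_threshold(self):
        sens, spec = cd.threshold_metrics([0.6] * 6, [1, 1, 0, 0, 0, 1], 0.5)
        assert (sens, spec) == (1.0, 0.0)

    def test_matches_confusion_matrix_brute_force(self):
        rng = np.random.default_rng(9)
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        sens, spec = cd.threshold_metrics(scores, labels, 0.4)
        pred = scores >= 0.4
        tp = np.sum(pred & (labels == 1)); fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0)); fp = np.sum(pred & (labels == 0))
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))
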