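"""Classifiers, case schemes, trial-wise cross-validation, metrics and the
Bonferroni-corrected ANOVA."""

import numpy as np
import pandas as pd
import pytest

from emgforce.evaluate import (
    CaseScheme,
    case_schemes,
    compare_methods_anova,
    confusion_counts,
    crossvalidate,
    make_classifier,
    metrics_from_counts,
    metrics_from_predictions,
)
from emgforce.signal_io import FORCES


class TestCaseSchemes:
    def test_structure(self):
        assert [s.train_forces for s in case_schemes(1)] == [(f,) for f in FORCES]
        assert all(s.test_forces == (f,) for s, f in zip(case_schemes(1), FORCES))
        assert all(s.test_forces == FORCES for s in case_schemes(2))
        assert [len(s.train_forces) for s in case_schemes(3)] == [2, 2, 2]
        assert case_schemes(4) == [CaseScheme(4, FORCES, FORCES)]

    def test_invalid_case_rejected(self):
        with pytest.raises(ValueError):
            case_schemes(5)

    def test_unknown_force_rejected(self):
        with pytest.raises(ValueError, match="force"):
            CaseScheme(1, ("extreme",), ("low",))


class TestClassifiers:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            make_classifier("CNN")

    def test_knn_majority_vote(self):
        X = np.array([[0.0], [0.1], [1.0], [5.0]])
        y = np.array(["A", "A", "B", "B"])
        clf = make_classifier("KNN").fit(X, y)
        assert clf.predict(np.array([[0.05]]))[0] == "A"  # neighbours A, A, B

    def test_knn_tie_broken_by_nearest(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["B", "A", "C"])
        clf = make_classifier("KNN").fit(X, y)
        assert clf.predict(np.array([[0.1]]))[0] == "B"

    def test_rbf_svm_solves_xor(self):
        rng = np.random.default_rng(0)
        centres = np.array([[2.0, 2], [-2, -2], [2, -2], [-2, 2]])
        labels = np.array([0, 0, 1, 1])
        X = np.vstack([c + 0.15 * rng.standard_normal((50, 2)) for c in centres])
        y = np.repeat(labels, 50)
        clf = make_classifier("SVM").fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_quadratic_boundary_beats_linear_on_unequal_covariances(self):
        rng = np.random.default_rng(1)
        a = rng.multivariate_normal([0, 0], [[1, 0], [0, 1]], 1000)
        b = rng.multivariate_normal([0.5, 0], [[9, 0], [0, 0.25]], 1000)
        X = np.vstack([a, b])
        y = np.repeat([0, 1], 1000)
        quad = make_classifier("LDA", quadratic=True).fit(X, y)
        lin = make_classifier("LDA", quadratic=False).fit(X, y)
        assert np.mean(quad.predict(X) == y) >= np.mean(lin.predict(X) == y)


class TestMetrics:
    def test_perfect_prediction_scores_100(self):
        m = metrics_from_predictions([1, 2, 3, 1], [1, 2, 3, 1])
        assert all(v == 100.0 for v in m.values())

    def test_balanced_counts_give_50_percent(self):
        counts = {"g": {"tp": 1, "tn": 1, "fp": 1, "fn": 1}}
        m = metrics_from_counts(counts)
        assert all(v == pytest.approx(50.0) for v in m.values())

    def test_two_thirds_example(self):
        counts = {"g": {"tp": 2, "tn": 0, "fp": 1, "fn": 1}}
        m = metrics_from_counts(counts)
        assert m["precision"] == pytest.approx(200 / 3)
        assert m["sensitivity"] == pytest.approx(200 / 3)
        assert m["f1"] == pytest.approx(200 / 3)

    def test_zero_denominator_defined_as_zero_with_warning(self):
        counts = {"g": {"tp": 0, "tn": 5, "fp": 0, "fn": 3}}
        with pytest.warns(UserWarning, match="zero denominator"):
            m = metrics_from_counts(counts)
        assert m["precision"] == 0.0

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(5)
        y_true = rng.integers(0, 4, 60)
        y_pred = rng.integers(0, 4, 60)
        counts = confusion_counts(y_true, y_pred)
        for cls, c in counts.items():
            assert c["tp"] == sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
            assert c["fp"] == sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
            assert c["fn"] == sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
            assert sum(c.values()) == 60

    def test_two_class_sensitivity_specificity_symmetry(self):
        rng = np.random.default_rng(6)
        y_true = rng.integers(0, 2, 80)
        y_pred = rng.integers(0, 2, 80)
        c = confusion_counts(y_true, y_pred)
        sens_a = c[0]["tp"] / (c[0]["tp"] + c[0]["fn"])
        spec_b = c[1]["tn"] / (c[1]["tn"] + c[1]["fp"])
        assert sens_a == pytest.approx(spec_b)


def _separable_feature_table(n_gestures=3, noise=0.05, seed=0):
    """Windows whose features are a noisy one-hot encoding of the gesture."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(1, n_gestures + 1):
        for force in FORCES:
            for trial in range(1, 6):
                for k in range(4):
                    feat = np.eye(n_gestures)[g - 1] + noise * rng.standard_normal(n_gestures)
                    rows.append(
                        {
                            "subject": "S1", "gesture": g, "force": force,
                            "trial": trial, "window_start": 100 * k,
                            **{f"x{i}": v for i, v in enumerate(feat)},
                        }
                    )
    return pd.DataFrame(rows)


class TestCrossvalidate:
    def test_separable_data_scores_perfectly_in_every_fold(self):
        df = _separable_feature_table()
        rep = crossvalidate(df, CaseScheme(4, FORCES, FORCES), classifier="SVM")
        assert list(rep["fold"]) == [1, 2, 3, 4, 5]
        assert np.all(rep["f1"].to_numpy() == 100.0)

    def test_fold_sizes_respect_scheme(self):
        df = _separable_feature_table()
        rep1 = crossvalidate(df, CaseScheme(1, ("medium",), ("medium",)), classifier="KNN")
        # train: 1 force x 4 trials x 3 gestures x 4 windows; test: 1 trial's worth
        assert np.all(rep1["n_train"] == 48)
        assert np.all(rep1["n_test"] == 12)
        rep4 = crossvalidate(df, CaseScheme(4, FORCES, FORCES), classifier="KNN")
        assert np.all(rep4["n_train"] == 144)
        assert np.all(rep4["n_test"] == 36)

    def test_no_test_trial_leakage(self):
        """The held-out trial's window identifiers never occur in training."""
        df = _separable_feature_table()
        scheme = CaseScheme(2, ("medium",), FORCES)
        for fold in range(1, 6):
            tr = df[(df.trial != fold) & df.force.isin(scheme.train_forces)]
            te = df[(df.trial == fold) & df.force.isin(scheme.test_forces)]
            tr_ids = set(map(tuple, tr[["gesture", "force", "trial", "window_start"]].to_numpy()))
            te_ids = set(map(tuple, te[["gesture", "force", "trial", "window_start"]].to_numpy()))
            assert not tr_ids & te_ids

    def test_missing_trial_is_reported_by_condition(self):
        df = _separable_feature_table()
        df = df[~((df.gesture == 2) & (df.force == "high") & (df.trial == 3))]
        with pytest.raises(ValueError, match=r"gesture 2, force 'high'"):
            crossvalidate(df, CaseScheme(4, FORCES, FORCES))

    def test_case4_not_worse_than_case2_on_synthetic_features(self):
        """More training force levels cannot hurt on force-varying data."""
        rng = np.random.default_rng(9)
        rows = []
        for g in range(1, 4):
            for fi, force in enumerate(FORCES):
                for trial in range(1, 6):
                    for k in range(4):
                        feat = (1 + fi) * np.eye(3)[g - 1] + 0.3 * rng.standard_normal(3)
                        rows.append(
                            {"subject": "S1", "gesture": g, "force": force,
                             "trial": trial, "window_start": k,
                             **{f"x{i}": v for i, v in enumerate(feat)}}
                        )
        df = pd.DataFrame(rows)
        f1_case2 = crossvalidate(df, CaseScheme(2, ("low",), FORCES), "KNN")["f1"].mean()
        f1_case4 = crossvalidate(df, CaseScheme(4, FORCES, FORCES), "KNN")["f1"].mean()
        assert f1_case4 >= f1_case2


class TestAnova:
    def test_identical_vectors_give_p_one(self):
        perf = {"proposed": np.array([80.0, 85, 90]), "TD": np.array([80.0, 85, 90])}
        out = compare_methods_anova(perf, n_comparisons=1)
        assert out.loc[0, "p_corrected"] == pytest.approx(1.0)

    def test_large_effect_is_significant_and_matches_hand_f(self):
        rng = np.random.default_rng(3)
        a = rng.normal(90, 1, 27)
        b = rng.normal(80, 1, 27)
        out = compare_methods_anova({"proposed": a, "TD": b}, n_comparisons=6)
        assert out.loc[0, "p_corrected"] < 0.05
        # hand-computed one-way F for two equal groups
        grand = np.concatenate([a, b]).mean()
        ssb = 27 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        f_hand = (ssb / 1) / (ssw / 52)
        assert out.loc[0, "f_stat"] == pytest.approx(f_hand, rel=1e-9)

    def test_bonferroni_multiplies_and_clips(self):
        rng = np.random.default_rng(4)
        perf = {"proposed": rng.normal(85, 5, 27), "TD": rng.normal(84, 5, 27)}
        out = compare_methods_anova(perf, n_comparisons=6)
        assert out.loc[0, "p_corrected"] == pytest.approx(min(1.0, out.loc[0, "p_raw"] * 6))

    def test_zero_variance_everywhere_is_flagged_degenerate(self):
        perf = {"proposed": np.full(9, 90.0), "TD": np.full(9, 80.0)}
        out = compare_methods_anova(perf)
        assert bool(out.loc[0, "degenerate"])
        assert np.isnan(out.loc[0, "p_corrected"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_methods_anova({"proposed": np.zeros(5), "TD": np.zeros(4)})
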