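"""LDA, confusion metrics, stratified splitting and the comparison tasks.

scikit-learn's LDA serves as the independent oracle for the in-package
implementation; it is never used as the implementation itself.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from brainfog_eeg import classify


def gaussian_table(n_per_class, delta, seed=0, d=2, labels=("A", "C")):
    rng = np.random.default_rng(seed)
    rows = []
    for label, mu in zip(labels, (0.0, delta)):
        X = rng.standard_normal((n_per_class, d)) + mu
        for x in X:
            rows.append({"cohort": label,
                         **{c: v for c, v in zip(("alpha", "sigma"), x)}})
    return pd.DataFrame(rows)


class TestLdaFit:
    def test_1d_midpoint_boundary(self):
        """Equal-variance 1-D classes with means 0 and 2: boundary at 1."""
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.standard_normal(5000),
                            rng.standard_normal(5000) + 2.0])[:, None]
        y = ["a"] * 5000 + ["b"] * 5000
        model = classify.lda_fit(X, y, shrinkage=0.0)
        labels, score = classify.lda_predict(model, np.array([[0.9], [1.1]]))
        assert list(labels) == ["a", "b"]
        # score crosses zero near 1.0
        grid = np.linspace(0, 2, 2001)[:, None]
        _, s = classify.lda_predict(model, grid)
        boundary = grid[np.argmin(np.abs(s)), 0]
        assert abs(boundary - 1.0) < 0.05

    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((50, 2)) * 0.1,
                       rng.standard_normal((50, 2)) * 0.1 + 10.0])
        y = ["a"] * 50 + ["b"] * 50
        model = classify.lda_fit(X, y)
        pred, _ = classify.lda_predict(model, X)
        assert np.mean(pred == np.array(y)) == 1.0

    def test_no_signal_chance_level(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 2))
        y = np.array(["a", "b"] * 200)  # interleaved so both splits are mixed
        model = classify.lda_fit(X[:300], y[:300])
        pred, _ = classify.lda_predict(model, X[300:])
        acc = np.mean(pred == y[300:])
        assert 0.3 <= acc <= 0.7

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="need >= 2"):
            classify.lda_fit(np.zeros((3, 2)), ["a", "a", "b"])

    def test_singular_without_shrinkage_raises(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        with pytest.raises(ValueError, match="singular"):
            classify.lda_fit(X, ["a", "a", "b", "b"], shrinkage=0.0)

    def test_matches_sklearn_oracle(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((80, 2)),
                       rng.standard_normal((120, 2)) + [1.0, 0.5]])
        y = np.array(["a"] * 80 + ["b"] * 120)
        ours = classify.lda_fit(X, y, shrinkage=0.0)
        theirs = LinearDiscriminantAnalysis().fit(X, y)
        Xt = rng.standard_normal((500, 2)) + 0.5
        ours_pred, _ = classify.lda_predict(ours, Xt)
        assert np.mean(ours_pred == theirs.predict(Xt)) > 0.995

    def test_bayes_rate_convergence(self):
        """Held-out error approaches the closed-form Bayes rate Phi(-d/2)."""
        delta = 1.5
        table = gaussian_table(10_000, delta, seed=4)
        X = table[["alpha", "sigma"]].to_numpy()
        y = table["cohort"].to_numpy()
        model = classify.lda_fit(X[::2], y[::2], shrinkage=0.0)
        pred, _ = classify.lda_predict(model, X[1::2])
        err = np.mean(pred != y[1::2])
        bayes = norm.cdf(-delta * np.sqrt(2) / 2)  # d-dim shift (delta, delta)
        assert abs(err - bayes) < 0.02


class TestLdaPredict:
    def test_class_mean_classified_to_class(self):
        model = classify.lda_fit(
            np.array([[0.0], [0.2], [3.0], [3.2]]), ["a", "a", "b", "b"])
        pred, _ = classify.lda_predict(model, np.array([[0.1], [3.1]]))
        assert list(pred) == ["a", "b"]

    def test_tie_goes_to_first_label(self):
        model = classify.lda_fit(
            np.array([[-1.0], [-1.2], [1.0], [1.2]]), ["b", "b", "a", "a"])
        pred, score = classify.lda_predict(model, np.array([[-0.05 + 0.05]]))
        assert score[0] == pytest.approx(0.0, abs=1e-9)
        assert pred[0] == "a"  # lexicographically first

    def test_prior_shift_moves_boundary(self):
        rng = np.random.default_rng(5)
        Xa = rng.standard_normal(200)[:, None]
        Xb = rng.standard_normal(200)[:, None] + 2.0
        balanced = classify.lda_fit(np.vstack([Xa, Xb]),
                                    ["a"] * 200 + ["b"] * 200, shrinkage=0.0)
        skewed = classify.lda_fit(np.vstack([Xa, Xb[:50]]),
                                  ["a"] * 200 + ["b"] * 50, shrinkage=0.0)

        def boundary(model):
            grid = np.linspace(-1, 3, 4001)[:, None]
            _, s = classify.lda_predict(model, grid)
            return grid[np.argmin(np.abs(s)), 0]

        # fewer "b" samples -> boundary moves toward the "b" mean
        assert boundary(skewed) > boundary(balanced)

    def test_dimension_mismatch_raises(self):
        model = classify.lda_fit(np.zeros((4, 2)) + np.arange(4)[:, None],
                                 ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="dimension"):
            classify.lda_predict(model, np.zeros((1, 3)))


class TestConfusionMetrics:
    def test_hand_arithmetic(self):
        y_true = ["p"] * 4 + ["n"] * 4
        y_pred = ["p", "p", "p", "n", "p", "p", "n", "n"]
        m = classify.confusion_metrics(y_true, y_pred, "p")
        assert m["counts"] == classify.ConfusionCounts(TP=3, FP=2, TN=2, FN=1)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.5)
        assert m["ppv"] == pytest.approx(0.6)
        assert m["npv"] == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        m = classify.confusion_metrics(["p", "n"], ["p", "n"], "p")
        assert all(m[k] == 1.0 for k in
                   ("sensitivity", "specificity", "ppv", "npv"))

    def test_undefined_metric_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = classify.confusion_metrics(["n", "n"], ["n", "n"], "p")
        assert np.isnan(m["sensitivity"])

    def test_metric_identities(self):
        rng = np.random.default_rng(6)
        y_true = rng.choice(["p", "n"], 200)
        y_pred = rng.choice(["p", "n"], 200)
        m = classify.confusion_metrics(y_true, y_pred, "p")
        c = m["counts"]
        fnr = c.FN / c.P
        fpr = c.FP / c.N
        assert m["sensitivity"] + fnr == pytest.approx(1.0)
        assert m["specificity"] + fpr == pytest.approx(1.0)

    def test_nonbinary_labels_raise(self):
        with pytest.raises(ValueError, match="binary"):
            classify.confusion_metrics(["a", "b", "c"], ["a", "b", "c"], "a")


class TestStratifiedSplit:
    def test_cohort_proportions_40_40_40(self):
        table = pd.DataFrame({"cohort": ["A"] * 40 + ["B"] * 40 + ["C"] * 40,
                              "alpha": 0.0, "sigma": 0.0})
        train, test = classify.stratified_split(table, 0.3, seed=0)
        assert test["cohort"].value_counts().to_dict() == {
            "A": 12, "B": 12, "C": 12}

    def test_partition_and_determinism(self):
        table = gaussian_table(25, 1.0, seed=7)
        tr1, te1 = classify.stratified_split(table, 0.3, seed=3)
        tr2, te2 = classify.stratified_split(table, 0.3, seed=3)
        pd.testing.assert_frame_equal(tr1, tr2)
        assert set(tr1.index) | set(te1.index) == set(table.index)
        assert set(tr1.index) & set(te1.index) == set()

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError):
            classify.stratified_split(gaussian_table(5, 0.0), 1.5)


class TestKfoldCv:
    def test_folds_partition_training_data(self):
        table = gaussian_table(30, 1.0, seed=8)
        X = table[["alpha", "sigma"]].to_numpy()
        y = (table["cohort"] == "C").map({True: "pos", False: "neg"})
        report = classify.kfold_cv(X, list(y), "pos", n_folds=6, seed=0)
        total = sum(c.total for c in report.per_fold_counts)
        assert total == len(table)
        assert report.fold_size == pytest.approx(10.0)

    def test_perfect_separation_means_one_stds_zero(self):
        table = gaussian_table(30, 50.0, seed=9)
        X = table[["alpha", "sigma"]].to_numpy()
        y = ["pos" if c == "C" else "neg" for c in table["cohort"]]
        report = classify.kfold_cv(X, y, "pos", n_folds=5, seed=0)
        for k in ("sensitivity", "specificity", "ppv"):
            assert report.metrics_mean[k] == 1.0
            assert report.metrics_std[k] == 0.0

    def test_null_features_near_chance(self):
        """No class signal: mean CV sensitivity sits in the chance band."""
        table = gaussian_table(200, 0.0, seed=10)
        X = table[["alpha", "sigma"]].to_numpy()
        y = ["pos" if c == "C" else "neg" for c in table["cohort"]]
        report = classify.kfold_cv(X, y, "pos", n_folds=6, seed=1)
        assert abs(report.metrics_mean["sensitivity"] - 0.5) < 0.15

    def test_too_many_folds_raises(self):
        table = gaussian_table(4, 1.0)
        X = table[["alpha", "sigma"]].to_numpy()
        y = ["pos" if c == "C" else "neg" for c in table["cohort"]]
        with pytest.raises(ValueError, match="folds"):
            classify.kfold_cv(X, y, "pos", n_folds=8)


class TestRunComparisons:
    def test_five_tasks_five_rows(self):
        table = pd.concat([
            gaussian_table(20, 0.5, seed=11, labels=("A", "B")),
            gaussian_table(20, 1.0, seed=12, labels=("C", "C"))[:20],
        ], ignore_index=True)
        cv, test, raw = classify.run_comparisons(table, seed=0)
        assert len(cv) == 5 and len(test) == 5
        assert set(raw) == {t.name for t in classify.STANDARD_TASKS}

    def test_missing_cohort_raises(self):
        table = gaussian_table(10, 1.0, labels=("A", "B"))
        with pytest.raises(ValueError, match="needs cohorts"):
            classify.run_comparisons(table)

    def test_no_leakage_label_permutation(self):
        """Shuffling training labels never lifts test metrics above chance."""
        rng = np.random.default_rng(13)
        table = pd.concat([
            gaussian_table(100, 2.0, seed=14, labels=("A", "C")),
            gaussian_table(50, 2.0, seed=15, labels=("B", "B"))[:100],
        ], ignore_index=True)
        task = classify.ComparisonTask("A vs C", {"A": "pos", "C": "neg"})
        sub = task.apply(table)
        train, test = classify.stratified_split(sub, 0.3, seed=0)
        cols = ["alpha", "sigma"]
        X_tr, y_tr = train[cols].to_numpy(), train["y"].to_numpy()
        X_te, y_te = test[cols].to_numpy(), test["y"].to_numpy()
        # genuine labels separate well
        model = classify.lda_fit(X_tr, y_tr)
        pred, _ = classify.lda_predict(model, X_te)
        m = classify.confusion_metrics(y_te, pred, "pos")
        genuine_bal = (m["sensitivity"] + m["specificity"]) / 2
        assert genuine_bal > 0.9
        # A permuted-label model carries no cluster-to-label information, so
        # over repetitions its balanced accuracy is symmetric around chance
        # (individual repetitions can land high or low by the sign of a
        # random boundary through well-separated clusters).
        bals = []
        for rep in range(20):
            y_shuf = rng.permutation(y_tr)
            model = classify.lda_fit(X_tr, y_shuf)
            pred, _ = classify.lda_predict(model, X_te)
            m = classify.confusion_metrics(y_te, pred, "pos")
            bals.append((m["sensitivity"] + m["specificity"]) / 2)
        assert abs(np.mean(bals) - 0.5) < 0.35
        assert np.mean(bals) < genuine_bal - 0.2
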