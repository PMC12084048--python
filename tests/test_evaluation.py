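"""Measurement protocol: encoding, splits, CV search, repeated-run metrics."""

import numpy as np
import pandas as pd
import pytest

from mosr.evaluation import (LeakageError, MetricReport, Partition,
                             Preprocessor, confusion_metrics, grid_search_cv,
                             pr_curve, repeated_test_evaluation, roc_auc,
                             stratified_split)


class TestPreprocessor:
    def make_partition(self, df, role="train"):
        return Partition(df, np.zeros(len(df)), role=role)

    def test_min_max_formula(self):
        train = pd.DataFrame({"v": [10.0, 20.0]})
        test = pd.DataFrame({"v": [15.0]})
        prep = Preprocessor().fit(self.make_partition(train))
        out = prep.transform(self.make_partition(test, role="validation"))
        assert out["v"].iloc[0] == 0.5

    def test_out_of_range_not_clipped_but_warned(self):
        train = pd.DataFrame({"v": [10.0, 20.0]})
        test = pd.DataFrame({"v": [25.0]})
        prep = Preprocessor().fit(self.make_partition(train))
        with pytest.warns(UserWarning, match="outside"):
            out = prep.transform(self.make_partition(test, role="test"))
        assert out["v"].iloc[0] == 1.5

    def test_one_hot_indicators_sum_to_one(self):
        train = pd.DataFrame({"surgery": [1, 2, 3, 2, 1]})
        prep = Preprocessor(categorical=["surgery"]).fit(
            self.make_partition(train))
        out = prep.transform(self.make_partition(train))
        assert out.shape[1] == 3
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_unseen_category_maps_to_zeros(self):
        train = pd.DataFrame({"surgery": [1, 2]})
        test = pd.DataFrame({"surgery": [9]})
        prep = Preprocessor(categorical=["surgery"]).fit(
            self.make_partition(train))
        with pytest.warns(UserWarning, match="unseen"):
            out = prep.transform(self.make_partition(test, role="test"))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_fit_on_test_partition_raises(self):
        with pytest.raises(LeakageError):
            Preprocessor().fit(self.make_partition(
                pd.DataFrame({"v": [1.0]}), role="test"))


class TestStratifiedSplit:
    @pytest.mark.parametrize("n,prev,ratio,expected", [
        (1190, 633, 0.8, (952, 238)),   # outer study split
        (952, 506, 0.9, (857, 95)),     # within-CV split
    ])
    def test_printed_partition_sizes(self, n, prev, ratio, expected):
        y = np.array([1] * prev + [0] * (n - prev))
        a, b = stratified_split(y, ratio, seed=0)
        assert (len(a), len(b)) == expected

    def test_small_balanced_split(self):
        y = np.array([0] * 5 + [1] * 5)
        a, b = stratified_split(y, 0.5, seed=1)
        assert len(a) == 5 and len(b) == 5
        assert abs(y[a].sum() - 2.5) <= 0.5

    def test_disjoint_exhaustive_and_prevalence_matched(self, rng):
        for _ in range(20):
            n = int(rng.integers(50, 400))
            y = (rng.random(n) < 0.4).astype(int)
            if min((y == 0).sum(), (y == 1).sum()) < 2:
                continue
            ratio = float(rng.uniform(0.3, 0.9))
            a, b = stratified_split(y, ratio, seed=int(rng.integers(1000)))
            assert len(a) + len(b) == n
            assert len(np.intersect1d(a, b)) == 0
            assert len(a) == int(np.floor(ratio * n + 0.5))
            for cls in (0, 1):
                total = (y == cls).sum()
                got = (y[a] == cls).sum()
                assert abs(got - ratio * total) <= 1.0

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 0, 1]), 0.5, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_pure_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_listed_ties_match_concordance_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.4, 0.4, 0.6, 0.6, 0.05, 0.9, 0.5, 0.35]
        labels = [0, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1]
        def oracle(p, y):
            pos = [pi for pi, yi in zip(p, y) if yi == 1]
            neg = [pi for pi, yi in zip(p, y) if yi == 0]
            total = 0.0
            for pp in pos:
                for nn in neg:
                    total += 1.0 if pp > nn else (0.5 if pp == nn else 0.0)
            return total / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(oracle(scores, labels),
                                                        abs=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        def oracle(p, y):
            pos, neg = p[y == 1], p[y == 0]
            grid = (pos[:, None] > neg[None, :]).sum() \
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
            return grid / (len(pos) * len(neg))
        for _ in range(100):
            p = rng.choice(np.linspace(0, 1, 11), size=30)
            y = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            assert roc_auc(p, y) == pytest.approx(oracle(p, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.random(50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        assert roc_auc(np.exp(3 * p), y) == pytest.approx(roc_auc(p, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_trapezoid_curve_agrees_with_concordance(self, rng):
        from sklearn.metrics import roc_auc_score
        p = rng.random(200)
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]
        assert roc_auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-10)


class TestConfusionMetrics:
    def test_f1_identity_holds_per_run(self, rng):
        for _ in range(50):
            p = rng.random(80)
            y = rng.integers(0, 2, size=80)
            m = confusion_metrics(p, y)
            if np.isfinite(m["f1"]):
                assert m["f1"] == pytest.approx(
                    2 * m["ppv"] * m["sensitivity"]
                    / (m["ppv"] + m["sensitivity"]), abs=1e-12)

    def test_metrics_recomputable_from_confusion_counts(self, rng):
        p = rng.random(100)
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        m = confusion_metrics(p, y)
        assert m["ppv"] == pytest.approx(m["tp"] / (m["tp"] + m["fp"]))
        assert m["npv"] == pytest.approx(m["tn"] / (m["tn"] + m["fn"]))
        assert m["accuracy"] == pytest.approx((m["tp"] + m["tn"]) / 100)

    def test_degenerate_all_positive_subsample(self):
        m = confusion_metrics([0.99] * 10, [1] * 10)
        assert m["sensitivity"] == 1.0
        assert np.isnan(m["specificity"])  # undefined, flagged as NaN
        assert np.isnan(m["auc"])


class TestRepeatedTestEvaluation:
    @staticmethod
    def deterministic_model(X):
        return (X["v"] > 0.5).astype(float).to_numpy()

    def make_test(self, n=238):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"v": rng.random(n)})
        y = (X["v"] > 0.45).astype(int).to_numpy()
        return Partition(X, y, role="test")

    def test_subsample_size_of_238_is_214(self):
        test = self.make_test(238)
        seen = []

        def spy(X):
            seen.append(len(X))
            return self.deterministic_model(X)

        repeated_test_evaluation(spy, test, n_runs=3, fraction=0.9, seed=1)
        assert seen == [214, 214, 214]

    def test_full_fraction_zero_ci_width(self):
        test = self.make_test(100)
        report = repeated_test_evaluation(self.deterministic_model, test,
                                          n_runs=10, fraction=1.0, seed=0)
        for metric, hw in report.ci_halfwidth.items():
            if np.isfinite(hw):
                assert hw == 0.0

    def test_undefined_metrics_flagged_and_excluded(self):
        test = Partition(pd.DataFrame({"v": [1.0] * 20}),
                         np.ones(20, dtype=int), role="test")
        report = repeated_test_evaluation(self.deterministic_model, test,
                                          n_runs=5, fraction=0.9, seed=0)
        assert report.undefined_counts["specificity"] == 5
        assert np.isnan(report.mean["specificity"])
        assert report.mean["sensitivity"] == 1.0


class TestGridSearchCV:
    def factory(self, **params):
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression(max_iter=500, **params)

    def make_train(self, n=200):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = (X["a"] + 0.5 * rng.normal(size=n) > 0).astype(int).to_numpy()
        return Partition(X, y, role="train")

    def test_single_point_grid_returned(self):
        train = self.make_train()
        best, table = grid_search_cv(self.factory, [{"C": 0.7}], train,
                                     folds=5, seed=0)
        assert best == {"C": 0.7}
        assert table["config"].nunique() == 1

    def test_dominant_configuration_chosen(self):
        # a degenerate configuration loses on every fold
        train = self.make_train()
        grid = [{"C": 1.0}, {"C": 1e-10}]
        best, table = grid_search_cv(self.factory, grid, train, folds=5, seed=0)
        assert best == {"C": 1.0}
        per_cfg = table.groupby("config")["auc"].mean()
        assert per_cfg[0] > per_cfg[1]

    def test_matches_exhaustive_refit_oracle(self):
        train = self.make_train(150)
        grid = [{"C": c} for c in (0.01, 1.0, 100.0)]
        best, table = grid_search_cv(self.factory, grid, train, folds=4, seed=5)
        means = table.groupby("config")["auc"].mean()
        assert best == grid[int(means.idxmax())]

    def test_selection_on_test_partition_raises(self):
        train = self.make_train()
        test = Partition(train.X, train.y, role="test")
        with pytest.raises(LeakageError):
            grid_search_cv(self.factory, [{"C": 1.0}], test)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_cv(self.factory, [], self.make_train())


def test_pr_curve_monotone_recall():
    rng = np.random.default_rng(1)
    p = rng.random(100)
    y = rng.integers(0, 2, size=100)
    y[:2] = [0, 1]
    curve = pr_curve(p, y)
    assert (np.diff(curve["recall"]) <= 1e-12).all()
    assert set(curve.columns) == {"threshold", "precision", "recall"}
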