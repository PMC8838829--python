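import numpy as np
import pandas as pd
import pytest

from filletbend.errors import DegenerateFitError, IncompleteGridError
from filletbend.stats_eval import (
    METRIC_NAMES,
    MODEL_NAMES,
    aggregate_report,
    binary_metrics,
    fit_predict_1d,
    group_statistics,
    load_reference_group_stats,
    load_reference_linespeed_scores,
    load_reference_scores_by_classifier,
    load_reference_svm_scores,
    repeated_cv,
    round3,
)


class TestBinaryMetrics:
    def test_perfect_prediction(self):
        m = binary_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert m == {"OACC": 1.0, "BACC": 1.0, "F1": 1.0, "MCC": 1.0}

    def test_all_positive_on_two_to_one_set(self):
        y_true = [1, 1, 1, 1, 0, 0]
        y_pred = [1, 1, 1, 1, 1, 1]
        m = binary_metrics(y_true, y_pred)
        assert m["OACC"] == pytest.approx(2 / 3)
        assert m["BACC"] == pytest.approx(0.5)
        assert m["MCC"] == 0.0  # zero-denominator convention

    def test_inverted_prediction_has_mcc_minus_one(self):
        m = binary_metrics([0, 1, 0, 1], [1, 0, 1, 0])
        assert m["MCC"] == -1.0
        assert m["OACC"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([0, 1], [0, 1, 1])


class TestClassifiers:
    def test_all_models_separate_disjoint_classes(self):
        x = np.r_[np.arange(10.0), np.arange(100.0, 110.0)]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        for model in MODEL_NAMES:
            pred = fit_predict_1d(model, (x, y), x)
            assert binary_metrics(y, pred)["OACC"] == 1.0

    def test_lda_threshold_near_midpoint_of_means(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0.0, 1.0, 400), rng.normal(6.0, 1.0, 400)]
        y = np.r_[np.zeros(400, int), np.ones(400, int)]
        mid = 0.5 * (x[:400].mean() + x[400:].mean())
        grid = np.linspace(mid - 2, mid + 2, 2001)
        pred = fit_predict_1d("LDA", (x, y), grid)
        boundary = grid[np.argmax(pred == 1)]
        assert boundary == pytest.approx(mid, abs=0.1)

    def test_qda_handles_nested_variances_better_than_lda(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(0.0, 0.5, 300), rng.normal(0.0, 6.0, 300)]
        y = np.r_[np.zeros(300, int), np.ones(300, int)]
        acc = {
            m: binary_metrics(y, fit_predict_1d(m, (x, y), x))["OACC"]
            for m in ("LDA", "QDA")
        }
        assert acc["QDA"] > acc["LDA"] + 0.1

    def test_single_class_training_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_predict_1d("LDA", ([1.0, 2.0], [1, 1]), [1.5])

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            fit_predict_1d("MLP", ([1.0, 2.0], [0, 1]), [1.5])


class TestRepeatedCV:
    def test_separable_data_scores_one(self):
        x = np.r_[np.arange(20.0), np.arange(100.0, 120.0)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        scores = repeated_cv(x, y, "SVM", seed=0)
        assert set(scores) == set(METRIC_NAMES)
        assert all(v == 1.0 for v in scores.values())

    def test_null_feature_has_near_zero_mcc(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        scores = repeated_cv(x, y, "LDA", seed=7)
        assert abs(scores["MCC"]) <= 0.15

    def test_duplicated_dataset_leaves_scores_similar(self):
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(0, 1, 30), rng.normal(2.5, 1, 30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        base = repeated_cv(x, y, "LDA", seed=3)
        doubled = repeated_cv(np.r_[x, x], np.r_[y, y], "LDA", seed=3)
        for m in METRIC_NAMES:
            assert doubled[m] == pytest.approx(base[m], abs=0.1)

    def test_monotone_power_with_class_separation(self):
        rng = np.random.default_rng(11)
        n = 60
        noise = rng.normal(size=2 * n)
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        prev = {m: -1.0 for m in METRIC_NAMES}
        for delta in (0.3, 1.5, 4.0):
            x = noise + delta * y
            scores = repeated_cv(x, y, "LDA", seed=2)
            for m in METRIC_NAMES:
                assert scores[m] >= prev[m] - 0.02
            prev = scores

    def test_fold_level_option_and_validation(self):
        x = np.r_[np.arange(10.0), np.arange(50.0, 60.0)]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        assert repeated_cv(x, y, "KNN", level="fold")["OACC"] == 1.0
        with pytest.raises(ValueError):
            repeated_cv(x, y, "KNN", level="bogus")
        with pytest.raises(DegenerateFitError):
            repeated_cv(x, np.zeros_like(y), "KNN")
        with pytest.raises(ValueError):
            repeated_cv(x[:4], [0, 0, 1, 1], "KNN", folds=5)


class TestGroupStatistics:
    def _table(self, values, labels):
        return pd.DataFrame({"NMDM": values, "label": labels})

    def test_feature_equal_to_score_has_rho_one(self):
        labels = [0] * 5 + [1] * 5 + [2] * 5
        res = group_statistics(self._table([float(v) for v in labels], labels))
        assert res.per_feature["NMDM"].spearman_rho == pytest.approx(1.0)

    def test_six_point_spearman_matches_rank_oracle(self):
        values = [3.0, 1.0, 4.0, 9.0, 2.0, 6.0]
        labels = [0, 0, 1, 1, 2, 2]
        res = group_statistics(self._table(values, labels))

        def ranks(a):
            a = np.asarray(a, float)
            order = a.argsort(kind="stable")
            r = np.empty(len(a))
            r[order] = np.arange(1, len(a) + 1)
            for v in np.unique(a):
                r[a == v] = r[a == v].mean()
            return r

        rx, ry = ranks(values), ranks(labels)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.per_feature["NMDM"].spearman_rho == pytest.approx(oracle, abs=1e-12)

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        vals = np.r_[rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10), rng.normal(10, 0.1, 10)]
        labels = [0] * 10 + [1] * 10 + [2] * 10
        s = group_statistics(self._table(vals, labels)).per_feature["NMDM"]
        letters = s.tukey_letters
        assert len({letters[0], letters[1], letters[2]}) == 3
        assert letters[2] == "a"  # highest mean gets the first letter
        assert s.anova_p < 1e-6

    def test_null_groups_rarely_separate(self):
        rng = np.random.default_rng(99)
        labels = [0] * 10 + [1] * 10 + [2] * 10
        no_separation = 0
        for _ in range(100):
            vals = rng.normal(size=30)
            s = group_statistics(self._table(vals, labels)).per_feature["NMDM"]
            common = set(s.tukey_letters[0]) & set(s.tukey_letters[1]) & set(s.tukey_letters[2])
            no_separation += bool(common)
        assert no_separation >= 90

    def test_letters_consistent_with_pairwise_pvalues(self, cohort_run):
        res = group_statistics(cohort_run["features"])
        for s in res.per_feature.values():
            for (g1, g2), p in s.tukey_pvalues.items():
                shares = bool(set(s.tukey_letters[g1]) & set(s.tukey_letters[g2]))
                assert shares == (p > 0.05)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            group_statistics(self._table([1.0, 2.0, 3.0], [0, 0, 0]))
        with pytest.raises(ValueError):
            group_statistics(self._table([1.0, 2.0, 3.0], [0, 1, 1]))
        with pytest.raises(ValueError):
            group_statistics(pd.DataFrame({"NMDM": [1.0, 2.0]}))


class TestAggregation:
    def test_round3_is_half_up(self):
        assert round3(0.9735) == 0.974
        assert round3(0.0005) == 0.001
        assert round3(0.8315) == 0.832

    def test_single_cell_grid(self):
        rep = aggregate_report(pd.DataFrame({"m": [0.5]}, index=["f"]))
        assert rep.grand_mean == 0.5
        assert rep.row_means["f"] == 0.5

    def test_row_mean_of_reference_top_feature(self):
        svm = load_reference_svm_scores()
        rep = aggregate_report(svm)
        assert round3(rep.row_means["NMDM"]) == 0.974

    def test_missing_cell_rejected(self):
        cells = pd.DataFrame({"A": [0.5, np.nan]}, index=["f", "g"])
        with pytest.raises(IncompleteGridError):
            aggregate_report(cells)

    def test_unknown_block_row_rejected(self):
        cells = pd.DataFrame({"A": [0.5]}, index=["f"])
        with pytest.raises(IncompleteGridError):
            aggregate_report(cells, row_blocks={"blk": ["missing"]})

    def test_rendered_table_has_marginals(self):
        cells, blocks = load_reference_scores_by_classifier()
        rendered = aggregate_report(cells, row_blocks=blocks).rendered()
        assert "MEAN" in rendered.columns
        assert "Average Total" in rendered.index
        assert any(i.startswith("Avg. subtotal") for i in rendered.index)


class TestReferenceTables:
    def test_classifier_table_shape(self):
        cells, blocks = load_reference_scores_by_classifier()
        assert list(cells.columns) == list(MODEL_NAMES)
        assert len(cells) == 10
        assert sorted(len(v) for v in blocks.values()) == [4, 6]

    def test_linespeed_table_is_complete_grid(self):
        long = load_reference_linespeed_scores()
        assert set(long["fpm"]) == {10, 50, 100}
        assert set(long["metric"]) == set(METRIC_NAMES)
        assert len(long) == 3 * 4 * 3

    def test_group_stats_table_matches_feature_names(self):
        ref = load_reference_group_stats()
        assert {"NMDM", "MDM", "MBE"} <= set(ref.index)
        assert ref["spearman_rho"].between(-1, 1).all()
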