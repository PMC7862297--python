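"""SVM classification, confusion matrices, metric reports, session votes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qeegpain as qp
from qeegpain.errors import FoldError, LabelError, StatsError
from qeegpain.pain import CLASS_ORDER

from conftest import make_feature_dataset


def blob_features(rng, n, center_dim):
    """35-dim features: standard noise plus a +4 shift on one dimension."""
    x = rng.standard_normal((n, 35))
    x[:, center_dim] += 4.0
    return x


def four_blob_dataset(n_per_class=24, seed=0, windows_per_session=4):
    rng = np.random.default_rng(seed)
    features, quartiles = [], []
    for i, q in enumerate(CLASS_ORDER):
        features.append(blob_features(rng, n_per_class, i))
        quartiles += [q] * n_per_class
    return make_feature_dataset(
        np.vstack(features), quartiles, windows_per_session=windows_per_session
    )


class TestFitSvm:
    def test_separable_toy_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((20, 2)), rng.standard_normal((20, 2)) + 8.0])
        y = np.array(["none"] * 20 + ["severe"] * 20, dtype=object)
        model = qp.fit_svm(X, y, qp.ClassifierConfig(inner_folds=3))
        assert (model.predict(X) == y).all()

    def test_determinism_on_probe_grid(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.standard_normal((30, 3)), rng.standard_normal((30, 3)) + 2.0])
        y = np.array(["mild"] * 30 + ["moderate"] * 30, dtype=object)
        cfg = qp.ClassifierConfig(seed=7, inner_folds=3)
        probe = np.random.default_rng(3).standard_normal((50, 3)) * 3.0
        pred_a = qp.fit_svm(X, y, cfg).predict(probe)
        pred_b = qp.fit_svm(X, y, cfg).predict(probe)
        np.testing.assert_array_equal(pred_a, pred_b)

    def test_hyperparameters_reproducible(self):
        dataset = four_blob_dataset()
        cfg = qp.ClassifierConfig(seed=5, inner_folds=3)
        a = qp.fit_svm(dataset, config=cfg).best_params_
        b = qp.fit_svm(dataset, config=cfg).best_params_
        assert a == b

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(StatsError):
            qp.fit_svm(X, np.array(["none"] * 10, dtype=object))


class TestCrossValidatedPredictions:
    def test_every_window_predicted_once(self):
        dataset = four_blob_dataset()
        cfg = qp.ClassifierConfig(n_folds=4, inner_folds=3, gamma_grid=("scale",))
        predictions = qp.cross_validated_predictions(dataset, cfg)
        assert len(predictions) == len(dataset)
        assert predictions["prediction"].isin(CLASS_ORDER).all()

    def test_session_scheme_never_splits_sessions(self):
        """Fold partition check: each session's windows share one test fold."""
        from sklearn.model_selection import LeaveOneGroupOut

        dataset = four_blob_dataset()
        groups = dataset.session_keys
        covered = np.zeros(len(dataset), dtype=int)
        for _, test_idx in LeaveOneGroupOut().split(dataset.features, groups=groups):
            assert len(set(groups[test_idx])) == 1
            covered[test_idx] += 1
        assert (covered == 1).all()

    def test_leave_one_out_matches_refit_oracle(self):
        """12 windows, one session each: LOO equals brute-force refit-per-window."""
        rng = np.random.default_rng(4)
        features = np.vstack(
            [blob_features(rng, 6, 0), blob_features(rng, 6, 1)]
        )
        dataset = make_feature_dataset(features, ["none"] * 6 + ["severe"] * 6)
        cfg = qp.ClassifierConfig(
            cv_scheme="session",
            cost_grid=(1.0,),
            gamma_grid=("scale",),
            inner_folds=2,
            seed=0,
        )
        predictions = qp.cross_validated_predictions(dataset, cfg)["prediction"].to_numpy()
        oracle = []
        for i in range(len(dataset)):
            rest = np.delete(np.arange(len(dataset)), i)
            model = qp.fit_svm(
                dataset.features[rest], dataset.labels[rest], cfg
            )
            oracle.append(model.predict(dataset.features[[i]])[0])
        np.testing.assert_array_equal(predictions, np.array(oracle, dtype=object))

    def test_infeasible_stratified_layout_rejected(self):
        rng = np.random.default_rng(5)
        dataset = make_feature_dataset(
            rng.standard_normal((12, 35)), ["none"] * 9 + ["severe"] * 3
        )
        with pytest.raises(FoldError):
            qp.cross_validated_predictions(dataset, qp.ClassifierConfig(n_folds=10))


TABLE_MATRIX = np.array(
    [[136, 9, 11, 4], [9, 53, 12, 6], [11, 10, 126, 3], [6, 4, 9, 51]]
)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["none", "mild", "moderate", "severe", "mild"]
        matrix = qp.confusion_matrix(labels, labels)
        assert np.trace(matrix.counts) == 5
        assert matrix.counts.sum() == 5

    def test_empty_lists_give_zero_matrix(self):
        matrix = qp.confusion_matrix([], [])
        assert matrix.counts.shape == (4, 4) and matrix.total == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(LabelError):
            qp.confusion_matrix(["none"], ["none", "mild"])

    def test_row_sums_are_truth_counts(self):
        rng = np.random.default_rng(6)
        truth = list(rng.choice(CLASS_ORDER, size=100))
        predicted = list(rng.choice(CLASS_ORDER, size=100))
        matrix = qp.confusion_matrix(truth, predicted)
        for i, label in enumerate(CLASS_ORDER):
            assert matrix.counts[i].sum() == truth.count(label)


class TestReportMetrics:
    def test_identity_matrix_all_metrics_one(self):
        report = qp.report_metrics(qp.ConfusionMatrix(np.diag([5, 5, 5, 5])))
        assert report.overall_accuracy == 1.0
        assert all(v == 1.0 for v in report.precision.values())
        assert all(v == 1.0 for v in report.f1.values())

    def test_undefined_precision_for_never_predicted_class(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 5
        counts[1, 0] = 5  # 'mild' rows all predicted 'none'
        report = qp.report_metrics(qp.ConfusionMatrix(counts))
        assert report.precision["mild"] is None
        assert report.recall["mild"] == 0.0
        assert report.f1["mild"] is None

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(LabelError):
            qp.report_metrics(qp.ConfusionMatrix(np.zeros((4, 4), dtype=int)))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=50), min_size=16, max_size=16
        ).filter(lambda counts: sum(counts) > 0)
    )
    def test_accuracy_is_weighted_mean_of_recalls(self, flat_counts):
        """accuracy == sum over classes of (row weight) * recall."""
        counts = np.array(flat_counts).reshape(4, 4)
        report = qp.report_metrics(qp.ConfusionMatrix(counts))
        weighted = 0.0
        for i, label in enumerate(CLASS_ORDER):
            row = counts[i].sum()
            if row:
                weighted += (row / counts.sum()) * report.recall[label]
        assert report.overall_accuracy == pytest.approx(weighted, abs=1e-12)

    def test_f1_is_harmonic_mean(self):
        report = qp.report_metrics(qp.ConfusionMatrix(TABLE_MATRIX))
        for label in CLASS_ORDER:
            p, r = report.precision[label], report.recall[label]
            assert report.f1[label] == pytest.approx(2 * p * r / (p + r), abs=1e-12)


class TestSessionLevelPredictions:
    def make_window_predictions(self, votes_by_session):
        rows = []
        for (subject, phase, nrs, truth), votes in votes_by_session.items():
            for i, vote in enumerate(votes):
                rows.append(
                    {
                        "subject_id": subject,
                        "phase": phase,
                        "window_index": i,
                        "nrs": nrs,
                        "quartile": truth,
                        "prediction": vote,
                    }
                )
        return pd.DataFrame(rows)

    def test_unanimous_votes(self):
        table = qp.session_level_predictions(
            self.make_window_predictions(
                {("S01", "pre", 8, "severe"): ["severe"] * 10}
            )
        )
        assert table.iloc[0]["prediction"] == "severe"
        assert not table.iloc[0]["discrepancy"]

    def test_tie_breaks_toward_more_severe(self):
        votes = ["mild"] * 5 + ["moderate"] * 5
        table = qp.session_level_predictions(
            self.make_window_predictions({("S01", "pre", 2, "mild"): votes})
        )
        assert table.iloc[0]["prediction"] == "moderate"
        assert bool(table.iloc[0]["discrepancy"])

    def test_majority_wins(self):
        votes = ["none"] * 6 + ["severe"] * 4
        table = qp.session_level_predictions(
            self.make_window_predictions({("S01", "post", 0, "none"): votes})
        )
        assert table.iloc[0]["prediction"] == "none"

    def test_missing_windows_rejected(self):
        predictions = self.make_window_predictions(
            {("S01", "pre", 8, "severe"): ["severe"] * 7}
        )
        with pytest.raises(LabelError, match="S01"):
            qp.session_level_predictions(predictions)

    def test_default_cohort_one_row_per_session(self, default_dataset, fast_classifier_config):
        predictions = qp.cross_validated_predictions(
            default_dataset, fast_classifier_config
        )
        table = qp.session_level_predictions(predictions)
        assert len(table) == 46
        assert table["discrepancy"].equals(table["truth"] != table["prediction"])
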