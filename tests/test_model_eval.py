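import numpy as np
import pytest

import stroketex as st
from stroketex.preprocess import ValidationError
from stroketex.reference_tables import (REFERENCE_FOLD_COUNTS,
                                        REPORTED_FOLD_METRICS,
                                        REPORTED_SUMMARY,
                                        REPORTED_TOTAL_COUNTS)


class TestMetricsFromCounts:
    def test_reference_spot_rows(self):
        m = st.metrics_from_counts(st.ConfusionCounts(37, 21, 1, 6))
        assert (m.acc, m.ppv, m.sen, m.spe, m.dice) == \
            (89.23, 97.37, 86.05, 95.45, 0.91)
        m = st.metrics_from_counts(st.ConfusionCounts(43, 21, 1, 1))
        assert (m.acc, m.ppv, m.sen, m.spe, m.dice) == \
            (96.97, 97.73, 97.73, 95.45, 0.98)

    def test_perfect_classifier(self):
        m = st.metrics_from_counts(st.ConfusionCounts(10, 10, 0, 0))
        assert (m.acc, m.ppv, m.sen, m.spe, m.dice) == (100.0,) * 4 + (1.0,)

    @pytest.mark.parametrize("kernel", list(REFERENCE_FOLD_COUNTS))
    def test_all_reference_fold_rows_exact(self, kernel):
        for counts, reported in zip(REFERENCE_FOLD_COUNTS[kernel],
                                    REPORTED_FOLD_METRICS[kernel]):
            m = st.metrics_from_counts(st.ConfusionCounts(*counts))
            assert (m.acc, m.ppv, m.sen, m.spe, m.dice) == reported, counts

    def test_zero_denominator_marked_undefined(self):
        m = st.metrics_from_counts(st.ConfusionCounts(0, 5, 0, 0))
        assert m.ppv is None and m.sen is None
        assert m.acc == 100.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            st.ConfusionCounts(0, 0, 0, 0)

    def test_dice_harmonic_mean_identity(self):
        for counts in REFERENCE_FOLD_COUNTS["rbf"]:
            m = st.metrics_from_counts(st.ConfusionCounts(*counts))
            harm = 2 * m.ppv * m.sen / (m.ppv + m.sen) / 100
            assert abs(m.dice - harm) < 0.005


class TestAggregateFolds:
    @pytest.mark.parametrize("kernel", list(REFERENCE_FOLD_COUNTS))
    def test_reference_summaries_exact(self, kernel):
        folds = [(st.ConfusionCounts(*c), st.metrics_from_counts(st.ConfusionCounts(*c)))
                 for c in REFERENCE_FOLD_COUNTS[kernel]]
        summary, totals = st.aggregate_folds(folds)
        assert (summary.acc, summary.ppv, summary.sen, summary.spe,
                summary.dice) == REPORTED_SUMMARY[kernel]
        assert (totals.TP, totals.TN, totals.FP, totals.FN) == \
            REPORTED_TOTAL_COUNTS[kernel]

    def test_single_fold_is_its_own_summary(self):
        c = st.ConfusionCounts(40, 22, 0, 4)
        m = st.metrics_from_counts(c)
        summary, totals = st.aggregate_folds([(c, m)])
        assert summary.as_dict() == m.as_dict()
        assert vars(totals) == vars(c)

    def test_empty_folds_rejected(self):
        with pytest.raises(ValidationError):
            st.aggregate_folds([])


class TestCollapse:
    def test_majority_ref_counts_sum_to_test_size(self):
        y_true = np.array(["P"] * 6 + ["L"] * 3 + ["T"] * 3)
        y_pred = np.array(["P"] * 5 + ["L"] + ["L"] * 2 + ["T"] + ["T"] * 2 + ["P"])
        c = st.majority_ref_counts(y_true, y_pred, "P")
        assert c.total == 12
        assert c.TN == 5 and c.FP == 1  # majority correct / mislabeled
        assert c.TP == 4 and c.FN == 2  # minority exactly correct / not
        m = st.metrics_from_counts(c)
        assert m.acc == pytest.approx(100 * 9 / 12, abs=0.01)

    def test_micro_ovr_counts(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "b", "b", "b", "c", "a"]
        c = st.micro_ovr_counts(y_true, y_pred)
        assert c.TP == 4  # correct predictions
        assert c.FP == c.FN == 2
        assert c.total == 6 * 3


class TestSFS:
    def make_separable(self, seed=11, n=60, noise_cols=9):
        rng = np.random.default_rng(seed)
        labels = np.repeat(["a", "b", "c"], n // 3)
        sep = np.repeat([0.0, 10.0, 20.0], n // 3) + rng.normal(0, 0.5, n)
        X = np.column_stack([sep] + [rng.normal(0, 1, n) for _ in range(noise_cols)])
        return X, labels

    def test_perfect_feature_found(self):
        X, y = self.make_separable()
        ranked = st.rank_features(X, y)
        sel = st.sfs_select(X, y, ranked, st.KernelSpec("linear"))
        assert 0 in sel
        from stroketex.model_eval import _internal_accuracy
        assert _internal_accuracy(X, np.asarray(y), sel,
                                  st.KernelSpec("linear"), 5) == 1.0

    def test_max_features_budget(self):
        X, y = self.make_separable()
        ranked = st.rank_features(X, y)
        sel = st.sfs_select(X, y, ranked, st.KernelSpec("linear"), max_features=1)
        assert len(sel) == 1

    def test_patience_zero_is_strictly_improving_prefix(self):
        X, y = self.make_separable()
        ranked = st.rank_features(X, y)
        sel = st.sfs_select(X, y, ranked, st.KernelSpec("linear"), patience=0)
        # replay the definition: scan ranked order, keep strict improvements,
        # stop at the first non-improvement
        from stroketex.model_eval import _internal_accuracy
        kept, best = [], -np.inf
        for j in ranked.order:
            acc = _internal_accuracy(X, np.asarray(y), kept + [int(j)],
                                     st.KernelSpec("linear"), 5)
            if acc > best:
                best, kept = acc, kept + [int(j)]
            else:
                break
        assert sel == kept

    def test_empty_training_rejected(self):
        with pytest.raises((ValidationError, ValueError)):
            st.sfs_select(np.zeros((0, 3)), [], st.RankedFeatures(
                np.arange(3), np.zeros(3), np.ones(3)), st.KernelSpec("linear"))


class TestSVM:
    def test_linearly_separable_zero_errors(self):
        rng = np.random.default_rng(1)
        train = np.vstack([rng.normal(-3, 0.5, (20, 2)), rng.normal(3, 0.5, (20, 2))])
        labels = np.array(["x"] * 20 + ["y"] * 20)
        test = np.vstack([rng.normal(-3, 0.5, (5, 2)), rng.normal(3, 0.5, (5, 2))])
        pred = st.svm_fit_predict(train, labels, test, st.KernelSpec("linear"))
        assert list(pred) == ["x"] * 5 + ["y"] * 5

    def test_xor_pattern_rbf_beats_linear(self):
        rng = np.random.default_rng(3)
        n = 50
        X = rng.uniform(-1, 1, (n, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, "p", "q")
        Xt = rng.uniform(-1, 1, (40, 2))
        yt = np.where(Xt[:, 0] * Xt[:, 1] > 0, "p", "q")
        acc = {}
        for kind in ("rbf", "linear"):
            pred = st.svm_fit_predict(X, y, Xt, st.KernelSpec(kind))
            acc[kind] = (pred == yt).mean()
        assert acc["rbf"] > acc["linear"]

    def test_single_class_training_rejected(self):
        with pytest.raises(ValidationError):
            st.svm_fit_predict(np.zeros((5, 2)), ["a"] * 5, np.zeros((2, 2)),
                               st.KernelSpec("linear"))

    def test_train_accuracy_at_least_disjoint_test_on_average(self):
        rng = np.random.default_rng(17)
        deltas = []
        for s in range(10):
            X = rng.normal(0, 1, (60, 3))
            y = np.where(X[:, 0] + 0.5 * rng.normal(0, 1, 60) > 0, "u", "v")
            tr, te = np.arange(40), np.arange(40, 60)
            pred_tr = st.svm_fit_predict(X[tr], y[tr], X[tr], st.KernelSpec("rbf"))
            pred_te = st.svm_fit_predict(X[tr], y[tr], X[te], st.KernelSpec("rbf"))
            deltas.append((pred_tr == y[tr]).mean() - (pred_te == y[te]).mean())
        assert np.mean(deltas) >= 0


class TestCrossValidate:
    def test_folds_partition_index_set(self, small_phantom_features):
        X, y = small_phantom_features
        rep = st.cross_validate(X.to_numpy(), y, st.KernelSpec("linear"),
                                folds=5, seed=0, max_features=5, patience=2)
        all_test = sorted(i for fold in rep.test_indices for i in fold)
        assert all_test == list(range(len(y)))
        sizes = {len(f) for f in rep.test_indices}
        assert sizes == {9}

    def test_too_few_members_per_class_rejected(self):
        X = np.zeros((12, 3))
        y = np.repeat(["a", "b", "c"], 4)
        with pytest.raises(ValidationError, match="fold"):
            st.cross_validate(X, y, st.KernelSpec("linear"), folds=10)

    def test_well_separated_phantoms_high_accuracy(self, small_phantom_features):
        X, y = small_phantom_features
        rep = st.cross_validate(X.to_numpy(), y, st.KernelSpec("rbf"),
                                folds=5, seed=0)
        assert rep.summary.acc >= 90.0

    def test_shuffled_labels_fall_to_chance_band(self, small_phantom_features):
        X, y = small_phantom_features
        accs = []
        for s in range(3):
            sh = np.random.default_rng(s).permutation(y)
            rep = st.cross_validate(X.to_numpy(), sh, st.KernelSpec("rbf"),
                                    folds=5, seed=s, max_features=10, patience=2)
            accs.append(rep.summary.acc)
        assert 20.0 <= np.median(accs) <= 47.0
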