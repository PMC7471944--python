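import math

import numpy as np
import pytest

from mirnaloc.evaluation import (
    ConfusionCounts,
    auc_pr,
    auc_roc,
    binary_metrics,
    multilabel_eval,
    repeated_cv,
)
from mirnaloc.sequence_io import LabelTable
from mirnaloc.synthetic import SyntheticConfig, generate


def mann_whitney_auc(scores, truth):
    """Brute-force pairwise-comparison AUC oracle: wins + half ties over n1*n2."""
    scores, truth = np.asarray(scores), np.asarray(truth)
    pos, neg = scores[truth == 1], scores[truth == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def step_auc_pr(scores, truth):
    """Threshold-enumeration oracle: sum of precision x recall increment."""
    scores, truth = np.asarray(scores, dtype=float), np.asarray(truth)
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    n_pos = t.sum()
    area, prev_recall = 0.0, 0.0
    i = 0
    tp = fp = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # group equal scores
            tp += t[j]
            fp += 1 - t[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return area


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        for k in ("sensitivity", "specificity", "precision", "f1", "mcc"):
            assert m[k] == 1.0
        assert m["undefined"] == []

    def test_perfectly_wrong(self):
        m = binary_metrics(ConfusionCounts(tp=0, tn=0, fp=5, fn=5))
        assert m["mcc"] == -1.0
        assert m["f1"] == 0.0

    def test_hand_arithmetic(self):
        m = binary_metrics(ConfusionCounts(tp=1, tn=1, fp=1, fn=1))
        assert m["precision"] == 0.5
        assert m["sensitivity"] == 0.5
        assert m["f1"] == 0.5
        assert m["mcc"] == 0.0

    def test_undefined_ratios_flagged_not_zeroed(self):
        m = binary_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["precision"])
        assert "sensitivity" in m["undefined"] and "precision" in m["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_class_swap_symmetry(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            a = binary_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            b = binary_metrics(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
            assert a["sensitivity"] == pytest.approx(b["specificity"])
            assert a["specificity"] == pytest.approx(b["sensitivity"])
            assert abs(a["mcc"]) == pytest.approx(abs(b["mcc"]))


class TestAucRoc:
    def test_perfect_ranking(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_are_chance(self):
        assert auc_roc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_mann_whitney_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            truth = rng.integers(0, 2, size=n)
            if truth.sum() in (0, n):
                truth[0], truth[-1] = 0, 1
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert auc_roc(scores, truth) == pytest.approx(
                mann_whitney_auc(scores, truth), abs=1e-10
            )

    def test_invariant_under_monotone_transform(self, rng):
        truth = rng.integers(0, 2, size=30)
        truth[0], truth[-1] = 0, 1
        scores = rng.normal(size=30)
        assert auc_roc(scores, truth) == pytest.approx(
            auc_roc(np.exp(3 * scores), truth), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_roc([0.1, 0.2], [1, 1])


class TestAucPr:
    def test_perfect_ranking(self):
        assert auc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_positive_truth(self):
        assert auc_pr([0.3, 0.9, 0.1], [1, 1, 1]) == 1.0

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            truth = rng.integers(0, 2, size=n)
            if truth.sum() == 0:
                truth[0] = 1
            scores = np.round(rng.random(n), 1)
            assert auc_pr(scores, truth) == pytest.approx(
                step_auc_pr(scores, truth), abs=1e-10
            )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            auc_pr([0.1, 0.2], [0, 0])


@pytest.fixture(scope="module")
def dataset():
    seqs, labels = generate(
        SyntheticConfig(n_classes=2, seqs_per_class=40, separation=0.9, seed=9)
    )
    return seqs, labels


class TestRepeatedCv:

    def test_oracle_pipeline_gives_auc_one(self, dataset):
        seqs, labels = dataset

        def oracle(X_train, y_train, X_test, seed):
            # a stub that leaks the truth: scores equal the held-out labels
            pos = labels.positives("axon")
            y = np.array([1 if sid in pos else 0 for sid in X_test.index])
            return y.astype(float), y

        rep = repeated_cv(seqs, labels, "axon", fold_fn=oracle, repeats=3, seed=0)
        assert rep["auc_roc_mean"] == 1.0
        assert rep["auc_roc_se"] == 0.0
        assert rep["sensitivity_mean"] == 1.0

    def test_identical_repeats_have_zero_se(self, dataset):
        seqs, labels = dataset

        def stub(X_train, y_train, X_test, seed):
            rng = np.random.default_rng(0)  # same scores every call
            s = rng.random(len(X_test))
            return s, (s > 0.5).astype(int)

        # constant per-fold behaviour plus identical splits across repeats
        reps = []
        for _ in range(2):
            reps.append(repeated_cv(seqs, labels, "axon", fold_fn=stub, repeats=1, seed=4))
        assert reps[0]["auc_roc_mean"] == reps[1]["auc_roc_mean"]

    def test_leakage_free_default_never_trains_on_heldout(self, dataset):
        seqs, labels = dataset
        seen = []

        def spy(X_train, y_train, X_test, seed):
            seen.append((set(X_train.index), set(X_test.index)))
            s = np.zeros(len(X_test))
            return s, s.astype(int)

        repeated_cv(seqs, labels, "axon", fold_fn=spy, repeats=2, seed=1)
        for train_ids, test_ids in seen:
            assert not train_ids & test_ids

    def test_signal_recovery_small(self, dataset):
        seqs, labels = dataset
        rep = repeated_cv(seqs, labels, "axon", repeats=3, k=5, seed=2)
        assert rep["auc_roc_mean"] >= 0.9

    def test_too_few_positives_rejected(self, dataset):
        seqs, labels = dataset
        small = LabelTable(
            labels={s.id: (frozenset({"axon"}) if i < 3 else frozenset({"circulating"}))
                    for i, s in enumerate(seqs)},
            localizations=("axon", "circulating"),
        )
        with pytest.raises(ValueError, match="smaller k"):
            repeated_cv(seqs, small, "axon", k=5, repeats=1)


class TestMultilabelEval:
    @staticmethod
    def table():
        return LabelTable(labels={
            "s1": frozenset({"nucleus"}),
            "s2": frozenset({"nucleus", "exosome"}),
            "s3": frozenset({"axon", "cytoplasm", "exosome"}),
        })

    def test_perfect_prediction(self):
        t = self.table()
        pred = {sid: set(t[sid]) for sid in t.ids()}
        res = multilabel_eval(pred, t)
        assert res["total_correct"] == 6
        assert res["confusion"] == {1: {1: 1}, 2: {2: 1}, 3: {3: 1}}

    def test_empty_predictions(self):
        t = self.table()
        res = multilabel_eval({sid: set() for sid in t.ids()}, t)
        assert res["total_correct"] == 0
        assert res["confusion"] == {1: {0: 1}, 2: {0: 1}, 3: {0: 1}}

    def test_hand_tallied_case(self):
        t = self.table()
        pred = {
            "s1": {"nucleus", "axon"},            # 1 of 1 correct
            "s2": {"exosome"},                    # 1 of 2 correct
            "s3": {"axon", "exosome", "nucleus"}, # 2 of 3 correct
        }
        res = multilabel_eval(pred, t)
        assert res["per_localization_correct"]["nucleus"] == 1
        assert res["per_localization_correct"]["exosome"] == 2
        assert res["per_localization_correct"]["axon"] == 1
        assert res["total_correct"] == 4
        assert res["total_localizations"] == 6
        assert res["confusion"] == {1: {1: 1}, 2: {1: 1}, 3: {2: 1}}

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            multilabel_eval({"ghost": set()}, self.table())
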