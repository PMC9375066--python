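"""Invariant accuracy, confusion metrics, sweeps, LOO and k-fold CV."""

import random

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from cnerbayes import (ClassLabel, FragmentNaiveBayes, confusion_metrics,
                       generate_corpus, invariant_accuracy, kfold_cv, loo_cv,
                       threshold_sweep)
from cnerbayes.evaluation import assign_folds, write_sweep_csv
from cnerbayes.simulate import GeneratorParams
from helpers import fot_from_words, rank_auc, random_micro_corpus


class TestInvariantAccuracy:
    def test_perfect_separation(self):
        assert invariant_accuracy([0.9, 0.8], [0.1]) == 1.0

    def test_all_equal_scores_strict_zero(self):
        # strict ">" in the pairwise definition: ties never count
        assert invariant_accuracy([0.5, 0.5], [0.5]) == 0.0

    def test_pair_enumeration_example(self):
        # pairs: (.7,.5)+ (.7,.1)+ (.2,.5)- (.2,.1)+ -> 3/4
        assert invariant_accuracy([0.7, 0.2], [0.5, 0.1]) == 0.75

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            invariant_accuracy([], [0.1])

    def test_matches_rank_auc_on_tie_free_scores(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_pos, n_neg = rng.integers(2, 40, size=2)
            scores = rng.permutation(np.linspace(0, 1, n_pos + n_neg))
            pos, neg = scores[:n_pos], scores[n_pos:]
            ia = invariant_accuracy(pos, neg)
            labels = [1] * n_pos + [0] * n_neg
            assert ia == pytest.approx(
                roc_auc_score(labels, np.concatenate([pos, neg])), abs=1e-12)
            assert ia == pytest.approx(rank_auc(list(pos), list(neg)), abs=1e-12)
            # complement symmetry on tie-free data
            assert invariant_accuracy(neg, pos) == pytest.approx(1 - ia, abs=1e-12)

    def test_strict_below_midrank_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pos = rng.integers(0, 5, size=12) / 4.0
            neg = rng.integers(0, 5, size=15) / 4.0
            strict = invariant_accuracy(pos, neg)
            mid = invariant_accuracy(pos, neg, ties="midrank")
            assert strict <= mid + 1e-15
            assert mid == pytest.approx(rank_auc(list(pos), list(neg)), abs=1e-12)


class TestConfusionMetrics:
    def test_reference_counts(self):
        row = confusion_metrics(95, 12, 88, 5)
        assert row.sensitivity == pytest.approx(0.95)
        assert row.specificity == pytest.approx(0.88)
        assert row.balanced_accuracy == pytest.approx(0.915)
        assert row.precision == pytest.approx(95 / 107)

    def test_missing_precision_when_no_positives_predicted(self):
        row = confusion_metrics(0, 0, 10, 5)
        assert row.precision is None
        assert row.f1 is None
        assert row.sensitivity == 0.0

    def test_random_counts_match_formula_oracle(self):
        rng = random.Random(5)
        for _ in range(50):
            tp, fp, tn, fn = (rng.randint(0, 30) for _ in range(4))
            row = confusion_metrics(tp, fp, tn, fn)
            if tp + fn:
                assert row.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert row.specificity == pytest.approx(tn / (tn + fp))
            if row.sensitivity is not None and row.specificity is not None:
                assert row.balanced_accuracy == pytest.approx(
                    (row.sensitivity + row.specificity) / 2)


class TestThresholdSweep:
    def test_extreme_thresholds(self):
        scores = [0.1, 0.4, 0.9]
        labels = [False, True, True]
        rows = threshold_sweep(scores, labels, thresholds=[-2.0, 2.0])
        assert rows[0].sensitivity == 1.0
        assert rows[1].sensitivity == 0.0
        assert rows[1].specificity == 1.0

    def test_roc_area_from_sweep_equals_ia(self):
        rng = np.random.default_rng(3)
        scores = rng.permutation(np.linspace(-1, 1, 60))
        labels = rng.uniform(size=60) < 0.4
        if not labels.any() or labels.all():
            labels[0] = True
            labels[1] = False
        # thresholds at every distinct score trace the full ROC curve
        thresholds = np.concatenate([[-1.001], np.sort(scores)])
        rows = threshold_sweep(scores, labels, thresholds)
        fpr = np.array([1 - r.specificity for r in rows])
        tpr = np.array([r.sensitivity for r in rows])
        order = np.argsort(fpr)
        area = np.trapezoid(tpr[order], fpr[order])
        ia = invariant_accuracy(scores[labels], scores[~labels])
        assert area == pytest.approx(ia, abs=1e-12)

    def test_sweep_csv_written(self, tmp_path):
        rows = threshold_sweep([0.2, 0.8], [False, True])
        path = tmp_path / "sweep.csv"
        write_sweep_csv(rows, path, ia=1.0)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("threshold,IA,recall")
        assert len(lines) == len(rows) + 1


class TestLooCV:
    def test_disjoint_two_class_corpus_gives_perfect_ia(self):
        fots = [fot_from_words(["aaa"], ClassLabel.TRIVIAL),
                fot_from_words(["aab"], ClassLabel.TRIVIAL),
                fot_from_words(["xxy"], ClassLabel.NON_CNE),
                fot_from_words(["xyy"], ClassLabel.NON_CNE)]
        res = FragmentNaiveBayes(fots, 3).fit()
        ia = loo_cv(res)
        assert ia[ClassLabel.TRIVIAL] == 1.0
        assert ia[ClassLabel.CNE] == 1.0
        assert ia[ClassLabel.NON_CNE] == 1.0
        assert ia[ClassLabel.FORMULA] is None  # no positives

    def test_shuffled_labels_give_chance_level(self):
        rng = random.Random(99)
        fots, _ = random_micro_corpus(rng, max_fots=50)
        # random labels independent of the word content
        for fot in fots:
            fot.label = rng.choice([ClassLabel.TRIVIAL, ClassLabel.NON_CNE])
        fots[0].label = ClassLabel.TRIVIAL
        fots[1].label = ClassLabel.NON_CNE
        values = []
        for rep in range(10):
            for fot in fots:
                fot.label = rng.choice([ClassLabel.TRIVIAL, ClassLabel.NON_CNE])
            fots[0].label = ClassLabel.TRIVIAL
            fots[1].label = ClassLabel.NON_CNE
            res = FragmentNaiveBayes(fots, 2).fit()
            values.append(loo_cv(res, ties="midrank")[ClassLabel.CNE])
        assert abs(np.mean(values) - 0.5) < 0.12

    def test_matches_naive_retrain_per_sample(self):
        rng = random.Random(31)
        fots, _ = random_micro_corpus(rng, max_fots=40)
        res = FragmentNaiveBayes(fots, 2).fit()
        ia = loo_cv(res)
        # oracle: retrain without each FoT, score it, recompute IA by pairs
        from cnerbayes.ngrams import fot_descriptors
        scores, is_pos = [], []
        for i, fot in enumerate(fots):
            rest = fots[:i] + fots[i + 1:]
            retrained = FragmentNaiveBayes(rest, 2).fit()
            scores.append(retrained.b_statistic(fot_descriptors(fot, 2),
                                                ClassLabel.CNE))
            is_pos.append(fot.label is not ClassLabel.NON_CNE)
        scores = np.asarray(scores)
        is_pos = np.asarray(is_pos)
        want = invariant_accuracy(scores[is_pos], scores[~is_pos])
        assert ia[ClassLabel.CNE] == pytest.approx(want, abs=1e-12)


class TestKFold:
    def test_fold_assignment_is_a_partition(self):
        ids = [f"D{i}" for i in range(23)]
        folds = assign_folds(ids, 5, seed=3)
        flat = [d for fold in folds for d in fold]
        assert sorted(flat) == sorted(ids)
        assert len(folds) == 5

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b"], 1, seed=0)

    def test_same_seed_reproduces_report(self):
        corpus = generate_corpus(GeneratorParams(n_docs=12, seed=5))
        cv1 = kfold_cv(corpus, k=3, seed=11)
        cv2 = kfold_cv(corpus, k=3, seed=11)
        assert [f.test_doc_ids for f in cv1.folds] == \
            [f.test_doc_ids for f in cv2.folds]
        assert cv1.token_ia == cv2.token_ia
        assert cv1.entity_recall == cv2.entity_recall

    def test_k_equal_to_documents_is_leave_one_document_out(self):
        corpus = generate_corpus(GeneratorParams(n_docs=6, seed=5))
        cv = kfold_cv(corpus, k=6, seed=0)
        assert all(len(f.test_doc_ids) == 1 for f in cv.folds)
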