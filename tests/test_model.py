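"""The B-statistic estimator: counting, scoring, LOO, calibration, persistence."""

import math
import random

import numpy as np
import pytest

from cnerbayes import (ClassLabel, FragmentNaiveBayes, fot_descriptors)
from cnerbayes.calibration import BinnedCalibration, fit_calibration
from cnerbayes.model import CLASS_INDEX, CLASS_ORDER, _b_vector, load_results
from helpers import brute_force_b, fot_from_words, random_micro_corpus


def _fit(specs, n_max=5, **kwargs):
    fots = [fot_from_words(words, label) for label, words in specs]
    return FragmentNaiveBayes(fots, n_max, **kwargs).fit()


class TestCounting:
    def test_direct_counts(self):
        res = _fit([(ClassLabel.TRIVIAL, ["a"]), (ClassLabel.NON_CNE, ["b"])])
        c = res.counts
        assert c.n_total == 2
        assert c.nk[CLASS_INDEX[ClassLabel.TRIVIAL]] == 1
        assert c.nk[CLASS_INDEX[ClassLabel.CNE]] == 1
        assert c.nk[CLASS_INDEX[ClassLabel.NON_CNE]] == 1
        a = c.gram_index["A"]
        assert c.ni[a] == 1
        assert c.nik[a, CLASS_INDEX[ClassLabel.TRIVIAL]] == 1
        assert c.nik[a, CLASS_INDEX[ClassLabel.CNE]] == 1
        c.check()

    def test_repeated_grams_count_once_per_fot(self):
        # "aa" yields gram A twice as a substring but Ni must be 1
        res = _fit([(ClassLabel.TRIVIAL, ["aa"]), (ClassLabel.NON_CNE, ["b"])])
        assert res.counts.ni[res.counts.gram_index["A"]] == 1

    def test_fit_is_order_invariant(self):
        rng = random.Random(3)
        fots, _ = random_micro_corpus(rng)
        res1 = FragmentNaiveBayes(fots, 2).fit()
        shuffled = fots[:]
        rng.shuffle(shuffled)
        res2 = FragmentNaiveBayes(shuffled, 2).fit()
        assert res1.counts.n_total == res2.counts.n_total
        assert (res1.counts.nk == res2.counts.nk).all()
        for gram, idx in res1.counts.gram_index.items():
            jdx = res2.counts.gram_index[gram]
            assert res1.counts.ni[idx] == res2.counts.ni[jdx]
            assert (res1.counts.nik[idx] == res2.counts.nik[jdx]).all()

    def test_counts_match_brute_recount(self):
        rng = random.Random(11)
        fots, view = random_micro_corpus(rng, max_fots=200)
        res = FragmentNaiveBayes(fots, 2).fit()
        c = res.counts
        for gram, idx in c.gram_index.items():
            assert c.ni[idx] == sum(1 for _, grams in view if gram in grams)
            for label in (ClassLabel.TRIVIAL, ClassLabel.CNE,
                          ClassLabel.NON_CNE):
                want = sum(1 for lab, grams in view if gram in grams
                           and (lab is not ClassLabel.NON_CNE
                                if label is ClassLabel.CNE else lab is label))
                assert c.nik[idx, CLASS_INDEX[label]] == want

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            FragmentNaiveBayes([])


class TestConditional:
    def test_ratio(self):
        res = _fit([(ClassLabel.TRIVIAL, ["ab"]), (ClassLabel.TRIVIAL, ["ac"]),
                    (ClassLabel.TRIVIAL, ["ad"]), (ClassLabel.NON_CNE, ["ax"])])
        # gram A occurs in 4 FoTs, 3 of them TRIVIAL
        assert res.conditional("A", ClassLabel.TRIVIAL) == pytest.approx(0.75)

    def test_unseen_gram_is_uninformative(self):
        res = _fit([(ClassLabel.TRIVIAL, ["a"]), (ClassLabel.NON_CNE, ["b"])])
        assert res.conditional("Z", ClassLabel.TRIVIAL) is None


class TestBStatistic:
    def test_fully_uninformative_gives_zero(self):
        # P(Ck|g) = P(Ck) = 0.5 for every gram -> S0 = S = 0 -> B = 0
        res = _fit([(ClassLabel.TRIVIAL, ["ax"]), (ClassLabel.NON_CNE, ["ay"])])
        assert res.b_statistic({"A"}, ClassLabel.TRIVIAL) == pytest.approx(0.0)

    def test_pure_class_gram_gives_one(self):
        # single gram with P(Ck|g)=1 while P(Ck)=0.5: arcsin(1)=pi/2 -> B=1
        res = _fit([(ClassLabel.TRIVIAL, ["a"]), (ClassLabel.NON_CNE, ["b"])])
        assert res.b_statistic({"A"}, ClassLabel.TRIVIAL) == pytest.approx(1.0)

    def test_empty_descriptor_set_gives_zero(self):
        res = _fit([(ClassLabel.TRIVIAL, ["a"]), (ClassLabel.NON_CNE, ["b"]),
                    (ClassLabel.NON_CNE, ["c"])])
        for label in CLASS_ORDER:
            assert res.b_statistic(frozenset(), label) == pytest.approx(0.0)

    def test_oracle_equivalence_on_random_corpora(self):
        rng = random.Random(202)
        for _ in range(30):
            fots, view = random_micro_corpus(rng)
            res = FragmentNaiveBayes(fots, 2).fit()
            for _ in range(3):
                _, query = view[rng.randrange(len(view))]
                for label in (ClassLabel.TRIVIAL, ClassLabel.SYSTEMATIC,
                              ClassLabel.CNE, ClassLabel.NON_CNE):
                    got = res.b_statistic(query, label)
                    want = brute_force_b(view, query, label)
                    assert abs(got - want) < 1e-12

    def test_sum_mode_matches_oracle(self):
        rng = random.Random(77)
        fots, view = random_micro_corpus(rng)
        res = FragmentNaiveBayes(fots, 2, sum_mode="sum").fit()
        _, query = view[0]
        got = res.b_statistic(query, ClassLabel.CNE)
        assert abs(got - brute_force_b(view, query, ClassLabel.CNE, "sum")) < 1e-12

    def test_bounded_and_monotone_in_s(self):
        # Bk = (S-S0)/(1-S*S0) stays in [-1,1] and increases with S
        for s0 in np.linspace(-0.95, 0.95, 9):
            s_grid = np.linspace(-1.0, 1.0, 101)
            b = (s_grid - s0) / (1.0 - s_grid * s0)
            assert (b >= -1.0 - 1e-12).all() and (b <= 1.0 + 1e-12).all()
            assert (np.diff(b) > 0).all()

    def test_b_vector_bounds_on_random_counts(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            nk = rng.multinomial(n, np.ones(7) / 7)
            m = int(rng.integers(0, 6))
            ni = rng.integers(1, n + 1, size=m)
            nik = np.minimum(rng.integers(0, n + 1, size=(m, 7)),
                             np.minimum(ni[:, None], nk[None, :]))
            b = _b_vector(n, nk, ni, nik)
            assert np.isfinite(b).all()
            assert (b >= -1.0).all() and (b <= 1.0).all()


class TestLeaveOneOut:
    def test_two_fot_corpus_equals_single_fot_model(self):
        fots = [fot_from_words(["ab"], ClassLabel.TRIVIAL),
                fot_from_words(["cd"], ClassLabel.NON_CNE)]
        res = FragmentNaiveBayes(fots, 5).fit()
        single = FragmentNaiveBayes([fots[1]], 5).fit()
        grams = fot_descriptors(fots[0], 5)
        for label in CLASS_ORDER:
            assert res.loo_b_all(0)[CLASS_INDEX[label]] == pytest.approx(
                single.b_statistic(grams, label), abs=1e-12)

    def test_loo_equals_full_retrain(self):
        rng = random.Random(909)
        for _ in range(15):
            fots, _ = random_micro_corpus(rng, max_fots=30)
            res = FragmentNaiveBayes(fots, 2).fit()
            i = rng.randrange(len(fots))
            rest = fots[:i] + fots[i + 1:]
            retrained = FragmentNaiveBayes(rest, 2).fit()
            grams = fot_descriptors(fots[i], 2)
            got = res.loo_b_all(i)
            for label in CLASS_ORDER:
                want = retrained.b_statistic(grams, label)
                assert abs(got[CLASS_INDEX[label]] - want) < 1e-12

    def test_loo_by_value_matches_loo_by_index(self):
        rng = random.Random(4)
        fots, _ = random_micro_corpus(rng, max_fots=15)
        res = FragmentNaiveBayes(fots, 2).fit()
        got = res.loo_predict(fots[3], ClassLabel.CNE)
        assert got == pytest.approx(
            float(res.loo_b_all(3)[CLASS_INDEX[ClassLabel.CNE]]), abs=1e-15)

    def test_foreign_fot_rejected(self):
        fots = [fot_from_words(["ab"], ClassLabel.TRIVIAL),
                fot_from_words(["cd"], ClassLabel.NON_CNE)]
        res = FragmentNaiveBayes(fots, 5).fit()
        with pytest.raises(ValueError):
            res.loo_predict(fot_from_words(["zz"], ClassLabel.TRIVIAL),
                            ClassLabel.CNE)

    def test_loo_does_not_mutate_counts(self):
        fots = [fot_from_words(["ab"], ClassLabel.TRIVIAL),
                fot_from_words(["cd"], ClassLabel.NON_CNE)]
        res = FragmentNaiveBayes(fots, 5).fit()
        before_ni = res.counts.ni.copy()
        before_nk = res.counts.nk.copy()
        res.loo_b_all(0)
        assert (res.counts.ni == before_ni).all()
        assert (res.counts.nk == before_nk).all()


class TestCalibration:
    def test_perfect_separation(self):
        scores = [0.9] * 10 + [-0.9] * 40
        positive = [True] * 10 + [False] * 40
        cal = BinnedCalibration.fit(scores, positive)
        assert cal(0.9) == pytest.approx(1.0)
        assert cal(-0.9) == pytest.approx(0.0)

    def test_labels_independent_of_score_give_half(self):
        # balanced class-conditional construction: uninformative scores map
        # to ~0.5 regardless of prevalence
        rng = np.random.default_rng(12)
        scores = rng.uniform(-1, 1, size=8000)
        positive = rng.uniform(size=8000) < 0.2
        cal = BinnedCalibration.fit(scores, positive)
        grid = np.linspace(-0.9, 0.9, 19)
        # binomial noise at ~200 samples/bin; generous 4-sigma band
        assert np.all(np.abs(cal(grid) - 0.5) < 0.2)

    def test_outputs_clipped_and_defined_everywhere(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0.2, 0.3, size=500).clip(-1, 1)
        positive = rng.uniform(size=500) < 0.5
        for method in ("binned", "poly"):
            cal = fit_calibration(scores, positive, method)
            values = cal(np.linspace(-1, 1, 201))
            assert np.all(values >= 0.0) and np.all(values <= 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            BinnedCalibration.fit([0.1, 0.2], [True, True])


class TestPrediction:
    def test_cne_only_grams_rank_cne_higher(self):
        res = _fit([(ClassLabel.TRIVIAL, ["benzene"]),
                    (ClassLabel.TRIVIAL, ["toluene"]),
                    (ClassLabel.NON_CNE, ["study"]),
                    (ClassLabel.NON_CNE, ["group"]),
                    (ClassLabel.NON_CNE, ["data"])])
        b = res.b_all(fot_descriptors(fot_from_words(["benzene"],
                                                     ClassLabel.TRIVIAL), 5))
        assert b[CLASS_INDEX[ClassLabel.CNE]] > b[CLASS_INDEX[ClassLabel.NON_CNE]]

    def test_prediction_deterministic(self, small_results, small_calibration):
        fot = small_results.model.fots[17]
        p1 = small_results.predict_fot(fot, small_calibration)
        p2 = small_results.predict_fot(fot, small_calibration)
        assert p1 == p2
        assert 0.0 <= p1.pc <= 1.0 and 0.0 <= p1.pnc <= 1.0

    def test_position_prediction_uses_covering_grams(self, small_results,
                                                     small_calibration):
        # chemical-looking token: the letter inside a morpheme scores CNE-ish
        pc, pnc = small_results.predict_position("quercetin", 4,
                                                 small_calibration)
        pc_bg, pnc_bg = small_results.predict_position("therefore", 4,
                                                       small_calibration)
        assert pc > pc_bg
        assert pnc < pnc_bg
        with pytest.raises(IndexError):
            small_results.predict_position("ab", 5, small_calibration)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path, small_results,
                                              small_calibration):
        path = tmp_path / "model.txt"
        small_results.save(path, small_calibration)
        loaded, cal = load_results(path)
        assert cal is not None
        assert loaded.counts.n_total == small_results.counts.n_total
        grams = {"QUERC", "ETIN", "Q", "IN"}
        for label in CLASS_ORDER:
            assert loaded.b_statistic(grams, label) == pytest.approx(
                small_results.b_statistic(grams, label), abs=1e-12)
        pred_old = small_results.predict_grams(grams, small_calibration)
        pred_new = loaded.predict_grams(grams, cal)
        assert pred_new.pc == pytest.approx(pred_old.pc, abs=1e-12)
        assert pred_new.pnc == pytest.approx(pred_old.pnc, abs=1e-12)

    def test_loaded_model_refuses_loo(self, tmp_path, small_results):
        path = tmp_path / "model.txt"
        small_results.save(path)
        loaded, cal = load_results(path)
        assert cal is None
        with pytest.raises(ValueError):
            loaded.loo_matrix()


def test_summary_mentions_key_quantities(small_results):
    text = small_results.summary()
    assert "n_max" in text and "CNE" in text and "NON_CNE" in text
    assert str(small_results.counts.n_total) in text
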