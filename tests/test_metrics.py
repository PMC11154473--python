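import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, f1_score, roc_auc_score

from survbias.exceptions import UndefinedMetricError
from survbias.metrics import (
    CompositeWeights,
    ConfusionCounts,
    auc,
    average_roc,
    basic_rates,
    cohens_kappa,
    composite_score,
    compute_report,
    confusion,
    cross_entropy,
    f1_weighted,
    heaviside,
    roc_points,
)

# ------------------------------------------------------------------ brute-force oracles


def oracle_counts(y_true, y_pred):
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def oracle_kappa(y_true, y_pred):
    tp, fp, tn, fn = oracle_counts(y_true, y_pred)
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fp) * (tn + fn)) / n**2
    return 0.0 if pe == 1 else (po - pe) / (1 - pe)


def oracle_auc_pairwise(y_true, scores):
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def oracle_cross_entropy(y_true, scores, eps=1e-15):
    total = 0.0
    for t, p in zip(y_true, scores):
        p = min(max(p, eps), 1 - eps)
        total += t * math.log(p) + (1 - t) * math.log(1 - p)
    return -total / len(y_true)


# --------------------------------------------------------------------------- confusion


class TestConfusion:
    def test_hand_examples(self):
        c = confusion((1, 0, 1), (1, 0, 1))
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 1, 0, 0)
        c = confusion((1, 1, 0, 0), (0, 0, 0, 0))
        assert (c.TP, c.FN, c.TN, c.FP) == (0, 2, 2, 0)

    def test_matches_elementwise_tally(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 1000)
        p = rng.integers(0, 2, 1000)
        c = confusion(y, p)
        assert (c.TP, c.FP, c.TN, c.FN) == oracle_counts(y, p)
        assert c.total == 1000

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            confusion((1, 0), (1,))
        with pytest.raises(ValueError):
            confusion((1, 2), (1, 0))


class TestBasicRates:
    def test_perfect_prediction(self):
        acc, rec, pp, nneg, f1, err = basic_rates(ConfusionCounts(TP=2, FP=0, TN=1, FN=0))
        assert (acc, rec, pp) == (1.0, 1.0, 1.0)
        assert err == 0.0

    def test_hand_arithmetic(self):
        acc, rec, pp, nneg, f1, err = basic_rates(ConfusionCounts(TP=30, FP=70, TN=880, FN=20))
        assert pp == pytest.approx(0.30)
        assert rec == pytest.approx(0.60)
        assert f1 == pytest.approx(0.40)

    def test_zero_denominator_convention(self, caplog):
        with caplog.at_level(logging.WARNING, logger="survbias.metrics"):
            _, _, pp, _, _, _ = basic_rates(ConfusionCounts(TP=0, FP=0, TN=3, FN=1))
        assert pp == 0.0
        assert any("positive precision" in r.message for r in caplog.records)


class TestF1Weighted:
    def test_perfect_is_one(self):
        y = np.array([0, 1, 0, 1, 1])
        assert f1_weighted(y, y) == pytest.approx(1.0)

    def test_all_negative_predictions_per_class_decomposition(self):
        rng = np.random.default_rng(1)
        y = (rng.random(1000) < 0.12).astype(int)
        pred = np.zeros(1000, dtype=int)
        # class-0 F1 from the class-0 confusion table; class-1 F1 is 0
        tp0 = int((y == 0).sum())
        prec0 = tp0 / 1000
        f1_0 = 2 * prec0 * 1.0 / (prec0 + 1.0)
        expected = (y == 0).mean() * f1_0
        assert f1_weighted(y, pred) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(5, 60)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert f1_weighted(y, p) == pytest.approx(
                f1_score(y, p, average="weighted", zero_division=0), abs=1e-12)


class TestKappa:
    def test_perfect_agreement(self):
        y = np.array([0, 1, 1, 0, 1])
        assert cohens_kappa(y, y) == pytest.approx(1.0)

    def test_constant_prediction_is_zero(self):
        y = np.array([0, 1, 1, 0])
        assert cohens_kappa(y, np.ones(4, dtype=int)) == pytest.approx(0.0)
        assert cohens_kappa(y, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_matches_formula_and_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(2, 50)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            k = cohens_kappa(y, p)
            assert k == pytest.approx(oracle_kappa(y, p), abs=1e-12)
            if len(np.unique(np.r_[y, p])) == 2:
                assert k == pytest.approx(cohen_kappa_score(y, p), abs=1e-12)


class TestCrossEntropy:
    def test_uniform_scores_give_log_two(self):
        y = np.array([0, 1, 1, 0])
        assert cross_entropy(y, np.full(4, 0.5)) == pytest.approx(math.log(2))

    def test_saturated_scores_hit_clipping_floor(self):
        y = np.array([1, 0])
        loss = cross_entropy(y, np.array([1.0, 0.0]))
        assert 0 < loss < 2e-15

    def test_matches_termwise_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        p = rng.random(200)
        assert cross_entropy(y, p) == pytest.approx(oracle_cross_entropy(y, p), abs=1e-12)

    def test_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            cross_entropy([0, 1], [0.5, 1.2])


class TestAUC:
    def test_separated_scores(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0, 1, 0, 1], [0.3] * 4) == pytest.approx(0.5)

    def test_matches_pairwise_oracle_and_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # rounding forces ties
            a = auc(y, s)
            assert a == pytest.approx(oracle_auc_pairwise(y, s), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([1, 1, 1], [0.2, 0.3, 0.4])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_invariance_under_increasing_transform(self, scores, label_seed):
        # integer-valued scores keep the tie structure exact under the affine map
        scores = np.asarray(scores, dtype=float)
        y = np.random.default_rng(label_seed).integers(0, 2, len(scores))
        if y.min() == y.max():
            y[0] = 1 - y[0]
        base = auc(y, scores)
        assert auc(y, 2.5 * scores + 7) == pytest.approx(base, abs=1e-12)
        assert auc(y, np.exp(scores / 1000)) == pytest.approx(base, abs=1e-12)


class TestComposite:
    def test_zero_recall_gates_kappa_off(self):
        w = CompositeWeights()
        assert composite_score(0.7, 0.9, 0.0, w) == pytest.approx(w.w1 * 0.7)

    def test_zero_kappa_leaves_auc_term(self):
        w = CompositeWeights()
        assert composite_score(0.6, 0.0, 0.8, w) == pytest.approx(w.w1 * 0.6)

    def test_maximal_inputs_with_default_weights(self):
        assert composite_score(1.0, 1.0, 1.0, CompositeWeights(2.0, 0.25)) == pytest.approx(2.25)

    def test_alternative_gate_parse(self):
        w = CompositeWeights()
        assert composite_score(0.7, 0.0, 0.9, w, gate="kappa") == pytest.approx(w.w1 * 0.7)
        assert composite_score(0.7, 0.4, 0.9, w, gate="kappa") == pytest.approx(
            w.w1 * 0.7 + w.w2 * 0.9)

    def test_heaviside_definition(self):
        assert heaviside(0.3) == 1.0
        assert heaviside(0.0) == 0.0
        assert heaviside(-1.0) == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(-1, 1), st.floats(0.01, 1))
    def test_monotone_in_auc_and_kappa(self, a1, a2, kappa, recall):
        w = CompositeWeights()
        lo, hi = sorted((a1, a2))
        assert composite_score(lo, kappa, recall, w) <= composite_score(hi, kappa, recall, w)
        if recall > 0:
            assert composite_score(lo, kappa, recall, w) <= composite_score(lo, min(kappa + 0.1, 1), recall, w)


class TestAverageRoc:
    def test_single_fold_equals_its_interpolation(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([0.1, 0.9, 0.4, 0.6, 0.7, 0.2])
        curve = roc_points(y, s)
        grid, mean_tpr, mean_auc = average_roc([curve])
        np.testing.assert_allclose(mean_tpr, np.interp(grid, *curve))
        assert mean_auc == pytest.approx(auc(y, s), abs=1e-12)

    def test_identical_folds_average_to_one_fold(self):
        y = np.array([0, 1, 1, 0, 1])
        s = np.array([0.2, 0.8, 0.5, 0.4, 0.9])
        c = roc_points(y, s)
        _, one, _ = average_roc([c])
        _, three, _ = average_roc([c, c, c])
        np.testing.assert_allclose(one, three)

    def test_mean_auc_is_mean_of_fold_aucs(self):
        c1 = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))       # AUC 0.5
        c2 = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]))  # AUC 1.0
        _, _, mean_auc = average_roc([c1, c2])
        assert mean_auc == pytest.approx(0.75)


class TestReport:
    def test_accuracy_error_rate_complement_exact(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 300)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        p = rng.random(300)
        r = compute_report(y, p)
        assert r.accuracy + r.error_rate == 1.0
        for v in (r.accuracy, r.recall, r.positive_precision, r.negative_precision,
                  r.f1_binary, r.f1_weighted, r.auc):
            assert 0.0 <= v <= 1.0
        assert -1.0 <= r.cohens_kappa <= 1.0
        assert r.composite == pytest.approx(
            composite_score(r.auc, r.cohens_kappa, r.recall))
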