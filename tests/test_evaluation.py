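"""Tests for the evaluation calculus: confusion matrix, per-class and macro
precision/recall/F1, accuracy, one-vs-rest ROC and macro-AUC.

Brute-force counting loops and scikit-learn serve as independent oracles.
"""

import numpy as np
import pytest
from sklearn.metrics import (
    confusion_matrix as sk_confusion,
    precision_score,
    recall_score,
    roc_auc_score,
)

from gaitphase.evaluation import (
    ConfusionMatrix,
    accuracy,
    confusion_matrix,
    evaluate,
    macro_metrics,
    per_class_prf,
    roc_ovr,
)


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 3, 3, 2])
        cm = confusion_matrix(y, y)
        assert (cm.counts == np.diag([1, 1, 2, 2])).all()

    def test_all_predicted_ff(self):
        y = np.array([0, 1, 2, 3])
        cm = confusion_matrix(y, np.full(4, 1))
        assert cm.counts[:, 1].sum() == 4 and cm.counts.sum() == 4
        assert (cm.counts[:, [0, 2, 3]] == 0).all()

    def test_brute_force_counting_oracle(self, rng):
        yt = rng.integers(0, 4, size=1000)
        yp = rng.integers(0, 4, size=1000)
        cm = confusion_matrix(yt, yp)
        # independent counting loop
        ref = np.zeros((4, 4), dtype=int)
        for a, b in zip(yt, yp):
            ref[a, b] += 1
        assert (cm.counts == ref).all()
        assert (cm.counts == sk_confusion(yt, yp, labels=[0, 1, 2, 3])).all()

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 1])

    def test_marginal_identities(self, rng):
        """Sum of TPs = trace; TP+FP = column sum; TP+FN = row sum."""
        yt = rng.integers(0, 4, size=500)
        yp = rng.integers(0, 4, size=500)
        cm = confusion_matrix(yt, yp)
        pc = per_class_prf(cm)
        assert sum(m.tp for m in pc.values()) == np.trace(cm.counts)
        for i, name in enumerate(("HS", "FF", "HO", "SW")):
            assert pc[name].tp + pc[name].fp == cm.counts[:, i].sum()
            assert pc[name].tp + pc[name].fn == cm.counts[i, :].sum()


class TestPerClassMetrics:
    def test_published_fms_hs_cell(self):
        """A class with P = 73.8% and R = 56.0% has F1 = 63.7% (harmonic
        mean, 1-decimal rounding)."""
        cm = ConfusionMatrix(np.array([
            [560, 440, 0, 0],
            [199, 801, 0, 0],
            [0, 0, 1000, 0],
            [0, 0, 0, 1000],
        ]))
        m = per_class_prf(cm)["HS"]
        assert m.precision == pytest.approx(73.8, abs=0.05)
        assert m.recall == pytest.approx(56.0, abs=0.05)
        assert round(m.f1, 1) == 63.7

    def test_zero_division_convention(self):
        """A never-predicted, never-correct class scores P = R = F1 = 0."""
        cm = ConfusionMatrix(np.array([
            [0, 10, 0, 0],
            [0, 90, 0, 0],
            [0, 0, 50, 0],
            [0, 0, 0, 50],
        ]))
        m = per_class_prf(cm)["HS"]
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_harmonic_mean_fixed_point(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 0])
        m = per_class_prf(cm)["HS"]
        assert m.precision == m.recall == pytest.approx(50.0)
        assert m.f1 == pytest.approx(50.0)  # F1 = P when P == R

    def test_agrees_with_sklearn(self, rng):
        yt = rng.integers(0, 4, size=400)
        yp = rng.integers(0, 4, size=400)
        pc = per_class_prf(confusion_matrix(yt, yp))
        skp = precision_score(yt, yp, labels=[0, 1, 2, 3], average=None,
                              zero_division=0)
        skr = recall_score(yt, yp, labels=[0, 1, 2, 3], average=None,
                           zero_division=0)
        for i, name in enumerate(("HS", "FF", "HO", "SW")):
            assert pc[name].precision == pytest.approx(100 * skp[i], abs=1e-9)
            assert pc[name].recall == pytest.approx(100 * skr[i], abs=1e-9)


class TestAccuracy:
    def test_diagonal_is_100(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]))
        assert accuracy(cm) == 100.0

    def test_single_error_among_100(self):
        counts = np.diag([24, 25, 25, 25])
        counts[0, 1] = 1
        assert accuracy(ConfusionMatrix(counts)) == pytest.approx(99.0)

    def test_uniform_random_chance_level(self, rng):
        yt = rng.integers(0, 4, size=10_000)
        yp = rng.integers(0, 4, size=10_000)
        assert accuracy(confusion_matrix(yt, yp)) == pytest.approx(25.0, abs=2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


class TestMacroMetrics:
    def test_all_perfect(self):
        cm = ConfusionMatrix(np.diag([10, 10, 10, 10]))
        assert macro_metrics(per_class_prf(cm)) == (100.0, 100.0, 100.0)

    def test_one_dead_class_fixed_point(self):
        """P = R = (0, 100, 100, 100) gives macro-P = macro-R = macro-F1 = 75."""
        cm = ConfusionMatrix(np.array([
            [0, 10, 0, 0],
            [0, 90, 0, 0],
            [0, 0, 50, 0],
            [0, 0, 0, 50],
        ]))
        # FF picks up HS's misclassifications: P_FF < 100, so build exact case
        cm = ConfusionMatrix(np.array([
            [0, 0, 0, 0],
            [0, 90, 0, 0],
            [0, 0, 50, 0],
            [0, 0, 0, 50],
        ]))
        mp, mr, mf1 = macro_metrics(per_class_prf(cm))
        assert (mp, mr, mf1) == (75.0, 75.0, 75.0)

    def test_macro_f1_is_harmonic_of_macros(self, rng):
        """Recomputation oracle from raw counts: macro-F1 combines the two
        macro averages, not the per-class F1 scores."""
        yt = rng.integers(0, 4, size=300)
        yp = np.where(rng.random(300) < 0.6, yt, rng.integers(0, 4, size=300))
        pc = per_class_prf(confusion_matrix(yt, yp))
        mp, mr, mf1 = macro_metrics(pc)
        ps = [m.precision for m in pc.values()]
        rs = [m.recall for m in pc.values()]
        expect = 2 * np.mean(ps) * np.mean(rs) / (np.mean(ps) + np.mean(rs))
        assert mf1 == pytest.approx(expect, abs=1e-9)

    def test_harmonic_mean_bound(self, rng):
        for _ in range(20):
            yt = rng.integers(0, 4, size=100)
            yp = rng.integers(0, 4, size=100)
            mp, mr, mf1 = macro_metrics(per_class_prf(confusion_matrix(yt, yp)))
            assert min(mp, mr) - 1e-9 <= mf1 <= max(mp, mr) + 1e-9


class TestRoc:
    def _one_hot_scores(self, labels, correct=True):
        q = np.full((len(labels), 4), 0.05)
        for i, c in enumerate(labels):
            q[i, c if correct else (c + 1) % 4] = 0.85
        return q

    def test_perfect_separation(self, rng):
        y = rng.integers(0, 4, size=40)
        _, macro_auc = roc_ovr(y, self._one_hot_scores(y))
        assert macro_auc == pytest.approx(1.0)

    def test_identical_scores_give_half(self, rng):
        y = rng.integers(0, 4, size=40)
        _, macro_auc = roc_ovr(y, np.full((40, 4), 0.25))
        assert macro_auc == pytest.approx(0.5)

    def test_brute_force_threshold_oracle(self):
        """6-example toy set: AUC equals exhaustive enumeration over all
        positive/negative pairs (ties count 1/2)."""
        y = np.array([0, 0, 1, 1, 2, 3])
        q = np.array([
            [0.6, 0.2, 0.1, 0.1],
            [0.3, 0.3, 0.2, 0.2],
            [0.4, 0.4, 0.1, 0.1],
            [0.1, 0.7, 0.1, 0.1],
            [0.2, 0.2, 0.5, 0.1],
            [0.25, 0.25, 0.2, 0.3],
        ])
        roc, macro_auc = roc_ovr(y, q)
        aucs = []
        for c in range(4):
            pos = q[y == c, c]
            neg = q[y != c, c]
            pairs = [(0.5 if p == n_ else float(p > n_)) for p in pos for n_ in neg]
            aucs.append(np.mean(pairs))
        assert macro_auc == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        y = rng.integers(0, 4, size=200)
        q = softmax_like = rng.dirichlet(np.ones(4), size=200)
        _, macro_auc = roc_ovr(y, q)
        ref = roc_auc_score(y, q, multi_class="ovr", average="macro")
        assert macro_auc == pytest.approx(ref, abs=1e-9)

    def test_score_reversal_flips_auc(self, rng):
        y = (rng.random(100) < 0.3).astype(int)  # classes 0/1 only
        q = np.zeros((100, 4))
        q[:, 0] = rng.random(100)
        q[:, 1] = 1 - q[:, 0]
        with pytest.warns(UserWarning):
            _, auc_fwd = roc_ovr(y, q)
        qr = q.copy()
        qr[:, 0], qr[:, 1] = q[:, 1], q[:, 0]
        with pytest.warns(UserWarning):
            _, auc_rev = roc_ovr(y, qr)
        assert auc_fwd == pytest.approx(1.0 - auc_rev, abs=1e-9)

    def test_absent_class_excluded_with_warning(self, rng):
        y = np.array([0, 0, 1, 1])
        q = rng.dirichlet(np.ones(4), size=4)
        with pytest.warns(UserWarning, match="absent"):
            roc, macro_auc = roc_ovr(y, q)
        assert set(roc) <= {"HS", "FF"}
        assert np.isfinite(macro_auc)

    def test_roc_points_monotone(self, rng):
        y = rng.integers(0, 4, size=100)
        q = rng.dirichlet(np.ones(4), size=100)
        roc, _ = roc_ovr(y, q)
        for pts in roc.values():
            assert (np.diff(pts[:, 0]) >= 0).all()
            assert (np.diff(pts[:, 1]) >= 0).all()


class TestFullReport:
    def test_report_serialization_and_consistency(self, rng):
        y = rng.integers(0, 4, size=300)
        yp = np.where(rng.random(300) < 0.8, y, rng.integers(0, 4, size=300))
        q = np.full((300, 4), 0.1)
        q[np.arange(300), yp] = 0.7
        rep = evaluate(y, yp, q)
        d = rep.to_dict()
        assert set(d) >= {"accuracy", "macro_p", "macro_r", "macro_f1",
                          "macro_auc", "per_class", "confusion"}
        assert 0 <= d["macro_auc"] <= 1
        text = rep.to_text()
        assert "Macro-F1" in text and "HS" in text
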