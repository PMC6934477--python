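"""LOPO ensemble prediction: metrics, balance, leakage and determinism."""

import numpy as np
import pandas as pd
import pytest

from srtrad.prediction import (
    ClassifierSpec,
    PatientSampler,
    balance_patients,
    compute_metrics,
    fast_auc,
    lopo_predict,
    spec_for_outcome,
)


def _data(n_pat, lesions_per, lf_frac, d, seed, n_feat=3):
    rng = np.random.default_rng(seed)
    pids = np.repeat([f"P{i:03d}" for i in range(n_pat)], lesions_per)
    y = rng.random(len(pids)) < lf_frac
    X = rng.normal(size=(len(pids), n_feat))
    X[y] += d
    labels = np.where(y, "LF", "LC")
    tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_feat)])
    tab.index = [f"L{i}" for i in range(len(pids))]
    return tab, labels, pids, y


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([True, False, True])
        m = compute_metrics(y, y)
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_constructed_confusion_table(self):
        # TP=43, FN=10, TN=63, FP=17 -> sens .81, spec .79, acc .80
        truth = np.array([True] * 53 + [False] * 80)
        pred = np.array([True] * 43 + [False] * 10 + [False] * 63 + [True] * 17)
        m = compute_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(43 / 53, abs=1e-12)
        assert m["specificity"] == pytest.approx(63 / 80, abs=1e-12)
        assert m["accuracy"] == pytest.approx(106 / 133, abs=1e-12)
        assert round(m["sensitivity"], 2) == 0.81
        assert round(m["specificity"], 2) == 0.79
        assert round(m["accuracy"], 2) == 0.80

    def test_all_positive_prediction(self):
        truth = np.array([True, True, False, False])
        pred = np.ones(4, dtype=bool)
        m = compute_metrics(pred, truth)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_absent_class_flagged_undefined(self):
        truth = np.zeros(5, dtype=bool)
        m = compute_metrics(np.zeros(5, dtype=bool), truth)
        assert np.isnan(m["sensitivity"]) and m["specificity"] == 1.0

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros(3, bool), np.zeros(4, bool))


class TestFastAuc:
    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        y = rng.random(80) < 0.4
        s = rng.normal(size=80) + y
        assert fast_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fast_auc(np.arange(4.0), np.ones(4, bool))


class TestBalance:
    def test_pure_majority_patients_dropped_to_balance(self):
        pids = [f"P{i}" for i in range(16)]
        y = np.array([True] * 6 + [False] * 10)
        lesions_of = {p: np.array([i]) for i, p in enumerate(pids)}
        kept = balance_patients(pids, lesions_of, y, np.random.default_rng(0))
        yk = y[[int(p[1:]) for p in kept]]
        assert yk.sum() == (~yk).sum() == 6

    def test_mixed_label_patients_never_dropped(self):
        pids = ["A", "B", "C"]
        lesions_of = {"A": np.array([0, 1]), "B": np.array([2]), "C": np.array([3])}
        y = np.array([True, False, False, False])
        kept = balance_patients(pids, lesions_of, y, np.random.default_rng(1))
        assert "A" in kept

    def test_bootstrap_training_sets_balanced(self):
        tab, labels, pids, y = _data(30, 1, 0.3, 0.0, seed=2)
        patients = list(pd.unique(pids))
        lesions_of = {p: np.flatnonzero(pids == p) for p in patients}
        sampler = PatientSampler(patients, lesions_of, y)
        rng = np.random.default_rng(3)
        for _ in range(20):
            keep = sampler.balanced_subset(rng)
            yk = np.concatenate([y[sampler.lesions[i]] for i in keep])
            assert yk.sum() == (~yk).sum()


class TestLopo:
    def test_perfectly_separable_biomarker(self):
        tab, labels, pids, _ = _data(24, 1, 0.4, 6.0, seed=4)
        res = lopo_predict(tab, labels, pids, ClassifierSpec(), n_bootstrap=20, rng=0)
        assert res.metrics["accuracy"] == 1.0
        assert set(res.frame().columns) == {
            "lesion_id", "patient_id", "truth", "vote_fraction", "predicted"
        }

    def test_vote_fraction_is_count_over_bootstraps(self):
        tab, labels, pids, _ = _data(16, 1, 0.4, 2.0, seed=5)
        res = lopo_predict(tab, labels, pids, ClassifierSpec(), n_bootstrap=16, rng=1)
        assert np.allclose(res.vote_fraction * 16, np.round(res.vote_fraction * 16))
        # exact-tie rule: half the votes suffice for LF
        assert np.array_equal(res.predicted, res.vote_fraction >= 0.5)

    def test_deterministic_under_seed(self):
        tab, labels, pids, _ = _data(14, 1, 0.4, 1.0, seed=6)
        a = lopo_predict(tab, labels, pids, ClassifierSpec(), n_bootstrap=10, rng=7)
        b = lopo_predict(tab, labels, pids, ClassifierSpec(), n_bootstrap=10, rng=7)
        assert np.array_equal(a.vote_fraction, b.vote_fraction)

    def test_held_out_patient_never_in_training(self):
        # flipping a patient's outcome labels must leave that patient's own
        # votes untouched: their lesions are only ever test data for
        # themselves, and labels enter prediction through training alone
        tab, labels, pids, _ = _data(12, 2, 0.3, 1.5, seed=2)
        a = lopo_predict(tab, labels, pids, ClassifierSpec(), n_bootstrap=10, rng=9)
        sel = pids == "P003"
        flipped = labels.copy()
        flipped[sel] = np.where(labels[sel] == "LF", "LC", "LF")
        b = lopo_predict(tab, flipped, pids, ClassifierSpec(), n_bootstrap=10, rng=9)
        assert np.array_equal(a.vote_fraction[sel], b.vote_fraction[sel])
        # ...while the same flip does change training for everyone else
        assert not np.array_equal(a.vote_fraction[~sel], b.vote_fraction[~sel])

    def test_too_few_patients_per_class_rejected(self):
        tab, labels, pids, _ = _data(6, 1, 0.0, 0.0, seed=10)
        labels[0] = "LF"
        with pytest.raises(ValueError, match="2 patients"):
            lopo_predict(tab, labels, pids, ClassifierSpec(), n_bootstrap=5, rng=0)


def test_kernel_choice_per_outcome():
    assert spec_for_outcome("overall").kernel == "rbf"
    assert spec_for_outcome("m12").kernel == "rbf"
    assert spec_for_outcome("m6").kernel == "linear"
    with pytest.raises(ValueError):
        ClassifierSpec(kernel="poly")
    with pytest.raises(ValueError):
        ClassifierSpec(regularization=0.0)
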