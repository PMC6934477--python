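"""Feature reduction/ranking/selection against constructed oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from srtrad.prediction import ClassifierSpec
from srtrad.selection import (
    ForwardSelectionResult,
    anova_minimal_set,
    assign_patient_folds,
    auc_632plus,
    combine_632plus,
    correlation_reduce,
    forward_select,
    mwu_pvalues,
    rank_features_mwu,
)


def _patients(n, lesions_per=1):
    return np.repeat([f"P{i:03d}" for i in range(n)], lesions_per)


class TestCorrelationReduce:
    def test_perfect_correlation_keeps_largest_range(self):
        rng = np.random.default_rng(0)
        f1 = rng.normal(size=30)
        tab = pd.DataFrame({"f1": f1, "f2": 2 * f1, "f3": rng.normal(size=30)})
        red = correlation_reduce(tab, 0.8)
        assert sorted(map(len, red.clusters)) == [1, 2]
        assert "f2" in red.representatives  # range of 2*f1 is double
        assert "f3" in red.representatives

    def test_independent_features_identity_reduction(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(rng.normal(size=(60, 8)), columns=list("abcdefgh"))
        red = correlation_reduce(tab, 0.8)
        assert red.representatives == list("abcdefgh")

    def test_constructed_component_structure(self):
        # x, x+eps, -x form one component; y, y+eps another; z alone
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        tab = pd.DataFrame(
            {
                "x1": x,
                "x2": x + 0.01 * rng.normal(size=50),
                "x3": -x,
                "y1": y,
                "y2": y + 0.01 * rng.normal(size=50),
                "z": rng.normal(size=50),
            }
        )
        red = correlation_reduce(tab, 0.8)
        comp = {frozenset(c) for c in red.clusters}
        assert comp == {
            frozenset({"x1", "x2", "x3"}),
            frozenset({"y1", "y2"}),
            frozenset({"z"}),
        }

    def test_constant_feature_never_shadows_varying(self):
        tab = pd.DataFrame(
            {"const": np.zeros(20), "var": np.linspace(0, 1, 20)}
        )
        red = correlation_reduce(tab, 0.8)
        assert "var" in red.representatives
        assert ["const"] in red.clusters  # its own singleton cluster

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(40, 4))
        tab = pd.DataFrame(
            np.column_stack([base, base + 0.3 * rng.normal(size=(40, 4))]),
            columns=[f"g{i}" for i in range(8)],
        )
        sizes = [
            len(correlation_reduce(tab, thr).representatives)
            for thr in (0.5, 0.8, 0.95)
        ]
        assert sizes == sorted(sizes)

    def test_missing_values_tolerated(self):
        rng = np.random.default_rng(4)
        tab = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        tab.iloc[::7, 2] = np.nan
        red = correlation_reduce(tab, 0.8)
        assert red.n_features == 5


def exact_mwu_p(a, b):
    """Two-sided Mann-Whitney p by enumerating all rank arrangements."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(b)
    u_min = min(u_obs, n1n2 - u_obs)
    count = 0
    total = 0
    all_ranks = np.arange(1, len(pooled) + 1)
    for idx in combinations(range(len(pooled)), n1):
        u = all_ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_min or u >= n1n2 - u_min:
            count += 1
    return count / total


class TestRanking:
    def test_exact_p_for_123_vs_456(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([False, False, False, True, True, True])
        p = mwu_pvalues(X, y)[0]
        assert p == pytest.approx(0.1, abs=1e-12)
        assert exact_mwu_p(X[y, 0], X[~y, 0]) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exact_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        X = np.concatenate([a, b])[:, None]
        y = np.array([True] * n1 + [False] * n2)
        assert mwu_pvalues(X, y)[0] == pytest.approx(
            exact_mwu_p(a, b), abs=1e-10
        )

    def test_huge_separation_ranks_first_with_full_frequency(self):
        rng = np.random.default_rng(5)
        pids = _patients(60)
        y = np.array([i % 2 == 0 for i in range(60)])
        labels = np.where(y, "LF", "LC")
        X = rng.normal(size=(60, 20))
        X[y, 7] += 30.0
        tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(20)])
        ranked = rank_features_mwu(tab, labels, pids, n_folds=20, top_k=5, rng=0)
        assert ranked.order[0] == "f7"
        assert ranked.frequency["f7"] == 20

    def test_null_ranking_carries_no_planted_scale_signal(self):
        # leave-one-fold-out subsets share ~96% of patients, so per-fold
        # rankings are strongly dependent and a spurious best feature can
        # recur in every fold even under permuted labels; the null
        # signature is instead that its p-value is only as small as the
        # minimum of ~200 uniforms, orders of magnitude above a real effect
        rng = np.random.default_rng(6)
        pids = _patients(80)
        labels = np.where(rng.random(80) < 0.5, "LF", "LC")
        tab = pd.DataFrame(
            rng.normal(size=(80, 200)), columns=[f"f{i}" for i in range(200)]
        )
        ranked = rank_features_mwu(tab, labels, pids, n_folds=50, top_k=15, rng=1)
        assert ranked.median_p[ranked.order[0]] > 1e-5
        informative = tab.copy()
        informative["sig"] = np.where(labels == "LF", 3.0, 0.0) + rng.normal(
            size=80
        )
        ranked2 = rank_features_mwu(informative, labels, pids, 50, 15, rng=1)
        assert ranked2.order[0] == "sig"
        assert ranked2.median_p["sig"] < 1e-8

    def test_single_class_fold_rejected(self):
        pids = _patients(10)
        labels = np.array(["LF"] + ["LC"] * 9)
        tab = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        tab.columns = ["a", "b", "c"]
        with pytest.raises(ValueError, match="class"):
            rank_features_mwu(tab, labels, pids, n_folds=5, top_k=2, rng=0)

    def test_folds_partition_patients(self):
        pids = _patients(55, lesions_per=2)
        pos = {p: (i % 3 == 0) for i, p in enumerate(pd.unique(pids))}
        folds = assign_patient_folds(pids, pos, 50, np.random.default_rng(0))
        assert set(folds.values()) == set(range(50))
        assert len(folds) == 55


class TestAuc632Plus:
    def test_blend_equals_resub_when_no_optimism(self):
        assert combine_632plus(0.8, 0.8) == pytest.approx(0.8)

    def test_blend_endpoints(self):
        # total overfitting: resub 1.0, test 0.5 -> R=1, w=1 -> 0.5
        assert combine_632plus(1.0, 0.5) == pytest.approx(0.5)
        # no overfitting ratio: w = 0.632
        assert combine_632plus(0.9, 0.9 - 0.0) == pytest.approx(0.9)
        v = combine_632plus(0.7, 0.75)  # test better than resub -> R = 0
        assert v == pytest.approx(0.368 * 0.7 + 0.632 * 0.75)

    def test_blend_floors_test_auc(self):
        assert combine_632plus(0.6, 0.2) == combine_632plus(0.6, 0.5)

    def test_bounded_by_resub_and_test(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            r = rng.uniform(0.5, 1.0)
            t = rng.uniform(0.3, 1.0)
            v = combine_632plus(r, t)
            lo, hi = sorted([r, max(t, 0.5)])
            assert lo - 1e-12 <= v <= hi + 1e-12

    def test_separable_features_score_high(self):
        rng = np.random.default_rng(1)
        pids = _patients(60)
        y = rng.random(60) < 0.45
        X = rng.normal(size=(60, 2))
        X[y] += 4.0
        res = auc_632plus(X, y, pids, ClassifierSpec(), n_bootstrap=40, rng=2)
        assert res.auc_632plus >= 0.9
        assert res.auc_resub >= 0.95

    def test_standardization_uses_training_rows_only(self):
        from srtrad.selection import _impute_standardize

        rng = np.random.default_rng(2)
        train = rng.normal(size=(30, 4))
        test = rng.normal(size=(10, 4))
        out_tr, _ = _impute_standardize(train, test)
        corrupted = test.copy()
        corrupted[:] = 1e6
        out_tr2, out_te2 = _impute_standardize(train, corrupted)
        assert np.array_equal(out_tr, out_tr2)  # leakage guard
        assert np.isfinite(out_te2).all()


class TestForwardSelection:
    def _ranked(self, names):
        from srtrad.selection import RankedFeatures

        return RankedFeatures(
            order=list(names),
            frequency={n: 1 for n in names},
            median_p={n: 0.5 for n in names},
            top_lists=[],
            n_folds=0,
            top_k=len(names),
        )

    def test_informative_feature_selected_first(self):
        rng = np.random.default_rng(3)
        pids = _patients(50)
        y = rng.random(50) < 0.5
        labels = np.where(y, "LF", "LC")
        X = rng.normal(size=(50, 6))
        X[y, 4] += 3.0
        tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        fwd = forward_select(
            self._ranked(tab.columns), tab, labels, pids,
            ClassifierSpec(), pool_size=6, n_bootstrap=25, rng=0,
        )
        assert fwd.chosen[0] == "f4"
        assert fwd.trajectory["auc_632plus"].iloc[0] > 0.8

    def test_null_pool_trajectory_near_chance(self):
        rng = np.random.default_rng(4)
        pids = _patients(60)
        labels = np.where(rng.random(60) < 0.5, "LF", "LC")
        tab = pd.DataFrame(
            rng.normal(size=(60, 8)), columns=[f"f{i}" for i in range(8)]
        )
        fwd = forward_select(
            self._ranked(tab.columns), tab, labels, pids,
            ClassifierSpec(), pool_size=8, n_bootstrap=25, rng=1,
        )
        # greedy max over a null pool is mildly optimistic but must stay
        # well below genuine signal
        assert fwd.trajectory["auc_632plus"].mean() == pytest.approx(0.5, abs=0.15)


class TestAnovaMinimalSet:
    def _fwd(self, per_size, chosen=None):
        k = len(per_size)
        chosen = chosen or [f"f{i}" for i in range(k)]
        traj = pd.DataFrame(
            {"size": np.arange(1, k + 1),
             "auc_632plus": [float(np.mean(s)) for s in per_size]}
        )
        best = int(np.argmax(traj["auc_632plus"])) + 1
        return ForwardSelectionResult(chosen, chosen, traj, per_size, best)

    def _table(self, names, n=40):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)
        labels = np.where(rng.random(n) < 0.5, "LF", "LC")
        return tab, labels

    def test_identical_distributions_select_single_feature(self):
        base = np.random.default_rng(1).normal(0.8, 0.02, size=50)
        fwd = self._fwd([base.copy() for _ in range(5)])
        tab, labels = self._table(fwd.chosen)
        bio = anova_minimal_set(fwd, tab, labels)
        assert len(bio.features) == 1

    def test_plateau_after_size_five_selects_five(self):
        rng = np.random.default_rng(2)
        per_size = (
            [rng.normal(0.60, 0.02, 100)]
            + [rng.normal(0.62 + 0.02 * i, 0.02, 100) for i in range(3)]
            + [rng.normal(0.80, 0.02, 100)]
            + [rng.normal(0.80, 0.02, 100)]
            + [rng.normal(0.80, 0.02, 100)]
        )
        fwd = self._fwd(per_size)
        tab, labels = self._table(fwd.chosen)
        bio = anova_minimal_set(fwd, tab, labels)
        assert len(bio.features) == 5

    def test_empty_trajectory_rejected(self):
        fwd = self._fwd([np.array([0.7])])
        fwd.per_size_auc = []
        tab, labels = self._table(["f0"])
        with pytest.raises(ValueError):
            anova_minimal_set(fwd, tab, labels)
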