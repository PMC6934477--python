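"""Multi-step reduction of the 3072 features to an optimal qMRI biomarker.

The procedure mirrors the clinical analysis chain:

1. **Correlation reduction** — clusters of mutually redundant features
   (connected components of the R² > 0.8 graph) are collapsed to the
   member with the largest dynamic range.
2. **Ranking** — two-sided Mann-Whitney U p-values per feature, computed
   on each of 50 leave-one-fold-out patient subsets; features are ranked
   by how often they land in a subset's 15 smallest p-values.
3. **Forward selection** — greedy growth over the top-15 pool, scoring
   candidate sets with the bootstrap .632+ AUC of an SVM classifier.
4. **ANOVA minimal set** — the smallest prefix of the greedy order whose
   bootstrap AUC distribution is not significantly worse than the best
   set's (one-way ANOVA, then Tukey HSD against the best size).

Bootstrap resampling and the class-balancing under-sampling both operate
at the patient level so that the multiple lesions of one patient never
straddle a train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .prediction import ClassifierSpec, PatientSampler, fast_auc, make_classifier


# --------------------------------------------------------------------------
# correlation-based reduction

@dataclass
class CorrelationReduction:
    r2_threshold: float
    clusters: list[list[str]]
    representatives: list[str]

    @property
    def n_features(self) -> int:
        return sum(len(c) for c in self.clusters)


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson R² matrix, tolerant of missing values.

    Constant (or all-missing) features get zero correlation with everything
    so they form singleton clusters.
    """
    finite = np.isfinite(X)
    if finite.all():
        sd = X.std(axis=0)
        ok = sd > 0
        r = np.zeros((X.shape[1], X.shape[1]))
        if ok.any():
            r[np.ix_(ok, ok)] = np.corrcoef(X[:, ok], rowvar=False)
        return r**2
    M = finite.astype(np.float64)
    X0 = np.where(finite, X, 0.0)
    n = M.T @ M
    sx = X0.T @ M
    sxx = (X0**2).T @ M
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        cov = sxy / n - mean_x * mean_x.T
        var_x = sxx / n - mean_x**2
        r2 = cov**2 / (var_x * var_x.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 3] = 0.0
    return np.clip(r2, 0.0, 1.0)


def correlation_reduce(
    table: pd.DataFrame, r2_threshold: float = 0.8
) -> CorrelationReduction:
    """Collapse clusters of correlated features to single representatives.

    Clusters are connected components of the graph joining feature pairs
    with R² strictly above the threshold; the representative of a cluster
    is its member with the largest dynamic range (max − min over lesions),
    so a constant feature can never shadow a varying clustermate.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 lesions")
    names = list(table.columns)
    X = table.to_numpy(dtype=np.float64)
    r2 = _pairwise_r2(X)
    adj = sparse.csr_matrix(r2 > r2_threshold)
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    with np.errstate(invalid="ignore"):
        dyn_range = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    dyn_range = np.where(np.isfinite(dyn_range), dyn_range, -np.inf)
    clusters: list[list[str]] = []
    representatives: list[str] = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        members = [names[i] for i in idx]
        best = idx[np.argmax(dyn_range[idx])]
        clusters.append(members)
        representatives.append(names[best])
    order = np.argsort([names.index(r) for r in representatives])
    clusters = [clusters[i] for i in order]
    representatives = [representatives[i] for i in order]
    return CorrelationReduction(r2_threshold, clusters, representatives)


# --------------------------------------------------------------------------
# Mann-Whitney ranking over patient folds

@dataclass
class RankedFeatures:
    order: list[str]
    frequency: dict[str, int]
    median_p: dict[str, float]
    top_lists: list[list[str]]
    n_folds: int
    top_k: int


def mwu_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per feature column."""
    return stats.mannwhitneyu(
        X[y], X[~y], axis=0, alternative="two-sided"
    ).pvalue


def assign_patient_folds(
    patient_ids: np.ndarray,
    patient_positive: dict[str, bool],
    n_folds: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Outcome-stratified assignment of patients to folds."""
    patients = pd.unique(patient_ids)
    if len(patients) < n_folds:
        raise ValueError(
            f"{len(patients)} patients cannot form {n_folds} folds"
        )
    fold_of: dict[str, int] = {}
    nxt = 0
    for positive in (True, False):
        grp = [p for p in patients if patient_positive[p] == positive]
        grp = list(np.array(grp)[rng.permutation(len(grp))])
        for p in grp:
            fold_of[p] = nxt % n_folds
            nxt += 1
    return fold_of


def rank_features_mwu(
    table: pd.DataFrame,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    n_folds: int = 50,
    top_k: int = 15,
    rng: np.random.Generator | int | None = None,
) -> RankedFeatures:
    """Frequency-of-occurrence ranking over leave-one-fold-out subsets.

    For each of the ``n_folds`` subsets (all patients except one fold) the
    ``top_k`` features with the smallest Mann-Whitney p-values are
    recorded; features are ranked by occurrence frequency, ties broken by
    the median p-value across subsets, then by name.
    """
    rng = np.random.default_rng(rng)
    names = list(table.columns)
    X = table.to_numpy(dtype=np.float64)
    y = np.asarray(labels) == "LF" if np.asarray(labels).dtype.kind in "UO" else np.asarray(labels, bool)
    patient_ids = np.asarray(patient_ids)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    X = np.where(np.isfinite(X), X, med)

    pos_of = {
        p: bool(y[patient_ids == p].any()) for p in pd.unique(patient_ids)
    }
    fold_of = assign_patient_folds(patient_ids, pos_of, n_folds, rng)
    fold_idx = np.array([fold_of[p] for p in patient_ids])

    pvals = np.full((n_folds, len(names)), np.nan)
    top_lists: list[list[str]] = []
    for f in range(n_folds):
        keep = fold_idx != f
        yk = y[keep]
        if yk.all() or not yk.any():
            raise ValueError(
                f"fold {f}: retained patients contain a single outcome class"
            )
        pvals[f] = mwu_pvalues(X[keep], yk)
        top = np.argsort(pvals[f], kind="stable")[:top_k]
        top_lists.append([names[i] for i in top])

    freq = {n: 0 for n in names}
    for lst in top_lists:
        for n in lst:
            freq[n] += 1
    med_p = dict(zip(names, np.median(pvals, axis=0)))
    order = sorted(names, key=lambda n: (-freq[n], med_p[n], n))
    return RankedFeatures(order, freq, med_p, top_lists, n_folds, top_k)


# --------------------------------------------------------------------------
# bootstrap .632+ AUC

@dataclass
class Auc632Result:
    auc_resub: float
    auc_test_per_bootstrap: np.ndarray
    auc_632plus_per_bootstrap: np.ndarray
    n_bootstrap: int
    n_resampled: int = 0

    @property
    def auc_632plus(self) -> float:
        return float(self.auc_632plus_per_bootstrap.mean())


def combine_632plus(auc_resub: float, auc_test: float) -> float:
    """The .632+ blend of re-substitution and out-of-bag AUC.

    The no-information rate for AUC is 0.5; the test AUC is floored there.
    The overfitting ratio R grows from 0 (no optimism) to 1 (pure
    overfitting), moving the weight w from 0.632 towards 1.
    """
    auc_test = max(auc_test, 0.5)
    if auc_resub <= 0.5 or auc_resub <= auc_test:
        R = 0.0
    else:
        R = (auc_resub - auc_test) / (auc_resub - 0.5)
    R = min(max(R, 0.0), 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    return (1.0 - w) * auc_resub + w * auc_test


def _impute_standardize(train: np.ndarray, *others: np.ndarray):
    """Median-impute and z-score with statistics from the training rows only."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isfinite(train), train, med)
    mu = tr.mean(axis=0)
    sd = tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    out = [(tr - mu) / sd]
    for X in others:
        Xi = np.where(np.isfinite(X), X, med)
        out.append((Xi - mu) / sd)
    return out


def auc_632plus(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    spec: ClassifierSpec,
    n_bootstrap: int = 250,
    rng: np.random.Generator | int | None = None,
) -> Auc632Result:
    """Bootstrap .632+ AUC of a feature set under patient-level resampling.

    The re-substitution AUC is computed once on all lesions. For each
    bootstrap sample the majority class is first randomly under-sampled at
    the patient level to balance the lesion counts; patients are then drawn
    with replacement and the lesions of out-of-bag patients form the test
    set. Bootstraps whose out-of-bag set lacks a class are redrawn (count
    reported in ``n_resampled``).
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=bool)
    patient_ids = np.asarray(patient_ids)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    (Xs,) = _impute_standardize(X)
    clf = make_classifier(spec)
    clf.fit(Xs, y)
    auc_resub = fast_auc(clf.decision_function(Xs), y)

    patients = pd.unique(patient_ids)
    lesions_of = {p: np.flatnonzero(patient_ids == p) for p in patients}
    sampler = PatientSampler(patients, lesions_of, y)

    auc_test = np.empty(n_bootstrap)
    auc_b = np.empty(n_bootstrap)
    n_resampled = 0
    for b in range(n_bootstrap):
        for _ in range(100):
            tr_idx, te_idx = sampler.bootstrap(rng)
            if te_idx.size == 0:
                n_resampled += 1
                continue
            ytr, yte = y[tr_idx], y[te_idx]
            if ytr.all() or not ytr.any() or yte.all() or not yte.any():
                n_resampled += 1
                continue
            break
        else:
            raise RuntimeError("could not draw a valid bootstrap sample")
        Xtr, Xte = _impute_standardize(X[tr_idx], X[te_idx])
        clf = make_classifier(spec)
        clf.fit(Xtr, ytr)
        a = fast_auc(clf.decision_function(Xte), yte)
        auc_test[b] = a
        auc_b[b] = combine_632plus(auc_resub, a)
    return Auc632Result(float(auc_resub), auc_test, auc_b, n_bootstrap, n_resampled)


# --------------------------------------------------------------------------
# forward selection and ANOVA minimal set

@dataclass
class ForwardSelectionResult:
    pool: list[str]
    chosen: list[str]                     # greedy order, full pool
    trajectory: pd.DataFrame              # size, auc_632plus
    per_size_auc: list[np.ndarray]        # per-bootstrap AUC.632+ samples
    best_size: int

    @property
    def best_set(self) -> list[str]:
        return self.chosen[: self.best_size]

    @property
    def best_auc(self) -> float:
        return float(self.trajectory["auc_632plus"].iloc[self.best_size - 1])


@dataclass
class OptimalBiomarker:
    outcome: str
    features: list[str]
    auc_632plus: float
    mwu_p: dict[str, float]


def forward_select(
    ranked: RankedFeatures,
    table: pd.DataFrame,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    spec: ClassifierSpec,
    pool_size: int = 15,
    n_bootstrap: int = 250,
    rng: np.random.Generator | int | None = None,
) -> ForwardSelectionResult:
    """Greedy forward selection scored by the bootstrap .632+ AUC.

    At each step the pool feature maximizing the AUC of the augmented set
    is added (ties resolved in favour of the better-ranked feature); the
    best set is the trajectory's argmax, smaller size winning ties.
    """
    ss = np.random.SeedSequence(
        np.random.default_rng(rng).integers(2**31)
    )
    pool = ranked.order[:pool_size]
    y = np.asarray(labels) == "LF" if np.asarray(labels).dtype.kind in "UO" else np.asarray(labels, bool)
    X = table[pool].to_numpy(dtype=np.float64)
    col = {f: i for i, f in enumerate(pool)}

    chosen: list[str] = []
    per_size_auc: list[np.ndarray] = []
    traj_auc: list[float] = []
    remaining = list(pool)
    step_seeds = ss.spawn(len(pool))
    for step in range(len(pool)):
        best_feat = None
        best_auc = -np.inf
        best_res = None
        cand_seeds = step_seeds[step].spawn(len(remaining))
        for cand, cseed in zip(remaining, cand_seeds):
            cols = [col[f] for f in chosen + [cand]]
            res = auc_632plus(
                X[:, cols], y, patient_ids, spec, n_bootstrap,
                np.random.default_rng(cseed),
            )
            if res.auc_632plus > best_auc:
                best_auc = res.auc_632plus
                best_feat = cand
                best_res = res
        chosen.append(best_feat)
        remaining.remove(best_feat)
        per_size_auc.append(best_res.auc_632plus_per_bootstrap)
        traj_auc.append(best_auc)

    trajectory = pd.DataFrame(
        {"size": np.arange(1, len(pool) + 1), "auc_632plus": traj_auc}
    )
    best_size = int(np.argmax(traj_auc)) + 1
    return ForwardSelectionResult(pool, chosen, trajectory, per_size_auc, best_size)


def anova_minimal_set(
    fwd: ForwardSelectionResult,
    table: pd.DataFrame,
    labels: np.ndarray,
    outcome: str = "overall",
    alpha: float = 0.05,
) -> OptimalBiomarker:
    """Smallest nested feature set statistically on par with the best set.

    One-way ANOVA across the per-size bootstrap AUC samples (sizes 1..best);
    when the ANOVA is significant, each smaller size is compared with the
    best via Tukey's HSD and the smallest size not significantly worse is
    kept. A non-significant ANOVA means all sizes perform alike, so the
    single best-ranked feature suffices.
    """
    if not fwd.per_size_auc:
        raise ValueError("empty forward-selection trajectory")
    best = fwd.best_size
    y = np.asarray(labels) == "LF" if np.asarray(labels).dtype.kind in "UO" else np.asarray(labels, bool)
    if best == 1:
        size = 1
    else:
        samples = fwd.per_size_auc[:best]
        if all(np.allclose(s, samples[0]) for s in samples[1:]):
            size = 1
        else:
            _, p_anova = stats.f_oneway(*samples)
            if not np.isfinite(p_anova) or p_anova >= alpha:
                size = 1
            else:
                hsd = stats.tukey_hsd(*samples)
                size = best
                for s in range(1, best):
                    if hsd.pvalue[s - 1, best - 1] >= alpha:
                        size = s
                        break
    features = fwd.chosen[:size]
    auc = float(fwd.per_size_auc[size - 1].mean())
    med = table[features].apply(lambda c: c.fillna(c.median()))
    pvals = mwu_pvalues(med.to_numpy(dtype=np.float64), y)
    return OptimalBiomarker(outcome, features, auc, dict(zip(features, pvals)))
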