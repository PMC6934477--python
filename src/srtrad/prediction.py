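"""Lesion-level LC/LF prediction with bootstrap-ensembled SVM classifiers.

Each held-out patient (leave-one-patient-out, LOPO) is classified by the
majority vote of 250 SVMs, each trained on a patient-level bootstrap sample
of the remaining patients after patient-level under-sampling of the
majority class. The positive class throughout is LF (local failure), the
clinically actionable event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC


@dataclass(frozen=True)
class ClassifierSpec:
    """SVM configuration; Gaussian kernel for the overall and 12-month
    outcomes, linear for the 6-month outcome."""

    kernel: str = "rbf"        # "rbf" (Gaussian) | "linear"
    regularization: float = 1.0
    kernel_width: float | str = "auto"   # gamma; "auto" = 1/(p · feature variance)

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


def spec_for_outcome(outcome: str) -> ClassifierSpec:
    """The per-horizon kernel choice: linear for 6-month, Gaussian otherwise."""
    return ClassifierSpec(kernel="linear" if outcome == "m6" else "rbf")


def make_classifier(spec: ClassifierSpec) -> SVC:
    gamma = "scale" if spec.kernel_width == "auto" else spec.kernel_width
    return SVC(kernel=spec.kernel, C=spec.regularization, gamma=gamma)


def fast_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC of scores for boolean labels (ties averaged)."""
    y = np.asarray(y, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class PatientSampler:
    """Patient-level under-sampling + bootstrap machinery.

    Precomputes per-patient lesion indices and class counts once, so the
    per-bootstrap work is only the random draws. Under-sampling removes
    pure-majority-class patients in random order while removal brings the
    two lesion counts closer to equality; mixed-label patients are never
    dropped, so exact equality is not always reachable.
    """

    def __init__(self, patients, lesions_of: dict, y: np.ndarray) -> None:
        self.patients = list(patients)
        self.lesions = [np.asarray(lesions_of[p]) for p in self.patients]
        n_pos = np.array([int(y[l].sum()) for l in self.lesions])
        n_tot = np.array([len(l) for l in self.lesions])
        self.n_lesions = n_tot
        maj = n_pos.sum() > (n_tot.sum() - n_pos.sum())
        self.diff0 = int(abs(2 * n_pos.sum() - n_tot.sum()))
        self.pure_maj = np.flatnonzero(
            n_pos == n_tot if maj else n_pos == 0
        )

    def balanced_subset(self, rng: np.random.Generator) -> np.ndarray:
        """Indices (into ``self.patients``) of the under-sampled cohort."""
        drop = set()
        diff = self.diff0
        if diff > 0 and self.pure_maj.size:
            for i in rng.permutation(self.pure_maj.size):
                p = self.pure_maj[i]
                k = int(self.n_lesions[p])
                if abs(diff - k) < abs(diff):
                    drop.add(p)
                    diff -= k
                if diff <= 0:
                    break
        return np.array([i for i in range(len(self.patients)) if i not in drop])

    def bootstrap(self, rng: np.random.Generator):
        """One balanced patient bootstrap: (train lesion idx, oob lesion idx)."""
        keep = self.balanced_subset(rng)
        draw = rng.choice(keep, size=keep.size, replace=True)
        tr_idx = np.concatenate([self.lesions[i] for i in draw])
        in_bag = set(draw.tolist())
        oob = [i for i in keep if i not in in_bag]
        te_idx = (
            np.concatenate([self.lesions[i] for i in oob])
            if oob
            else np.empty(0, dtype=int)
        )
        return tr_idx, te_idx


def balance_patients(
    patients,
    lesions_of: dict,
    y: np.ndarray,
    rng: np.random.Generator,
) -> list:
    """Random patient-level under-sampling of the majority class."""
    sampler = PatientSampler(patients, lesions_of, y)
    keep = sampler.balanced_subset(rng)
    return [sampler.patients[i] for i in keep]


@dataclass
class PredictionResult:
    """Per-lesion LOPO votes plus pooled cross-validated metrics."""

    lesion_ids: list[str]
    patient_ids: list[str]
    truth: np.ndarray             # boolean, LF positive
    vote_fraction: np.ndarray     # votes for LF / n_bootstrap
    predicted: np.ndarray         # boolean
    n_bootstrap: int
    metrics: dict[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lesion_id": self.lesion_ids,
                "patient_id": self.patient_ids,
                "truth": np.where(self.truth, "LF", "LC"),
                "vote_fraction": self.vote_fraction,
                "predicted": np.where(self.predicted, "LF", "LC"),
            }
        )


def compute_metrics(predicted: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity and specificity with LF as positive class.

    A metric whose denominator class is absent from the truth is NaN.
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("misaligned label vectors")
    tp = int((predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    n_pos = tp + fn
    n_neg = tn + fp
    return {
        "accuracy": (tp + tn) / truth.size,
        "sensitivity": tp / n_pos if n_pos else np.nan,
        "specificity": tn / n_neg if n_neg else np.nan,
    }


def lopo_predict(
    table: pd.DataFrame,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    spec: ClassifierSpec,
    n_bootstrap: int = 250,
    rng: np.random.Generator | int | None = None,
    lesion_ids: list[str] | None = None,
) -> PredictionResult:
    """Leave-one-patient-out prediction by 250-classifier majority vote.

    For each held-out patient, ``n_bootstrap`` training samples are drawn
    from the remaining patients (under-sampling the majority class at
    patient level before each draw, then bootstrapping patients with
    replacement); each trains one SVM, and the held-out lesions take the
    majority label. An exact 50/50 vote is called LF (favouring
    sensitivity). Feature imputation and standardization use training
    statistics only.
    """
    from .selection import _impute_standardize  # shared leakage-guarded scaler

    rng = np.random.default_rng(rng)
    X = table.to_numpy(dtype=np.float64)
    labels = np.asarray(labels)
    y = labels == "LF" if labels.dtype.kind in "UO" else labels.astype(bool)
    patient_ids = np.asarray(patient_ids)
    patients = pd.unique(patient_ids)
    if (
        sum(y[patient_ids == p].any() for p in patients) < 2
        or sum((~y[patient_ids == p]).all() for p in patients) < 2
    ):
        raise ValueError("need at least 2 patients per class for LOPO")
    lesions_of = {p: np.flatnonzero(patient_ids == p) for p in patients}
    votes = np.zeros(len(y), dtype=np.int64)

    # one independent stream per held-out patient: the prediction for a
    # patient depends only on the other patients' data and their own features
    root = np.random.SeedSequence(rng.integers(2**31))
    streams = [np.random.default_rng(s) for s in root.spawn(len(patients))]

    for held_out, rng_p in zip(patients, streams):
        te_idx = lesions_of[held_out]
        train_patients = [p for p in patients if p != held_out]
        sampler = PatientSampler(train_patients, lesions_of, y)
        rng = rng_p
        for _ in range(n_bootstrap):
            for _attempt in range(100):
                tr_idx, _ = sampler.bootstrap(rng)
                ytr = y[tr_idx]
                if ytr.any() and not ytr.all():
                    break
            else:
                raise RuntimeError(
                    "training set collapsed to one class after under-sampling"
                )
            Xtr, Xte = _impute_standardize(X[tr_idx], X[te_idx])
            clf = make_classifier(spec)
            clf.fit(Xtr, ytr)
            votes[te_idx] += clf.predict(Xte).astype(np.int64)

    vote_fraction = votes / n_bootstrap
    predicted = vote_fraction >= 0.5
    metrics = compute_metrics(predicted, y)
    if lesion_ids is None:
        lesion_ids = list(table.index.astype(str))
    return PredictionResult(
        lesion_ids=list(lesion_ids),
        patient_ids=list(patient_ids),
        truth=y,
        vote_fraction=vote_fraction,
        predicted=predicted,
        n_bootstrap=n_bootstrap,
        metrics=metrics,
    )
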