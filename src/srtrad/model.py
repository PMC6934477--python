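"""Model/Results interface over the full biomarker-discovery chain.

`LocalFailureModel` holds a lesion × feature table with LC/LF labels and
patient identifiers; `fit()` runs correlation reduction, Mann-Whitney
ranking, forward selection on the bootstrap .632+ AUC, ANOVA minimal-set
reduction, and leave-one-patient-out outcome prediction, returning a
`LocalFailureResults` with the optimal biomarker, the selection
trajectory, cross-validated metrics and per-lesion votes.

Example
-------
>>> from srtrad.cohort import CohortConfig, generate_cohort
>>> from srtrad.features import extract_cohort_features
>>> from srtrad.model import LocalFailureModel
>>> lesions, survival = generate_cohort(CohortConfig(n_patients=60, seed=7))
>>> table = extract_cohort_features(lesions)
>>> labels = {l.lesion_id: l.label_overall for l in lesions}
>>> model = LocalFailureModel.from_dataframe(
...     table.assign(label=[labels[i] for i in table.index]),
...     label_col="label", patient_col="patient_id")
>>> results = model.fit(seed=0, n_bootstrap=50, n_folds=25)
>>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prediction import (
    ClassifierSpec,
    PredictionResult,
    lopo_predict,
    spec_for_outcome,
)
from .selection import (
    CorrelationReduction,
    ForwardSelectionResult,
    OptimalBiomarker,
    RankedFeatures,
    anova_minimal_set,
    auc_632plus,
    correlation_reduce,
    forward_select,
    rank_features_mwu,
)
from .survival import RiskAssessment, risk_assessment

OUTCOMES = ("overall", "m6", "m12")


class LocalFailureModel:
    """Radiomic LC/LF outcome model for one prediction horizon.

    Parameters
    ----------
    table : lesion × feature DataFrame (relative-change features).
    labels : per-lesion "LC"/"LF" (lesions labelled "excluded" must be
        dropped beforehand; `from_dataframe` does this).
    patient_ids : per-lesion patient identifier; all lesions of a patient
        stay on the same side of every train/test split.
    outcome : "overall", "m6" or "m12"; fixes the default SVM kernel
        (linear for m6, Gaussian otherwise).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        labels,
        patient_ids,
        outcome: str = "overall",
        r2_threshold: float = 0.8,
        classifier_spec: ClassifierSpec | None = None,
    ) -> None:
        if outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        labels = np.asarray(labels)
        if set(np.unique(labels)) - {"LC", "LF"}:
            raise ValueError("labels must be 'LC'/'LF' (drop excluded lesions)")
        self.table = table
        self.labels = labels
        self.patient_ids = np.asarray(patient_ids)
        self.outcome = outcome
        self.r2_threshold = r2_threshold
        self.spec = classifier_spec or spec_for_outcome(outcome)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str,
        patient_col: str = "patient_id",
        outcome: str = "overall",
        **kwargs,
    ) -> "LocalFailureModel":
        keep = df[label_col].isin(["LC", "LF"])
        df = df.loc[keep]
        features = df.drop(columns=[label_col, patient_col])
        return cls(
            features, df[label_col].to_numpy(), df[patient_col].to_numpy(),
            outcome=outcome, **kwargs,
        )

    @classmethod
    def from_cohort(
        cls,
        lesions,
        outcome: str = "overall",
        margin_mm: float = 3.0,
        **kwargs,
    ) -> "LocalFailureModel":
        """Extract features from synthetic lesions and build the model."""
        from .features import extract_cohort_features

        table = extract_cohort_features(lesions, margin_mm=margin_mm)
        label_attr = {
            "overall": "label_overall", "m6": "label_6mo", "m12": "label_12mo"
        }[outcome]
        labels = pd.Series(
            {l.lesion_id: getattr(l, label_attr) for l in lesions}
        ).reindex(table.index)
        df = table.assign(_label=labels)
        return cls.from_dataframe(
            df, label_col="_label", patient_col="patient_id", outcome=outcome,
            **kwargs,
        )

    def fit(
        self,
        seed: int = 0,
        n_folds: int = 50,
        top_k: int = 15,
        pool_size: int = 15,
        n_bootstrap: int = 250,
    ) -> "LocalFailureResults":
        """Run the full selection + LOPO-prediction chain."""
        rng = np.random.default_rng(seed)
        reduction = correlation_reduce(self.table, self.r2_threshold)
        reduced = self.table[reduction.representatives]
        ranked = rank_features_mwu(
            reduced, self.labels, self.patient_ids,
            n_folds=n_folds, top_k=top_k,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        fwd = forward_select(
            ranked, reduced, self.labels, self.patient_ids, self.spec,
            pool_size=pool_size, n_bootstrap=n_bootstrap,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        biomarker = anova_minimal_set(
            fwd, reduced, self.labels, outcome=self.outcome
        )
        prediction = lopo_predict(
            self.table[biomarker.features], self.labels, self.patient_ids,
            self.spec, n_bootstrap=n_bootstrap,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        return LocalFailureResults(
            model=self,
            reduction=reduction,
            ranked=ranked,
            forward=fwd,
            biomarker=biomarker,
            prediction=prediction,
            seed=seed,
            n_bootstrap=n_bootstrap,
        )


@dataclass
class LocalFailureResults:
    """Fitted biomarker, selection trajectory and cross-validated metrics."""

    model: LocalFailureModel
    reduction: CorrelationReduction
    ranked: RankedFeatures
    forward: ForwardSelectionResult
    biomarker: OptimalBiomarker
    prediction: PredictionResult
    seed: int
    n_bootstrap: int

    @property
    def metrics(self) -> dict[str, float]:
        return self.prediction.metrics

    @property
    def auc_632plus(self) -> float:
        return self.biomarker.auc_632plus

    def predictions_frame(self) -> pd.DataFrame:
        return self.prediction.frame()

    def risk_stratification(
        self,
        times: pd.Series,
        events: pd.Series,
        unit: str = "lesion",
    ) -> RiskAssessment:
        """Kaplan-Meier comparison of the predicted LC vs LF cohorts."""
        return risk_assessment(self.predictions_frame(), times, events, unit)

    def summary(self) -> str:
        n = len(self.model.labels)
        n_lf = int((self.model.labels == "LF").sum())
        lines = [
            "Local-failure radiomic biomarker"
            f" — outcome: {self.model.outcome}",
            "=" * 58,
            f"lesions: {n} ({n_lf} LF / {n - n_lf} LC), "
            f"patients: {len(pd.unique(self.model.patient_ids))}",
            f"features: {self.reduction.n_features} -> "
            f"{len(self.reduction.representatives)} after R^2 > "
            f"{self.reduction.r2_threshold:g} reduction",
            f"kernel: {self.model.spec.kernel}, bootstraps: {self.n_bootstrap}, "
            f"seed: {self.seed}",
            "-" * 58,
            f"max AUC.632+: {self.forward.best_auc:.3f} "
            f"({self.forward.best_size} features)",
            f"optimal biomarker AUC.632+: {self.biomarker.auc_632plus:.3f} "
            f"({len(self.biomarker.features)} features)",
            "-" * 58,
            f"{'feature':<48}  MWU p",
        ]
        for f in self.biomarker.features:
            lines.append(f"{f:<48}  {self.biomarker.mwu_p[f]:.2g}")
        m = self.metrics
        lines += [
            "-" * 58,
            f"LOPO accuracy:    {m['accuracy']:.2%}",
            f"LOPO sensitivity: {m['sensitivity']:.2%}  (LF positive)",
            f"LOPO specificity: {m['specificity']:.2%}",
        ]
        return "\n".join(lines)
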