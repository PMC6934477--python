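"""End-to-end orchestration: synthesize → extract → select → predict → risk.

One seeded configuration drives every stage; rerunning with the same
configuration reproduces the CSV/JSON artifacts bit-identically. Stage
outputs land in a run directory together with a provenance manifest
(package version, configuration, derived stage seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort, recovered_controls
from .features import extract_cohort_features
from .model import LocalFailureModel


@dataclass
class PipelineConfig:
    """Defaults match the emulated study's printed parameters
    (R² = 0.8, 50 folds, top 15, 250 bootstraps, 3 mm margin)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    outcome: str = "overall"
    margin_mm: float = 3.0
    r2_threshold: float = 0.8
    n_folds: int = 50
    top_k: int = 15
    pool_size: int = 15
    n_bootstrap: int = 250
    seed: int = 0
    save_volumes: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


logger = logging.getLogger("srtrad.pipeline")


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, write artifacts, return the summary dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    logger.info("config hash %s", config.config_hash())

    logger.info("stage 1/5: synthesizing cohort (%d patients, seed %d)",
                config.cohort.n_patients, config.cohort.seed)
    lesions, survival = generate_cohort(config.cohort)
    if config.save_volumes:
        from .io import save_cohort

        save_cohort(lesions, survival, outdir / "cohort")

    logger.info("stage 2/5: extracting features for %d lesions", len(lesions))
    table = extract_cohort_features(lesions, margin_mm=config.margin_mm)
    table.to_csv(outdir / "features.csv")

    label_attr = {
        "overall": "label_overall", "m6": "label_6mo", "m12": "label_12mo"
    }[config.outcome]
    labels = pd.Series({l.lesion_id: getattr(l, label_attr) for l in lesions})
    labels.rename("label").to_csv(outdir / "labels.csv")

    model = LocalFailureModel.from_dataframe(
        table.assign(_label=labels.reindex(table.index)),
        label_col="_label",
        patient_col="patient_id",
        outcome=config.outcome,
        r2_threshold=config.r2_threshold,
    )
    logger.info("stage 3/5: selection + stage 4/5: LOPO prediction "
                "(%d bootstraps)", config.n_bootstrap)
    results = model.fit(
        seed=config.seed,
        n_folds=config.n_folds,
        top_k=config.top_k,
        pool_size=config.pool_size,
        n_bootstrap=config.n_bootstrap,
    )

    pd.DataFrame(
        {
            "feature": results.ranked.order,
            "frequency": [results.ranked.frequency[f] for f in results.ranked.order],
            "median_p": [results.ranked.median_p[f] for f in results.ranked.order],
        }
    ).to_csv(outdir / "ranking.csv", index=False)
    results.forward.trajectory.to_csv(outdir / "trajectory.csv", index=False)
    cluster_rows = [
        {"feature": f, "cluster": i, "representative": rep}
        for i, (cl, rep) in enumerate(
            zip(results.reduction.clusters, results.reduction.representatives)
        )
        for f in cl
    ]
    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.csv", index=False)
    (outdir / "biomarker.json").write_text(
        json.dumps(
            {
                "outcome": config.outcome,
                "features": results.biomarker.features,
                "auc_632plus": results.biomarker.auc_632plus,
                "mwu_p": results.biomarker.mwu_p,
            },
            indent=2,
        )
    )
    results.predictions_frame().to_csv(outdir / "predictions.csv", index=False)

    # risk stratification: local control at lesion level, OS at patient level
    lc_times = pd.Series(
        {
            l.lesion_id: (
                l.lf_time_months
                if l.label_overall == "LF"
                else l.followup_months
            )
            for l in lesions
        }
    )
    lc_events = pd.Series(
        {l.lesion_id: l.label_overall == "LF" for l in lesions}
    )
    os_times = pd.Series({s.patient_id: s.time_months for s in survival})
    os_events = pd.Series({s.patient_id: s.event for s in survival})
    logger.info("stage 5/5: Kaplan-Meier risk stratification")
    risk_lesion = results.risk_stratification(lc_times, lc_events, unit="lesion")
    risk_patient = results.risk_stratification(os_times, os_events, unit="patient")

    summary = {
        "n_patients": config.cohort.n_patients,
        "n_lesions": len(lesions),
        "n_lesions_analysed": int(len(model.labels)),
        "n_features": int(table.shape[1] - 1),
        "n_after_reduction": len(results.reduction.representatives),
        "biomarker": results.biomarker.features,
        "n_biomarker_features": len(results.biomarker.features),
        "recovered_controls": sorted(
            recovered_controls(results.biomarker.features, config.cohort)
        ),
        "auc_632plus_max": results.forward.best_auc,
        "auc_632plus_biomarker": results.biomarker.auc_632plus,
        **{f"lopo_{k}": v for k, v in results.metrics.items()},
        "logrank_p_local_control": risk_lesion.logrank.p_value,
        "logrank_p_survival": risk_patient.logrank.p_value,
    }
    manifest = {
        "srtrad_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("done: %s", {k: v for k, v in summary.items() if "logrank" in k})
    logger.removeHandler(handler)
    handler.close()
    return summary
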