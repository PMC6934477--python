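"""NIfTI and CSV input/output for cohorts, masks and feature tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import SurvivalRecord, SyntheticLesion

_VOLUME_KEYS = (
    "t1w_baseline",
    "t1w_followup",
    "flair_baseline",
    "flair_followup",
)


def _affine(voxel_mm) -> np.ndarray:
    return np.diag(list(voxel_mm) + [1.0])


def save_nifti(path, data: np.ndarray, voxel_mm) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_mm))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), zooms


def save_cohort(lesions, survival, outdir) -> Path:
    """Write volumes/masks as .nii.gz plus manifest.csv and survival.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    voldir = outdir / "volumes"
    voldir.mkdir(exist_ok=True)
    rows = []
    for les in lesions:
        paths = {}
        for key in _VOLUME_KEYS:
            p = voldir / f"{les.lesion_id}_{key}.nii.gz"
            save_nifti(p, getattr(les, key).astype(np.float32), les.voxel_size_mm)
            paths[key] = str(p.relative_to(outdir))
        for key in ("tumour_mask", "edema_mask"):
            p = voldir / f"{les.lesion_id}_{key}.nii.gz"
            save_nifti(p, getattr(les, key).astype(np.uint8), les.voxel_size_mm)
            paths[key] = str(p.relative_to(outdir))
        rows.append(
            {
                "patient_id": les.patient_id,
                "lesion_id": les.lesion_id,
                **paths,
                "label_overall": les.label_overall,
                "label_6mo": les.label_6mo,
                "label_12mo": les.label_12mo,
                "lf_time_months": les.lf_time_months,
                "followup_months": les.followup_months,
                "true_effect_flags": ";".join(les.true_effect_flags),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": s.patient_id, "time_months": s.time_months, "event": s.event}
            for s in survival
        ]
    ).to_csv(outdir / "survival.csv", index=False)
    return outdir


def load_cohort(outdir) -> tuple[list[SyntheticLesion], list[SurvivalRecord]]:
    """Inverse of :func:`save_cohort`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    lesions = []
    for _, row in manifest.iterrows():
        vols = {}
        voxel = None
        for key in _VOLUME_KEYS:
            vols[key], voxel = load_nifti(outdir / row[key])
            vols[key] = vols[key].astype(np.float32)
        masks = {}
        for key in ("tumour_mask", "edema_mask"):
            m, _ = load_nifti(outdir / row[key])
            masks[key] = m > 0.5
        flags = row.get("true_effect_flags", "")
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        lesions.append(
            SyntheticLesion(
                patient_id=row["patient_id"],
                lesion_id=row["lesion_id"],
                **vols,
                **masks,
                voxel_size_mm=voxel,
                label_overall=row["label_overall"],
                label_6mo=row["label_6mo"],
                label_12mo=row["label_12mo"],
                true_effect_flags=flags,
                lf_time_months=float(row["lf_time_months"]),
                followup_months=float(row["followup_months"]),
            )
        )
    sdf = pd.read_csv(outdir / "survival.csv")
    survival = [
        SurvivalRecord(r["patient_id"], float(r["time_months"]), bool(r["event"]))
        for _, r in sdf.iterrows()
    ]
    return lesions, survival


def save_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
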