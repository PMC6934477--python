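"""Per-lesion extraction of the 3072 relative-change features.

For each of the 8 (region × sequence) blocks, 384 features are computed at
baseline and first follow-up: 8 geometric + 16 first-order + 16 LBP-code
first-order + 24 GLCM on the original image, plus (16 + 24) on each of the
8 wavelet sub-band images. Every feature is reported as the relative change
from baseline,

    delta_f = (f_followup - f_baseline) / (|f_baseline| + eps),

with eps tied to the in-mask intensity scale and delta_f winsorized at ±10
so a near-zero baseline cannot dominate downstream ranking. Degenerate
sub-regions (empty or single-level) propagate NaNs, never silent zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..masks import SubLesionMasks
from .firstorder import histogram_statistics, histogram_statistics_matrix
from .geometric import geometric_features
from .glcm import GLCMSpec, glcm_features_from_pairs_multi, region_pair_indices
from .lbp import lbp_map
from .names import (
    FeatureName,
    N_FEATURES,
    REGIONS,
    SEQUENCES,
    WAVELET_BANDS,
    all_feature_names,
)
from .wavelet import band_images

WINSOR_LIMIT = 10.0
EPS_SCALE = 1e-9

from functools import lru_cache


@lru_cache(maxsize=None)
def _name_table(region: str, filt: str, family: str, sequence: str) -> dict[str, str]:
    """stat -> full feature-name string, precomputed once per block."""
    from .names import GLCM_STATS, HISTOGRAM_STATS

    stats = GLCM_STATS if family == "GLCM" else HISTOGRAM_STATS
    return {
        s: str(FeatureName(region, filt, family, s, sequence)) for s in stats
    }


def relative_change(f_bl: float, f_fu: float, scale: float) -> float:
    """Winsorized relative change from baseline."""
    if not (np.isfinite(f_bl) and np.isfinite(f_fu)):
        return np.nan
    eps = EPS_SCALE * scale + 1e-300
    delta = (f_fu - f_bl) / (abs(f_bl) + eps)
    return float(np.clip(delta, -WINSOR_LIMIT, WINSOR_LIMIT))


def _crop_bbox(masks: SubLesionMasks, pad: int, shape: tuple[int, ...]):
    union = np.zeros(shape, dtype=bool)
    for m in masks.regions().values():
        union |= m
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, shape)
    # align the crop origin to even indices so the wavelet phase does not
    # depend on where the lesion happens to sit in the volume
    lo = lo - (lo % 2)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _timepoint_block(
    image: np.ndarray,
    pair_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    sequence: str,
    glcm_spec: GLCMSpec,
    wavelet: str,
) -> dict[str, float]:
    """All intensity-based features of one image at one timepoint.

    ``pair_cache`` maps region name to (flat voxel indices, pair indices)
    from :func:`~srtrad.features.glcm.region_pair_indices`; reusing it
    across the 18 image/filter combinations of a lesion is what keeps
    whole-cohort extraction fast.
    """
    out: dict[str, float] = {}
    codes_flat = lbp_map(image).ravel()
    bands = {
        b: img.ravel().astype(np.float32)
        for b, img in band_images(image, wavelet).items()
    }
    flat = image.ravel().astype(np.float32)
    n = glcm_spec.n_grey_levels
    filters = ("Original",) + WAVELET_BANDS
    for region, (voxel_idx, ra, rb) in pair_cache.items():
        V = np.column_stack(
            [flat[voxel_idx]] + [bands[b][voxel_idx] for b in WAVELET_BANDS]
        )
        hist_tables = [
            _name_table(region, f, "Histogram", sequence) for f in filters
        ]
        for stat, arr in histogram_statistics_matrix(V).items():
            for k, names in enumerate(hist_tables):
                out[names[stat]] = float(arr[k])
        lbp_vals = codes_flat[voxel_idx].astype(np.float64)
        names = _name_table(region, "Original", "LBP", sequence)
        for stat, v in histogram_statistics(lbp_vals).items():
            out[names[stat]] = v
        glcm_tables = [_name_table(region, f, "GLCM", sequence) for f in filters]
        for stat, arr in glcm_features_from_pairs_multi(V, ra, rb, n).items():
            for k, names in enumerate(glcm_tables):
                out[names[stat]] = float(arr[k])
    return out


def extract_lesion_features(
    baseline: dict[str, np.ndarray],
    followup: dict[str, np.ndarray],
    masks: SubLesionMasks,
    glcm_spec: GLCMSpec = GLCMSpec(),
    wavelet: str = "haar",
) -> pd.Series:
    """The 3072-long relative-change feature vector of one lesion.

    ``baseline`` and ``followup`` map sequence ("T1", "T2") to co-registered
    3D volumes on the masks' grid; the same mask set is applied at both
    timepoints (the synthetic pipeline generates time-invariant geometry).
    """
    shape = masks.tumour.shape
    for seq in SEQUENCES:
        for imgs in (baseline, followup):
            if imgs[seq].shape != shape:
                raise ValueError("image and mask grids differ")
    sl = _crop_bbox(masks, pad=4, shape=shape)
    region_masks = {r: m[sl] for r, m in masks.regions().items()}
    pair_cache = {
        r: region_pair_indices(m, glcm_spec) for r, m in region_masks.items()
    }
    geo_cache = {
        r: geometric_features(m, masks.voxel_size_mm) for r, m in region_masks.items()
    }

    features: dict[str, float] = {}
    for seq in SEQUENCES:
        img_bl = np.ascontiguousarray(np.asarray(baseline[seq])[sl], dtype=np.float64)
        img_fu = np.ascontiguousarray(np.asarray(followup[seq])[sl], dtype=np.float64)
        scale = float(np.abs(img_bl).mean()) or 1.0
        f_bl = _timepoint_block(img_bl, pair_cache, seq, glcm_spec, wavelet)
        f_fu = _timepoint_block(img_fu, pair_cache, seq, glcm_spec, wavelet)
        for name in f_bl:
            features[name] = relative_change(f_bl[name], f_fu[name], scale)
        # geometric features are computed per sequence from the (shared)
        # masks; with one mask set per lesion their relative change is 0
        for region, geo in geo_cache.items():
            for stat, v in geo.items():
                name = str(FeatureName(region, "Original", "Geometric", stat, seq))
                features[name] = 0.0 if np.isfinite(v) else np.nan

    ordered = pd.Series(features).reindex(all_feature_names())
    assert len(ordered) == N_FEATURES
    return ordered


def extract_cohort_features(
    lesions,
    margin_mm: float = 3.0,
    glcm_spec: GLCMSpec = GLCMSpec(),
    wavelet: str = "haar",
) -> pd.DataFrame:
    """Feature table (lesions × 3072) for a list of synthetic lesions.

    Returns a DataFrame indexed by lesion_id with a ``patient_id`` column
    attached as the first column, followed by the 3072 feature columns.
    """
    from ..masks import make_margin_masks

    rows = {}
    patients = {}
    for les in lesions:
        masks = make_margin_masks(
            les.tumour_mask, les.edema_mask, les.voxel_size_mm, margin_mm
        )
        rows[les.lesion_id] = extract_lesion_features(
            {"T1": les.t1w_baseline, "T2": les.flair_baseline},
            {"T1": les.t1w_followup, "T2": les.flair_followup},
            masks,
            glcm_spec,
            wavelet,
        )
        patients[les.lesion_id] = les.patient_id
    table = pd.DataFrame(rows).T
    table.index.name = "lesion_id"
    table.insert(0, "patient_id", pd.Series(patients))
    return table


def parametric_map(
    image: np.ndarray,
    mask: np.ndarray,
    statistic: str,
    patch_radius: int = 2,
) -> np.ndarray:
    """Patch-wise map of a first-order statistic for visual QA.

    For every in-mask voxel the statistic is computed over the cubic patch
    of half-width ``patch_radius`` intersected with the mask. Out-of-mask
    voxels are NaN. A constant image yields a constant map wherever the
    statistic is defined.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    out = np.full(image.shape, np.nan)
    r = patch_radius
    for x, y, z in np.argwhere(mask):
        sl = tuple(
            slice(max(c - r, 0), min(c + r + 1, s))
            for c, s in zip((x, y, z), image.shape)
        )
        vals = image[sl][mask[sl]]
        out[x, y, z] = histogram_statistics(vals)[statistic]
    return out
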