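"""Synthetic cohort generator: determinism, structure, planted effects."""

import numpy as np
import pytest
from scipy import stats

from srtrad.cohort import (
    CohortConfig,
    DEFAULT_CONTROLS,
    generate_cohort,
    generate_texture_volume,
    null_config,
    recovered_controls,
)


def test_seed_determinism_bit_identical():
    cfg = CohortConfig(n_patients=4, seed=42)
    a_lesions, a_surv = generate_cohort(cfg)
    b_lesions, b_surv = generate_cohort(cfg)
    assert len(a_lesions) == len(b_lesions)
    for la, lb in zip(a_lesions, b_lesions):
        assert np.array_equal(la.t1w_followup, lb.t1w_followup)
        assert np.array_equal(la.flair_baseline, lb.flair_baseline)
        assert np.array_equal(la.tumour_mask, lb.tumour_mask)
        assert la.label_overall == lb.label_overall
    for sa, sb in zip(a_surv, b_surv):
        assert sa.time_months == sb.time_months and sa.event == sb.event


def test_lesion_count_matches_multiplicity_expectation():
    # E[lesions/patient] = 0.73 + 2*0.20 + 3*0.07 = 1.34 -> ~134 per 100
    cfg = CohortConfig(n_patients=100, seed=1)
    lesions, survival = generate_cohort(cfg)
    assert len(survival) == 100
    n = len(lesions)
    # binomial-ish noise around 134: sd ~ sqrt(100*Var(count)) ~ 6
    assert 110 <= n <= 158
    counts = {}
    for l in lesions:
        counts[l.patient_id] = counts.get(l.patient_id, 0) + 1
    assert set(counts.values()) <= {1, 2, 3}


def test_mask_structure_edema_is_shell(small_cohort):
    _, lesions, _ = small_cohort
    for l in lesions:
        assert l.tumour_mask.any() and l.edema_mask.any()
        assert not (l.tumour_mask & l.edema_mask).any()
        for vol in (l.t1w_baseline, l.flair_followup):
            assert vol.shape == l.tumour_mask.shape


def test_horizon_labels_consistent(small_cohort):
    _, lesions, _ = small_cohort
    for l in lesions:
        assert l.label_overall in ("LC", "LF")
        assert l.label_6mo in ("LC", "LF", "excluded")
        if l.label_overall == "LC":
            assert l.label_6mo != "LF" and l.label_12mo != "LF"
            assert np.isnan(l.lf_time_months)
        else:
            assert 0 < l.lf_time_months <= l.followup_months + 1e-9


def test_oversized_lesion_rejected():
    cfg = CohortConfig(
        n_patients=1, seed=0, grid_shape=(16, 16, 16),
        tumour_radius_range_mm=(5.0, 6.0),
    )
    with pytest.raises(ValueError, match="fit"):
        generate_cohort(cfg)


def test_planted_effect_size_recovered():
    """Direct control feature separates classes by roughly the configured d."""
    d_target = 1.5
    ds = []
    for seed in range(3):
        lesions, _ = generate_cohort(CohortConfig(seed=seed))
        y = np.array([l.label_overall == "LF" for l in lesions])
        vals = np.array(
            [
                (l.flair_followup[l.edema_mask].std() - l.flair_baseline[l.edema_mask].std())
                / abs(l.flair_baseline[l.edema_mask].std())
                for l in lesions
            ]
        )
        a, b = vals[y], vals[~y]
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        ds.append((a.mean() - b.mean()) / sp)
    assert np.mean(ds) == pytest.approx(d_target, abs=0.3)


def test_null_cohort_has_no_class_signal():
    lesions, _ = generate_cohort(null_config(CohortConfig(seed=3)))
    assert all(l.true_effect_flags == () for l in lesions)
    y = np.array([l.label_overall == "LF" for l in lesions])
    pvals = []
    for fn in (
        lambda l, m: l.flair_followup[m].std() - l.flair_baseline[m].std(),
        lambda l, m: l.t1w_followup[m].mean() - l.t1w_baseline[m].mean(),
        lambda l, m: l.flair_followup[m].mean() - l.flair_baseline[m].mean(),
    ):
        vals = np.array([fn(l, l.edema_mask) for l in lesions])
        pvals.append(stats.mannwhitneyu(vals[y], vals[~y]).pvalue)
    assert min(pvals) > 0.001  # no systematic separation


def test_survival_hazard_linked_to_lf():
    cfg = CohortConfig(n_patients=200, seed=9, censor_rate=0.0)
    lesions, survival = generate_cohort(cfg)
    lf_patients = {l.patient_id for l in lesions if l.label_overall == "LF"}
    t = np.array([s.time_months for s in survival])
    is_lf = np.array([s.patient_id in lf_patients for s in survival])
    # hazard ratio 3 -> mean LF survival much shorter
    assert t[is_lf].mean() < 0.6 * t[~is_lf].mean()


def test_texture_volume_contract():
    grid = generate_texture_volume((24, 24, 24), 5.0, 2.0, 0.0, rng=1)
    assert grid.mean() == pytest.approx(5.0, abs=0.1)
    assert grid.std() == pytest.approx(2.0, abs=0.1)
    a = generate_texture_volume((12, 12, 12), 0.0, 1.0, 1.0, rng=5)
    b = generate_texture_volume((12, 12, 12), 0.0, 1.0, 1.0, rng=5)
    assert np.array_equal(a, b)
    # smoothed field keeps unit marginal variance but gains autocorrelation
    smooth = generate_texture_volume((32, 32, 32), 0.0, 1.0, 1.0, rng=2)
    white = generate_texture_volume((32, 32, 32), 0.0, 1.0, 0.0, rng=2)
    def lag1(f):
        return np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1]
    assert lag1(smooth) > lag1(white) + 0.3
    assert smooth.std() == pytest.approx(1.0, abs=0.05)
    with pytest.raises(ValueError):
        generate_texture_volume((8, 8, 8), 0.0, -1.0, 1.0)


def test_anisotropic_acquisition_round_trip(small_cohort):
    from srtrad.cohort import simulate_anisotropic
    from srtrad.masks import resample_isotropic

    _, lesions, _ = small_cohort
    les = lesions[0]
    bl, _ = simulate_anisotropic(les, slice_thickness_mm=1.5, sequence="T1")
    assert bl.voxel_size_mm == (0.5, 0.5, 1.5)
    assert bl.image.shape[2] == les.t1w_baseline.shape[2] // 3
    iso = resample_isotropic(bl, 0.5)
    assert iso.voxel_size_mm == (0.5, 0.5, 0.5)
    # slab averaging then linear interpolation approximates the original
    nz = min(iso.image.shape[2], les.t1w_baseline.shape[2])
    orig = np.asarray(les.t1w_baseline[:, :, :nz], dtype=np.float64)
    corr = np.corrcoef(iso.image[:, :, :nz].ravel(), orig.ravel())[0, 1]
    assert corr > 0.7
    with pytest.raises(ValueError):
        simulate_anisotropic(les, 0.25)


def test_planted_feature_attribution():
    cfg = CohortConfig()
    feats = [
        "Edema_Wavelet_I_HLH__Histogram_Maximum_T2",  # edema_t2_sigma block
        "Tumour-Margin_GLCM_Contrast_T1",             # margin_t1_sigma block
        "Edema_LBP_Median_T1",                        # boundary-mediated, edema T1
        "Tumour_Geometric_Convexity_T2",              # geometric: never attributed
        "Tumour_Histogram_Mean_T1",                   # tumour-T1: no control there
    ]
    from srtrad.cohort import attributable_features

    assert attributable_features(feats, cfg) == feats[:3]
    hits = recovered_controls(feats, cfg)
    assert hits == {"edema_t2_sigma", "margin_t1_sigma", "edema_t1_mean"}
    assert {c.name for c in DEFAULT_CONTROLS} == set(cfg.effect_features)
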