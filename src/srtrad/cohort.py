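"""Synthetic brain-metastasis imaging cohort.

Generates a statistically controllable stand-in for a stereotactic
radiotherapy (SRT) study cohort: ~100 patients with 1–3 lesions each, paired
T1w-like and T2-FLAIR-like volumes at baseline and first follow-up, tumour
and edema masks, local-control (LC) / local-failure (LF) labels at three
horizons, and survival records whose hazard depends on the patient's LF
status.

Each lesion is a spherical tumour core with a surrounding edema shell on a
background of brain-like tissue. Intensities are zone-wise constant plus a
stationary Gaussian random field; per-lesion latent offsets of the zone
means and noise amplitudes create realistic between-lesion variability.
Class-dependent texture change is *planted* through named effect controls:
for LF lesions, at follow-up only, the latent mean (or noise amplitude) of
a chosen zone/sequence is shifted by an amount calibrated so the relative
change of the corresponding first-order feature differs between classes by
a standardized effect size ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .features.names import FeatureName

# intensity priors per sequence and tissue zone (arbitrary MR-like units)
ZONE_MEANS = {
    "T1": {"background": 100.0, "tumour": 140.0, "edema": 85.0},
    "T2": {"background": 100.0, "tumour": 120.0, "edema": 160.0},
}
ZONES = ("background", "tumour", "edema")
_LOCATION_STATS = (
    "Mean", "Median", "Minimum", "Maximum", "Percentile10", "Percentile90", "Energy",
)
_DISPERSION_STATS = (
    "Variance", "StandardDeviation", "Range", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "InterquartileRange",
)
_ZONE_REGIONS = {
    "tumour": ("Tumour",),
    "edema": ("Edema",),
    "background": ("Tumour-Margin", "Lesion-Margin"),
}


@dataclass(frozen=True)
class EffectControl:
    """A named texture control: which zone/sequence/property LF perturbs."""

    name: str
    zone: str        # tumour | edema | background
    sequence: str    # T1 | T2
    kind: str        # mean | sigma

    def feature_names(self) -> tuple[str, ...]:
        """First-order features (original filter) directly driven by this control."""
        stats = _LOCATION_STATS if self.kind == "mean" else _DISPERSION_STATS
        return tuple(
            str(FeatureName(region, "Original", "Histogram", s, self.sequence))
            for region in _ZONE_REGIONS[self.zone]
            for s in stats
        )

    def affected_blocks(self) -> tuple[tuple[str, str], ...]:
        """(region, sequence) blocks whose follow-up image statistics the
        control perturbs (through the zone's latent mean/amplitude)."""
        return tuple(
            (region, self.sequence) for region in _ZONE_REGIONS[self.zone]
        )


DEFAULT_CONTROLS: tuple[EffectControl, ...] = (
    EffectControl("edema_t2_sigma", "edema", "T2", "sigma"),
    EffectControl("margin_t2_mean", "background", "T2", "mean"),
    EffectControl("tumour_t2_mean", "tumour", "T2", "mean"),
    EffectControl("edema_t1_mean", "edema", "T1", "mean"),
    EffectControl("margin_t1_sigma", "background", "T1", "sigma"),
)
_CONTROLS_BY_NAME = {c.name: c for c in DEFAULT_CONTROLS}


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the emulated clinical study: 100 patients with 1–3
    lesions (73/20/7%), ≈40% overall LF, 0.5 mm isotropic grids, and an
    overall-survival hazard three times higher for LF patients.
    """

    n_patients: int = 100
    lesions_per_patient_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.73, 2: 0.20, 3: 0.07}
    )
    lf_fraction: float = 0.4
    grid_shape: tuple[int, int, int] = (36, 36, 36)
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    tumour_radius_range_mm: tuple[float, float] = (2.0, 3.0)
    edema_thickness_range_mm: tuple[float, float] = (1.0, 2.5)
    effect_features: tuple[str, ...] = tuple(c.name for c in DEFAULT_CONTROLS)
    effect_size: float = 1.5
    noise_sigma: float = 10.0
    correlation_length_mm: float = 0.5
    regional_tau: float = 6.0        # s.d. of per-lesion zone-mean offsets
    sigma_jitter: float = 0.20       # s.d. of per-lesion relative noise-amplitude jitter
    hazard_lc: float = 0.045         # overall-survival event rate, 1/month
    hazard_lf: float = 0.135
    lf_event_rate: float = 0.15      # time-to-local-failure rate, 1/month
    censor_rate: float = 0.02        # independent censoring rate, 1/month
    max_followup_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.array(list(self.lesions_per_patient_probs.values()), dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("lesion-count probabilities must be >= 0 and sum to 1")
        if not 0.0 <= self.lf_fraction <= 1.0:
            raise ValueError("lf_fraction must be a probability")
        if self.tumour_radius_range_mm[0] <= 0:
            raise ValueError("tumour radius must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        unknown = set(self.effect_features) - set(_CONTROLS_BY_NAME)
        if unknown:
            raise ValueError(f"unknown effect controls: {sorted(unknown)}")

    @property
    def controls(self) -> tuple[EffectControl, ...]:
        return tuple(_CONTROLS_BY_NAME[n] for n in self.effect_features)

    def planted_feature_map(self) -> dict[str, tuple[str, ...]]:
        """control name -> feature names directly driven by it."""
        return {c.name: c.feature_names() for c in self.controls}


@dataclass
class SyntheticLesion:
    """Images, masks, labels and event times of one synthetic lesion."""

    patient_id: str
    lesion_id: str
    t1w_baseline: np.ndarray
    t1w_followup: np.ndarray
    flair_baseline: np.ndarray
    flair_followup: np.ndarray
    tumour_mask: np.ndarray
    edema_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    label_overall: str      # LC | LF
    label_6mo: str          # LC | LF | excluded
    label_12mo: str
    true_effect_flags: tuple[str, ...]
    lf_time_months: float   # NaN for LC lesions
    followup_months: float  # local-control censoring time

    def volumes(self) -> dict[tuple[str, str], np.ndarray]:
        return {
            ("T1", "baseline"): self.t1w_baseline,
            ("T1", "followup"): self.t1w_followup,
            ("T2", "baseline"): self.flair_baseline,
            ("T2", "followup"): self.flair_followup,
        }


@dataclass
class SurvivalRecord:
    """Patient-level overall-survival observation."""

    patient_id: str
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("survival time must be nonnegative")


def generate_texture_volume(
    shape: tuple[int, int, int],
    base_mean: float,
    base_sigma: float,
    correlation_length_mm: float,
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Stationary Gaussian random field with the requested first two moments.

    White Gaussian noise is smoothed to the requested correlation length and
    rescaled to unit variance before shifting/scaling, so the marginal
    standard deviation is ``base_sigma`` regardless of smoothing.
    """
    if base_sigma <= 0:
        raise ValueError("base_sigma must be positive")
    if correlation_length_mm < 0:
        raise ValueError("correlation length must be nonnegative")
    rng = np.random.default_rng(rng)
    field_ = rng.standard_normal(shape)
    if correlation_length_mm > 0:
        sig_vox = [correlation_length_mm / v for v in voxel_size_mm]
        field_ = ndimage.gaussian_filter(field_, sigma=sig_vox, mode="wrap")
        field_ /= field_.std()
    return base_mean + base_sigma * field_


def _lesion_geometry(config: CohortConfig, rng: np.random.Generator):
    shape = np.asarray(config.grid_shape)
    voxel = np.asarray(config.voxel_size_mm)
    half_extent_mm = (shape * voxel).min() / 2.0
    r = rng.uniform(*config.tumour_radius_range_mm)
    t = rng.uniform(*config.edema_thickness_range_mm)
    if r + t + max(voxel) >= half_extent_mm:
        raise ValueError(
            f"lesion (radius {r:.1f} + edema {t:.1f} mm) does not fit the "
            f"{half_extent_mm:.1f} mm half-extent of the grid"
        )
    centre = (shape - 1) / 2.0 + rng.uniform(-1.0, 1.0, size=3)
    coords = np.indices(tuple(shape)).astype(np.float64)
    dist = np.sqrt(
        sum(((coords[a] - centre[a]) * voxel[a]) ** 2 for a in range(3))
    )
    tumour = dist <= r
    edema = (dist > r) & (dist <= r + t)
    return tumour, edema


def _synth_image(
    config: CohortConfig,
    zone_map: dict[str, np.ndarray],
    sequence: str,
    mean_offsets: dict[str, float],
    sigma_factors: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    noise = generate_texture_volume(
        config.grid_shape, 0.0, 1.0, config.correlation_length_mm,
        config.voxel_size_mm, rng,
    )
    img = np.zeros(config.grid_shape, dtype=np.float64)
    for zone in ZONES:
        m = zone_map[zone]
        level = ZONE_MEANS[sequence][zone] + mean_offsets[zone]
        amp = config.noise_sigma * max(0.05, sigma_factors[zone])
        nf = noise[m]
        if nf.size > 1 and nf.std() > 0:
            # pin the zone's sample moments so the per-lesion latents are
            # the sole carriers of mean/amplitude variation
            nf = (nf - nf.mean()) / nf.std()
        img[m] = level + amp * nf
    return img.astype(np.float32)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SyntheticLesion], list[SurvivalRecord]]:
    """Draw a full synthetic cohort; bit-reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    counts = np.array(sorted(config.lesions_per_patient_probs))
    probs = np.array(
        [config.lesions_per_patient_probs[int(k)] for k in counts], dtype=float
    )
    controls = config.controls
    d = config.effect_size
    tau = config.regional_tau
    jit = config.sigma_jitter

    lesions: list[SyntheticLesion] = []
    survival: list[SurvivalRecord] = []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        n_lesions = int(rng.choice(counts, p=probs))
        patient_lf = False
        lesion_buffer = []
        for j in range(n_lesions):
            lid = f"{pid}_L{j}"
            is_lf = bool(rng.random() < config.lf_fraction)
            patient_lf |= is_lf
            tumour, edema = _lesion_geometry(config, rng)
            zone_map = {
                "tumour": tumour,
                "edema": edema,
                "background": ~(tumour | edema),
            }
            # latent per-lesion intensity offsets: baseline drawn freely,
            # follow-up expressed relative to baseline so that the
            # relative-change features are exactly normal latents
            offsets = {
                (tp, seq): {z: rng.normal(0.0, tau) for z in ZONES}
                for tp in ("baseline", "followup")
                for seq in ("T1", "T2")
            }
            factors = {
                ("baseline", seq): {z: 1.0 + rng.normal(0.0, jit) for z in ZONES}
                for seq in ("T1", "T2")
            }
            growth = {
                seq: {z: rng.normal(0.0, np.sqrt(2.0) * jit) for z in ZONES}
                for seq in ("T1", "T2")
            }
            flags: tuple[str, ...] = ()
            if is_lf and d != 0.0:
                # shift follow-up latents so the relative-change feature of
                # each control separates the classes by standardized d:
                # sd(delta) across lesions is sqrt(2)*latent-sd
                for c in controls:
                    if c.kind == "mean":
                        offsets[("followup", c.sequence)][c.zone] += d * np.sqrt(2) * tau
                    else:
                        growth[c.sequence][c.zone] += d * np.sqrt(2) * jit
                flags = tuple(c.name for c in controls)
            for seq in ("T1", "T2"):
                factors[("followup", seq)] = {
                    z: factors[("baseline", seq)][z] * (1.0 + growth[seq][z])
                    for z in ZONES
                }
            images = {
                (seq, tp): _synth_image(
                    config, zone_map, seq, offsets[(tp, seq)], factors[(tp, seq)], rng
                )
                for seq in ("T1", "T2")
                for tp in ("baseline", "followup")
            }
            lesion_buffer.append(
                dict(
                    lesion_id=lid, is_lf=is_lf, tumour=tumour, edema=edema,
                    images=images, flags=flags,
                )
            )

        # patient-level survival coupled to LF status
        hazard = config.hazard_lf if patient_lf else config.hazard_lc
        t_death = rng.exponential(1.0 / hazard)
        t_cens = (
            rng.exponential(1.0 / config.censor_rate)
            if config.censor_rate > 0
            else np.inf
        )
        time = min(t_death, t_cens, config.max_followup_months)
        event = t_death <= min(t_cens, config.max_followup_months)
        survival.append(SurvivalRecord(pid, float(time), bool(event)))

        for buf in lesion_buffer:
            if buf["is_lf"]:
                # truncated exponential on (0, follow-up]: the failure is
                # observed within the follow-up window by definition
                u = rng.random()
                rate = config.lf_event_rate
                tmax = max(time, 1e-6)
                lf_time = -np.log1p(-u * (1.0 - np.exp(-rate * tmax))) / rate
                label_6 = "LF" if lf_time <= 6.0 else "LC"
                label_12 = "LF" if lf_time <= 12.0 else "LC"
            else:
                lf_time = np.nan
                label_6 = "LC"
                label_12 = "LC"
            # LC lesions of patients deceased before the window end carry no
            # horizon outcome and are excluded, not silently dropped
            if label_6 == "LC" and event and time < 6.0:
                label_6 = "excluded"
            if label_12 == "LC" and event and time < 12.0:
                label_12 = "excluded"
            lesions.append(
                SyntheticLesion(
                    patient_id=pid,
                    lesion_id=buf["lesion_id"],
                    t1w_baseline=buf["images"][("T1", "baseline")],
                    t1w_followup=buf["images"][("T1", "followup")],
                    flair_baseline=buf["images"][("T2", "baseline")],
                    flair_followup=buf["images"][("T2", "followup")],
                    tumour_mask=buf["tumour"],
                    edema_mask=buf["edema"],
                    voxel_size_mm=config.voxel_size_mm,
                    label_overall="LF" if buf["is_lf"] else "LC",
                    label_6mo=label_6,
                    label_12mo=label_12,
                    true_effect_flags=buf["flags"],
                    lf_time_months=float(lf_time),
                    followup_months=float(time),
                )
            )
    return lesions, survival


def attributable_features(features, config: CohortConfig) -> list[str]:
    """The subset of a feature list attributable to the planted effects.

    A feature is planted-attributable when it is extracted from an
    affected (region, sequence) block and belongs to a family the
    perturbation can reach: histogram, GLCM and LBP features all respond
    to the zone-latent shifts (LBP only through comparisons across zone
    boundaries, but measurably so), while geometric features never change
    because the lesion geometry is time-invariant.
    """
    from .features.names import parse_feature_name

    blocks = {b for c in config.controls for b in c.affected_blocks()}
    out = []
    for f in features:
        fn = parse_feature_name(str(f))
        if fn.family == "Geometric":
            continue
        if (fn.region, fn.sequence) in blocks:
            out.append(str(f))
    return out


def recovered_controls(features, config: CohortConfig) -> set[str]:
    """Which distinct planted controls a selected feature set points at.

    Same block-level attribution as :func:`attributable_features`,
    collapsed to the control names.
    """
    from .features.names import parse_feature_name

    hits: set[str] = set()
    for f in features:
        fn = parse_feature_name(str(f))
        if fn.family == "Geometric":
            continue
        for c in config.controls:
            if (fn.region, fn.sequence) in c.affected_blocks():
                hits.add(c.name)
    return hits


def null_config(config: CohortConfig | None = None, **overrides) -> CohortConfig:
    """A copy of a config with the planted effect switched off."""
    base = config or CohortConfig()
    return replace(base, effect_size=0.0, **overrides)


def simulate_anisotropic(
    lesion: SyntheticLesion, slice_thickness_mm: float, sequence: str = "T1"
):
    """Thick-slice acquisition of one sequence, to exercise resampling.

    Averages consecutive axial slices into slabs of the requested
    thickness (e.g. 1.5 mm from a 0.5 mm grid), returning baseline and
    follow-up :class:`~srtrad.masks.LesionVolume` objects whose voxel size
    records the anisotropy; `resample_isotropic` brings them back to the
    isotropic grid. The default pipeline generates directly isotropic
    volumes; this path exists for interpolation tests and demos.
    """
    from .masks import LesionVolume, Sequence, Timepoint

    dz = lesion.voxel_size_mm[2]
    k = int(round(slice_thickness_mm / dz))
    if k < 1 or slice_thickness_mm < dz:
        raise ValueError("slice thickness below the native resolution")
    pairs = {
        "T1": (lesion.t1w_baseline, lesion.t1w_followup, Sequence.T1W),
        "T2": (lesion.flair_baseline, lesion.flair_followup, Sequence.T2FLAIR),
    }
    bl, fu, seq = pairs[sequence]

    def slab(vol: np.ndarray) -> np.ndarray:
        nz = (vol.shape[2] // k) * k
        v = vol[:, :, :nz].reshape(vol.shape[0], vol.shape[1], nz // k, k)
        return v.mean(axis=3)

    voxel = (lesion.voxel_size_mm[0], lesion.voxel_size_mm[1], dz * k)
    return (
        LesionVolume(slab(np.asarray(bl, float)), voxel, seq, Timepoint.BASELINE),
        LesionVolume(slab(np.asarray(fu, float)), voxel, seq, Timepoint.FOLLOWUP),
    )
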