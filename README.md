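# srtrad

MR-radiomics analysis of stereotactic radiotherapy (SRT) outcome in brain
metastasis: quantitative MRI biomarkers of local failure built from texture
change between baseline and first follow-up imaging.

About 10–20% of brain metastases progress locally after stereotactic
radiotherapy, and a change in tumour size can take months to appear on
follow-up MRI. `srtrad` implements a complete framework for predicting
local failure (LF) versus local control (LC) per lesion from early texture
change, long before a size change is measurable:

1. **Sub-lesion masks** — tumour, edema, and 3 mm tumour-/lesion-margin
   rings on 0.5 mm isotropic grids (`srtrad.masks`);
2. **3072 features per lesion** — geometric, first-order histogram, local
   binary pattern (LBP), and grey-level co-occurrence (GLCM) statistics on
   the original and eight 3D wavelet sub-band images, over 4 regions × 2
   sequences (T1w, T2-FLAIR), each as relative change from baseline
   Δf = (f_FU − f_BL)/(|f_BL| + ε) (`srtrad.features`);
3. **Feature selection** — R² > 0.8 correlation clustering, Mann-Whitney
   ranking over a 50-fold patient sampling scheme, forward selection
   scored by the bootstrap .632+ AUC

       AUC.632+,b = (1 − w_b)·AUC_resub + w_b·AUC_test,b,
       w_b = 0.632 / (1 − 0.368·R_b),
       R_b = (AUC_resub − AUC_test,b) / (AUC_resub − 0.5) ∈ [0, 1],

   and an ANOVA/Tukey minimal-set reduction (`srtrad.selection`);
4. **Outcome prediction** — leave-one-patient-out (LOPO) majority vote of
   250 SVMs trained on balanced patient bootstraps (`srtrad.prediction`);
5. **Risk assessment** — Kaplan-Meier local-control and overall-survival
   curves of the predicted LC vs LF cohorts compared by log-rank test
   (`srtrad.survival`).

Because the underlying clinical images are not public, the package ships a
first-class synthetic cohort generator (`srtrad.cohort`) that emulates the
study conditions — 100 patients with 1–3 lesions, ≈40% LF, survival
hazards coupled to the LF label — and plants class-dependent texture
change of a controlled standardized effect size, so the entire pipeline is
testable end to end. See `docs/methods.md` for the model, assumptions and
design decisions.

## Worked example

```python
from srtrad import CohortConfig, LocalFailureModel, generate_cohort

lesions, survival = generate_cohort(CohortConfig(seed=11))   # 100 patients
model = LocalFailureModel.from_cohort(lesions, outcome="overall")
results = model.fit(seed=0, n_bootstrap=50)
print(results.summary())
```

```
Local-failure radiomic biomarker — outcome: overall
==========================================================
lesions: 121 (63 LF / 58 LC), patients: 100
features: 3072 -> 822 after R^2 > 0.8 reduction
kernel: rbf, bootstraps: 50, seed: 0
----------------------------------------------------------
max AUC.632+: 0.969 (7 features)
optimal biomarker AUC.632+: 0.964 (3 features)
----------------------------------------------------------
feature                                           MWU p
Edema_Wavelet_I_LLL__GLCM_Correlation_T2          6.4e-16
Edema_LBP_Percentile90_T1                         1.2e-11
Edema_Wavelet_I_HLH__GLCM_JointEnergy_T2          5.9e-15
----------------------------------------------------------
LOPO accuracy:    90.08%
LOPO sensitivity: 85.71%  (LF positive)
LOPO specificity: 94.83%
```

Reading the output: the 3072 relative-change features collapse to ~800
non-redundant representatives; forward selection peaks at 7 features but
the ANOVA minimal set keeps 3, all drawn from blocks carrying the planted
texture change (here edema on both sequences). The LOPO metrics are the
cross-validated lesion-level performance of that biomarker; on this
phantom the planted effect (d = 1.5) is strong enough for ~90% accuracy,
while a null cohort (`effect_size=0`) stays at chance. Risk stratification
hangs off the same results object:

```python
import pandas as pd
times  = pd.Series({s.patient_id: s.time_months for s in survival})
events = pd.Series({s.patient_id: s.event for s in survival})
ra = results.risk_stratification(times, events, unit="patient")
print(f"overall-survival log-rank p = {ra.logrank.p_value:.4g}")
# overall-survival log-rank p = 0.0004218
```

The command line mirrors the library (`srtrad synth-cohort`, `make-masks`,
`extract-features`, `select-features`, `predict`, `risk`, `run-all`); each
stage reads/writes NIfTI volumes and CSV/JSON tables, and `run-all`
produces a run directory with a provenance manifest that reruns
bit-identically under the same seed.

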