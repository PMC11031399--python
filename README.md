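# triagekit

Diagnostic-accuracy evaluation of fluid biomarkers for Alzheimer's disease
against PET-defined reference outcomes.

A blood test for amyloid pathology — plasma %p-tau217, the concentration of
tau phosphorylated at threonine-217 expressed as a percentage of
non-phosphorylated mid-region tau — is clinically useful only if it matches
the accuracy of the FDA-approved CSF assays (p-tau181/Aβ42 and Aβ42/40 ratios)
at classifying amyloid or tau PET status. `triagekit` implements the complete
statistical pipeline such a comparison needs, for anyone evaluating a new
quantitative diagnostic marker against an established one on the same
subjects:

* **ROC / AUC with DeLong inference** — Mann–Whitney AUC (ties credited ½),
  placement-value variance, and the paired DeLong test for two correlated
  AUCs measured on the same subjects.
* **Constrained cutpoints** — the *single-cutoff* rule (maximise sensitivity
  subject to specificity ≥ 90%) and the *two-cutoff triage* rule (a lower
  threshold maximising specificity with sensitivity fixed at 95% and an upper
  threshold maximising sensitivity with specificity fixed at 95%); subjects
  between the two thresholds are *intermediate* and referred for confirmatory
  testing rather than classified.
* **Stratified bootstrap estimation** — accuracy, PPV, NPV, sensitivity,
  specificity and the intermediate fraction, estimated as bootstrap means
  with 2.5/97.5-percentile CIs over n = 1,000 resamples drawn with
  replacement within each outcome stratum; in-bag, out-of-bag (cutoffs
  re-derived per replicate, evaluated on the ~36.8% of subjects left out) and
  cross-cohort transfer variants.
* **Clinical equivalence verdicts** — for each metric the paired
  plasma-minus-CSF difference per replicate; *equivalent* if the 95% CI of
  the difference includes zero, *plasma superior* if the CI lies entirely
  above zero.
* **Synthetic cohorts** — a generator producing cohorts with the relevant
  structure (binary PET status with configurable prevalence,
  state-conditional Centiloid/SUVR reference values, plasma and CSF markers
  correlated through a shared latent severity, either pathological
  direction, per-column missingness), so the whole pipeline is testable
  without access-restricted patient data.

Outcome definitions follow the published positivity rules: amyloid PET
positive at ≥ 37 Centiloids, tau PET positive at SUVR > 1.32 (strict), plus
optional binary visual-read and clinical-diagnosis outcomes.

## Worked example

```python
from triagekit import (SimulationConfig, generate_cohort, AMYLOID_PET_OUTCOME,
                       BiomarkerCutoffModel, PairedBiomarkerModel)

table = generate_cohort(SimulationConfig(n_cu=720, n_ci=702, seed=11))

m = BiomarkerCutoffModel.from_cohort(table, "pct_ptau217", AMYLOID_PET_OUTCOME,
                                     subgroup="CI", mode="dual")
print(m.fit(n_resamples=1000, seed=0).summary())
```

```
Biomarker cutoff evaluation: pct_ptau217 (dual mode)
============================================================
n = 702 (329 positive), orientation = higher_is_positive
AUC = 0.936 (95% CI 0.918, 0.955)
thresholds (original scale): 2.366, 9.005

metric                 observed  boot mean              95% CI
accuracy                  0.937      0.937   ( 0.916,  0.956)
ppv                       0.920      0.920   ( 0.886,  0.953)
npv                       0.949      0.950   ( 0.926,  0.972)
sensitivity               0.929      0.929   ( 0.895,  0.960)
specificity               0.943      0.943   ( 0.916,  0.968)
intermediate_fraction     0.231      0.231   ( 0.199,  0.264)
```

Reading: among the 702 simulated cognitively impaired subjects, 23.1% fall
between the two %p-tau217 thresholds (intermediate, excluded from the other
metrics); the remaining subjects are classified against amyloid-PET status
with 93.7% accuracy, and the bootstrap CIs quantify the sampling uncertainty
of each statistic at this sample size and ~47% outcome prevalence.

```python
pm = PairedBiomarkerModel.from_cohort(table, "pct_ptau217", "csf_ab42_40",
                                      AMYLOID_PET_OUTCOME, subgroup="CI")
print(pm.fit(n_resamples=1000, seed=0).summary())
```

```
Paired comparison: pct_ptau217 (reference) vs csf_ab42_40 (single mode)
======================================================================
n = 702 (329 positive)
AUC pct_ptau217 = 0.936, AUC csf_ab42_40 = 0.838; DeLong diff = +0.099 (95% CI +0.075, +0.122), p = 1.83e-16
metric                    diff              95% CI  verdict
accuracy                 0.121   ( 0.093,  0.155)  plasma_superior
ppv                      0.044   ( 0.001,  0.088)  plasma_superior
npv                      0.153   ( 0.122,  0.188)  plasma_superior
sensitivity              0.260   ( 0.207,  0.316)  plasma_superior
specificity             -0.001   (-0.032,  0.032)  equivalent
intermediate_fraction    0.000   ( 0.000,  0.000)  equivalent
```

Here the simulated plasma marker was given more discriminative signal than
the CSF Aβ42/40 ratio, and the paired bootstrap correctly judges it superior
on accuracy/NPV/sensitivity while the specificities (both pinned near the
90% floor by construction) are equivalent.

The same analysis runs end-to-end from the shell:

```sh
triagekit simulate --seed 1 --out cohort.csv
triagekit run --config analysis.yaml --out report/
triagekit report --report report/
```

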