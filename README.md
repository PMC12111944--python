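# hepindex

Non-invasive assessment of hepatic steatosis and fibrosis in metabolic
dysfunction-associated steatotic liver disease (MASLD), built for
hepatology and biostatistics workflows that combine cheap metabolic
indices with vibration-controlled transient elastography (VCTE).

MASLD affects roughly a third of adults, and most of them will never
get a liver biopsy. Clinics therefore lean on two layers of
non-invasive tools: elastography (CAP for fat, liver stiffness for
fibrosis) and blood/anthropometry-based indices. This package
implements that full pipeline as a tested library:

* **Index calculators** — TyG = log(FBG·TG/2); the sex-specific
  visceral adiposity index VAI = WC/(a+b·BMI) · (TG/t₀) · (h₀/HDL);
  the lipid accumulation product LAP = (WC−65)·TG for men and
  (WC−58)·TG for women; the NAFLD fibrosis score
  NFS = −1.675 + 0.037·age + 0.094·BMI + 1.13·dysglycemia
  + 0.99·AST/ALT − 0.013·PLT − 0.66·albumin; and
  FIB-4 = age·AST/(PLT·√ALT). Unit conversions (mg/dL ↔ mmol/L) are
  handled internally.
* **Staging** — steatosis grades S0–S3 from CAP (S1 ≥ 294, S2 ≥ 310,
  S3 ≥ 331 dB/m), fibrosis stages F0/F1–F4 from stiffness (F2 ≥ 8.2,
  F3 ≥ 9.7, F4 ≥ 13.6 kPa), the VCTE reliability rule
  (IQR/median < 30%, ≥ 10 valid readings), and the MASLD/control
  eligibility screen (CAP 248 dB/m, metabolic risk factors).
* **Grey-zone cascade** — a two-stage classifier for severe fibrosis
  (F3–F4): NFS/FIB-4 rule-out (NFS ≤ −1.455 and FIB-4 ≤ 1.3) and
  rule-in (NFS > 0.676 and FIB-4 > 2.67) first; subjects in the grey
  zone between these cut-offs are re-examined with TyG/VAI rule-in and
  rule-out thresholds, shrinking the indeterminate fraction.
* **Diagnostics** — ROC curves with Mann–Whitney AUC, DeLong paired
  AUC comparison, Youden-optimal and sensitivity/specificity-floor
  rule cut-offs, Wilson confidence intervals, Spearman correlations
  with Fisher-z CIs, normality-gated group tests, and backward-stepwise
  logistic regression with odds ratios.
* **Synthetic cohorts** — a seeded Gaussian-copula generator whose
  calibrated defaults reproduce a tertiary-care MASLD screening
  cohort's marginal distributions, severity prevalence strata and
  index–severity rank correlations, so the entire pipeline is testable
  end to end without patient data.

## Worked example

```python
from hepindex import (
    SubjectRecord, compute_panel, grade_steatosis, stage_fibrosis,
    stage1_classify, stage2_classify,
)

subject = SubjectRecord(
    subject_id="P001", sex="male", age=52.79, bmi=31.4,
    waist_circumference=109.1, fbg=114.5, tg=198.2, hdl=44.3,
    ast=42.3, alt=53.1, platelets=225, albumin=3.3,
    diabetes_or_ifg=True, cap=322.5, te=9.8,
)
panel = compute_panel(subject)
print(f"TyG  {panel.tyg:.3f}   VAI {panel.vai:.3f}   LAP {panel.lap:.2f}")
print(f"NFS  {panel.nfs:.3f}   FIB-4 {panel.fib4:.3f}")
print(grade_steatosis(subject.cap), stage_fibrosis(subject.te))
print("stage 1:", stage1_classify(panel.nfs, panel.fib4))
```

prints

```
TyG  9.337   VAI 2.746   LAP 98.69
NFS  0.045   FIB-4 1.362
SteatosisGrade(grade='S2', significant=True) FibrosisStage(stage='F3', severe=True)
stage 1: grey
```

The subject carries significant steatosis (CAP 322.5 dB/m ≥ 310) and
severe fibrosis by stiffness (9.8 kPa ≥ 9.7), but NFS 0.045 and FIB-4
1.36 both sit between the published rule-out and rule-in cut-offs —
exactly the indeterminate case the second cascade stage targets.

The same flow is available from a shell:

```bash
hepindex simulate --n 178 --seed 42 --out cohort.csv
hepindex compute-indices --in cohort.csv --out panel.csv
hepindex stage --in cohort.csv --out staged.csv
hepindex roc --panel panel.csv --staged staged.csv \
    --score tyg,vai,lap --target steatosis --out cutoffs.yaml
hepindex classify --panel panel.csv --reference staged.csv \
    --report report.json --markdown report.md
```

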