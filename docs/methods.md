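# Methods

This note documents the statistical model behind `hepindex`, the
conventions and defaults that matter, and what the synthetic cohorts
do and do not show about real data.

## Indices and units

The five calculators are literal implementations of their defining
formulas. TG and HDL arrive in mg/dL and are converted to mmol/L for
VAI and LAP using the standard molar-mass factors 88.57 and 38.67
mg/dL per mmol/L. Albumin is g/dL (the physiologic range of the NFS
formula), platelets 10⁹/L.

**TyG log base.** The defining TyG formula uses the natural logarithm
of FBG·TG/2, and `natural` is the default everywhere. Published TyG
values and cut-offs, however, span a wide range (roughly 4–8) that is
inconsistent with the natural-log scale of typical labs (≈ 8–10), and
some reported cut-off sets — including the grey-zone thresholds
shipped here (rule-out 2.65, rule-in 5.61) — only make sense on a
compressed scale. Neither base reproduces every published summary
value from the corresponding published lab means, so the ambiguity is
exposed rather than silently resolved: `log_base="decimal"` is
available on every TyG entry point, and both the cohort calibration
targets and the acceptance quantity are *rank* statistics, which are
identical under either base. Users applying the stage-2 cascade to
their own cohorts should derive TyG/VAI cut-offs on their own scale
with `hepindex roc` rather than assume the shipped constants transfer.

**Missing data.** An index is computed only when all of its inputs are
present; otherwise it is explicitly absent (`None`/NaN). No
imputation, ever.

## Staging and eligibility

CAP thresholds 294/310/331 dB/m (S1/S2/S3) and stiffness thresholds
8.2/9.7/13.6 kPa (F2/F3/F4) are lower-bound inclusive, producing a
monotone partition of the device ranges (CAP 100–400 dB/m, stiffness
2.5–75 kPa). Significant steatosis is S2–S3; severe fibrosis is F3–F4.
A VCTE examination is reliable when IQR/median < 0.30 (strict) with at
least 10 valid readings.

Eligibility uses a *different* CAP scale than severity grading: the
MASLD screen asks for steatosis evidence via ultrasound and/or
CAP > 248 dB/m, while grading starts S1 at 294 dB/m. The two scales
are deliberately kept as separate operations — a subject with CAP 270
is MASLD-eligible yet grades S0. CAP exactly 248 satisfies neither the
steatosis rule (>) nor the control rule (<) and yields `ineligible`.
Controls additionally require a *negative* ultrasound (absence must be
confirmed by both modalities), BMI < 25, no diabetes and at most one
metabolic risk factor. The transaminase exclusion (> 5× the upper
normal limit) uses a configurable ULN, default 40 U/L. All clinical
constants live in `src/hepindex/defaults.yaml`.

## The grey-zone cascade

Stage 1 applies the published NFS/FIB-4 cut-offs jointly (AND on both
scores): rule-out at NFS ≤ −1.455 and FIB-4 ≤ 1.3, rule-in at
NFS > 0.676 and FIB-4 > 2.67. Stage 2 re-examines only grey-zone
subjects with TyG/VAI rule-in/rule-out thresholds. The combination
rule for stage 2 is configurable: the default `both` mirrors the AND
logic of stage 1; `either` accepts a single decisive index. Discordant
signals (one index rules in, the other rules out) are never resolved —
the subject stays unclassified with reason `conflict`. Classified
subjects are never relabelled by a later stage, so the unclassified
fraction can only shrink.

Correctness is evaluated against elastography staging on whatever
analysis subset the caller passes in; the package imposes no cohort
filter. Percentages render to one decimal, rounding half-up.

## ROC machinery

A positive call is *score ≥ threshold* throughout; candidate
thresholds are the distinct observed scores plus one value above the
maximum. AUC is the Mann–Whitney concordance probability with ties
counted ½, computed from midranks. The optimal cut-off maximises
Youden's J with ties resolved toward the lower threshold. Rule
cut-offs are deterministic constrained scans: rule-out maximises
specificity subject to a sensitivity floor (default 0.80), rule-in
maximises sensitivity subject to a specificity floor (default 0.74);
degenerate operating points (Se = 0 or Sp = 0) are never returned, and
an unsatisfiable floor yields an absent cut-off. On strongly
discriminative scores the two scans can legitimately cross (rule-in
below rule-out), meaning no grey zone remains.

Paired AUC comparison uses the DeLong placement-variance construction
with a two-sided normal reference; identical score vectors give
delta 0, p = 1 by convention. Proportion CIs are Wilson at 95%;
ratios with zero denominators are absent, never zero. Spearman CIs
use the Fisher z-transform with the Fieller–Hartley–Pearson standard
error √(1.06/(n−3)). Group comparison routes through a
Lilliefors-corrected Kolmogorov–Smirnov normality gate (α = 0.05 per
group) to Student's t (equal variances) or Mann–Whitney U; boolean or
two-valued data go to Pearson's χ² without continuity correction. No
multiple-testing correction is applied anywhere, matching the analysis
style the pipeline reproduces.

Backward-stepwise logistic regression starts from the full model and
repeatedly removes the predictor with the largest Wald p > 0.10,
accepting a removal only while the AIC does not worsen. Note a
structural property of this (conventional) rule: a pure-noise
predictor has a uniform null p-value, so about 10% of noise predictors
are retained at any given fit — per-predictor noise removal rates
plateau around 85–90%, not higher. Perfect separation is flagged and
the (unstable) fit returned rather than suppressed.

## Synthetic cohort generator

The generator emulates the statistical structure of a 178-subject
tertiary-care MASLD screening cohort (69% MASLD, 55% male, mean age
≈ 53) so the pipeline can be exercised end to end.

**Dependence model.** A Gaussian copula: each subject draws a latent
multivariate normal vector with unit variances; each variable is then
mapped through its marginal inverse CDF. The correlation matrix is a
one-factor structure — every variable loads on a single latent
"metabolic severity" factor — plus a handful of explicit pairwise
overrides (WC–BMI 0.75, AST–ALT 0.65, TC–LDL 0.85, TG–HDL −0.36 on
the Spearman scale, converted to latent Pearson via 2·sin(πρ/6)).
Eigenvalue-clipping repair handles mild indefiniteness; targets that
would require a repair shifting any entry by more than 0.05 raise an
error naming the offending pair.

**Marginals.** Most labs are normal with the cohort's published
moments, clipped to physiologic bounds (clipping is counted and
reported). Right-skewed triglycerides are log-normal matched to mean
198.2 / SD 148.9 mg/dL; fasting glucose is log-normal matched to
median 114.5 and IQR 110–120 mg/dL. CAP and stiffness use a
prevalence-preserving stratum quantile map: the latent percentile
selects the severity stratum (steatosis 31/5/21.3/42.7% over S0–S3;
fibrosis 45.5/27/17.4/10.1% over F0/F1–F4) and interpolates linearly
across that stratum's value bin, so realised severity counts are exact
multinomial draws and the map stays monotone in the latent variable.

**Calibration.** The factor loadings for TG, waist circumference, HDL,
CAP and stiffness, plus the TG–HDL override, were fitted once by
Nelder-Mead against six target index–severity Spearman correlations
(TyG/VAI/LAP × steatosis grade 0.66/0.76/0.61, × fibrosis stage
0.53/0.63/0.51) on a 100 000-subject simulation with common random
numbers, then frozen into `DEFAULT_FACTOR_LOADINGS`. Residual
miscalibration is below 0.012 on every target. Indices in generated
cohorts are always *computed from the raw measurements*, never drawn
directly, so the formula modules are exercised by every cohort.

`calibration_report` re-measures all targets on a generated cohort:
rank-correlation rows at ±0.05 absolute (n ≥ 100), marginal mean/SD
rows at ±10% relative, evaluated at n ≥ 5000 (below that, sampling
noise dominates and the verdict column is left empty). Clipped normal
marginals are compared against their censored-normal moments — the
generator's actual contract — not the unclipped parameters.

**Determinism.** One `numpy` Generator seeded from the spec drives
every draw in a fixed order; identical spec + seed gives byte-identical
tables. Problem sizes used by the shipped checks — 5000 subjects for
calibration verification and the headline correlation, 1000 for the
pipeline-closure AUROC, 100 000 (one-time, offline) for loading
calibration — were chosen so each quantity's Monte-Carlo error is
small relative to its tolerance.

**What the generator does not emulate.** No missing data beyond what a
user masks; no longitudinal structure; no tail dependence (a Gaussian
copula cannot produce it, and only pairwise rank targets were
available); fasting-glucose spread reflects the cohort's narrow
printed IQR, making dysglycemia nearly universal; and the calibrated
waist-circumference loading came out small (0.12), so WC correlates
with severity mainly through BMI and more weakly than in real
patients. One CBC variable is carried as `hgb_like` because its
published label and value pattern disagree; it loads on nothing and is
excluded from all targets. Passing tests on synthetic cohorts
therefore demonstrate that the pipeline's arithmetic, threshold logic
and statistical machinery are correct under a faithful rank-dependence
structure — not that the shipped TyG/VAI cut-offs would achieve the
same operating characteristics in an external clinical population.

## Numerical conventions

* Threshold boundaries: every "≥" threshold is lower-bound inclusive;
  rule-out uses ≤, rule-in strict >.
* Percentages: one decimal, half-up (`Decimal` arithmetic, no binary
  float surprises).
* Tie handling: midranks everywhere ranks appear (AUC, DeLong,
  Spearman).
* Degenerate inputs fail loudly: single-class ROC labels, constant
  stepwise predictors, constant Spearman vectors and out-of-range
  CAP/stiffness all raise with specific messages.
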