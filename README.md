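# nils — noninvasive axillary lymph node staging for breast cancer

Most patients with clinically node-negative early breast cancer undergo
sentinel lymph node biopsy (SLNB), yet the majority turn out to have healthy
axillary nodes (pathological N0), so the surgery brings morbidity without
therapeutic benefit. `nils` implements a decision-support engine that
estimates the probability of healthy nodes from 10 routinely available
preoperative variables — largest tumor size, vascular invasion (VI),
multifocality, ER status, histological type, PR status, mode of detection,
age, tumor localization, and Ki67 — so that low-risk patients can be
identified as candidates for omitting SLNB.

## The model

The predictor is an ensemble of 30 multilayer perceptrons. Each MLP has one
hidden layer of 10 `tanh` units and a logistic output:

    p(N0 | x) = σ( w₂ᵀ tanh(W₁x + b₁) + b₂ )

Members are trained on leave-one-part-out unions of a class-stratified
3-way split of the training data (10 random splits × 3 parts = 30 member
training sets), minimizing mean cross-entropy with an L2 weight-decay
penalty λ‖W‖² (biases unpenalized); the ensemble prediction is the mean of
the member outputs. λ is selected by repeated stratified 5-fold
cross-validation (5 repeats × 5 folds): each repeat's out-of-fold
predictions are fused into a validation list covering every patient, the
five lists are averaged per patient, and the λ with the best fused-list AUC
wins.

Because VI, ER, PR and Ki67 are often unreported on core needle biopsy, the
deployed tool is a four-pathway workflow. Missing VI is imputed by one of
two dedicated VI sub-models (with or without ER/PR/Ki67 inputs) and the
imputed probability feeds the N0 model's VI slot; missing ER/PR/Ki67 routes
to a reduced N0 model without those inputs. Input vectors have 16 / 15 /
13 / 12 values depending on the variant.

Decision cut-points are chosen on the fused validation lists to maximize
the SLNB reduction rate (TN+FN)/n subject to a false-negative rate
FN/(FN+TP) ≤ 10% — the accepted miss rate of the SLNB procedure itself.
Calibration is assessed with the Hosmer–Lemeshow statistic over deciles
(df = 8), discrimination with the Mann–Whitney AUC and DeLong 95% CI, and
the risk display contextualizes each estimate against a background
distribution of development-cohort predictions, smoothed by a Gaussian
kernel (bandwidth 0.5) on the logit scale so its support stays inside
(0, 1).

The development cohort behind the original tool is private, so the package
includes a synthetic-cohort generator that emulates its structure (800
patients, 64.5% N0 prevalence, realistic marginals, configurable effect
directions, MCAR missingness restricted to VI/ER/PR/Ki67) and a 100-subject
technical-validation set covering all four missingness pathways; a
concordance harness compares the full prediction path against an
independent plain-Python recomputation from the serialized parameters.

## Worked example

```python
from nils import GeneratorConfig, generate_cohort, BuildConfig, build_registry, predict_n0
from nils.synthetic import generate_technical_validation_set

records = generate_cohort(GeneratorConfig(n=800, seed=42))
config = BuildConfig(seed=42, lambda_grid=(0.001, 0.01, 0.1),
                     ensemble_repeats=2, cv_ensemble_repeats=1, cv_repeats=2)
registry, report = build_registry(records, config)
```

Printed summary of the build (`report["models"]["n0_full"]` and the
registry):

```
n0_full: lambda*=0.01, AUC=0.777 (95% CI 0.744-0.811), HL chi2=5.3 (df=8)
cut-points: full=0.7986, reduced=0.7775
at cut-point: sensitivity=0.90, specificity=0.37, FNR=0.100, SLNB reduction=0.27
```

The fused-validation AUC of 0.777 is the discrimination of the full-input
pathway on this synthetic cohort; the HL statistic of 5.3 on 8 df indicates
no evidence of miscalibration; and at the stored cut-point the FNR respects
the 10% constraint while 27% of patients would be classified N0 (surgery
potentially omitted). Predicting a patient whose biopsy did not report VI:

```python
rec = generate_technical_validation_set(GeneratorConfig(n=800, seed=42), seed=1).records[30]
res = predict_n0(registry, rec)
```

```
patient T031: p(N0)=0.4886, pathway=full_vi_imputed, imputed VI=0.310, classified predict_Npos
```

The record was routed through the VI imputation sub-model (estimated
probability of vascular invasion 0.31), and its N0 probability of 0.49 falls
below the full-pathway cut-point, so SLNB remains indicated.

The same pipeline is available from a shell:

```sh
nils simulate --n 800 --seed 42 --out cohort.csv
nils build --cohort cohort.csv --registry registry.json --report report.json --seed 42
nils predict --registry registry.json --cohort cohort.csv --out payloads.json
```

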