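# Methods

This note records the modelling and numerical choices behind `nils`, the
assumptions they rest on, and what the synthetic test bed does and does not
establish.

## Prediction model

Each model variant is an ensemble of feed-forward networks with one hidden
layer of 10 `tanh` units and a single logistic output. The four variants
differ only in their input vector: the full N0 model consumes all 10
variables as 16 encoded values; the reduced N0 model drops ER, PR and Ki67
(13 values); the two VI imputation models mirror these but exclude the VI
slot (15 and 12 values), since VI is their prediction target. Continuous
inputs (tumor size in mm, age in years, Ki67 in percent) are standardized
to zero mean and unit SD with statistics fitted once on the full training
cohort; histological type (NST/ILC/other) and localization
(central/UIQ/UOQ/LIQ/LOQ) are one-hot; the remaining variables are 0/1
indicators. The feature order is fixed and serialized with the model, so
registries are portable and independently recomputable.

Ki67 enters as a percent in [0, 100]; pathology reports state it that way,
and the standardization makes the choice of percent versus fraction
irrelevant to the fitted model, affecting only the CSV contract.

Localization is derived from laterality and the o'clock position with the
examiner-facing-the-patient convention: with h' = h mod 12, the right
breast maps [0,3)→UIQ, [3,6)→LIQ, [6,9)→LOQ, [9,12)→UOQ and the left breast
mirrors inner↔outer. Boundary hours (3, 6, 9, 12) fall in the sector they
open — a deterministic convention this package fixes, since "quadrant" is
otherwise underspecified at exact boundary hours.

## Training and regularization

Members minimize mean binary cross-entropy plus λ·Σw² over the weights
(biases excluded, standard weight-decay practice; it also makes the
large-λ limit collapse exactly to the class prevalence through the free
output bias). The mean — rather than summed — cross-entropy gives λ a scale
independent of training-set size, so one grid serves every member subset.
Optimization is full-batch L-BFGS with analytic gradients (datasets are at
most 800 × 16, so full-batch is cheap and avoids minibatch seed bookkeeping);
defaults: 500 iterations maximum, ftol 1e-8, weights initialized uniform in
(−0.5, 0.5) from a seeded generator, biases zero. The logistic output is
clipped to [1e-12, 1−1e-12] so downstream logit transforms are always
defined.

Each ensemble has 3 × `repeats` members (default `repeats = 10`, 30
members): per round, the training data are split into three class-stratified
parts of near-equal size (per-class part sizes within 1 of n/3, remainders
assigned in seeded shuffle order — a rule that must be pinned because 800 is
not divisible by 3) and each part is left out once. Member seeds derive from
the master seed via `SeedSequence(master, spawn_key=(round, part))`, so
members are independent but the whole build is bit-reproducible; two builds
with the same seed serialize byte-identically.

## Weight-decay selection and validation lists

λ is selected by repeated stratified 5-fold cross-validation with a full
member-subsampled ensemble trained inside every fold. The five out-of-fold
prediction sets of a repeat are concatenated into one fused validation list
covering each patient exactly once; the five repeats' lists are averaged
per patient into the final list, and every reported performance number
(AUC, HL, confusion at cut-points) comes from final lists. The selection
criterion is the final-list AUC — the workflow's one reported
discrimination measure — with ties broken toward the larger (more
regularized) λ. All grid values share the same seeded fold partitions, so
comparisons are paired and the result is invariant to grid order. The
default grid is {1e-4, 1e-3, 1e-2, 1e-1, 1} on the mean-loss scale;
`cv_ensemble_repeats` bounds the inside-fold ensemble size (tests and the
acceptance pipeline use 1, i.e. 3 members per fold, with a 3-value grid —
the package's test-scale configuration; the structure of the procedure is
unchanged).

Normalization statistics are fitted once on the full cohort and shared by
all folds and models, matching a preprocess-before-training design; the
leakage this admits is negligible at these sizes and buys exact
train/deploy consistency of the encoding.

## Missing data

Deployment tolerates missing VI, ER, PR and Ki67 only (the six other
variables are mandatory; records missing them are rejected as ineligible).
Routing is a 2 × 2 truth table on (VI missing?, any of ER/PR/Ki67
missing?). A missing VI is imputed by the routed VI sub-model and enters
the N0 model as the continuous probability ("soft" imputation, the
default) — it preserves the imputer's information; a registry-level
`vi_hard_threshold` binarizes it at a chosen threshold for the alternative
reading.

At training time the same imputers (trained first, on records with
observed VI) fill missing VI, mirroring deployment. Missingness beyond the
workflow's allowance — e.g. a missing ER in a record used to train a
full-input model — is resolved by a seeded hot-deck draw from the
variable's observed marginal, re-drawn per ensemble member and per CV fold,
a light-weight stand-in for a full multiple-imputation layer that keeps
every build deterministic.

## Cut-points, metrics and the background display

The positive class for confusion accounting is N+ (the patient is sent to
SLNB); classification predicts N0 iff p ≥ c, with equality counted as N0 (a
tie rule that must be pinned). Candidate cut-points are midpoints between
consecutive distinct predicted probabilities plus sentinels outside the
observed range; among candidates with FNR ≤ 10% (the accepted miss rate of
SLNB itself), the one maximizing the SLNB reduction rate (TN+FN)/n is
chosen, ties toward the higher cut-point. The all-predict-N+ sentinel has
FNR = 0, so the search is always feasible. One cut-point is stored per N0
model.

AUC is the tie-corrected Mann–Whitney concordance that an N0 patient's
p(N0) exceeds an N+ patient's, with a DeLong 95% CI (deterministic, unlike
a bootstrap). The Hosmer–Lemeshow statistic uses quantile groups (ties kept
together; df = groups − 2, so 10 groups give the 8-df statistic); with
fewer than three groups the statistic is still returned but the p-value is
undefined (NaN). Variable importance is ranked by the drop in AUC under
seeded within-column permutation (localization permuted as the
laterality+position pair), largest drop = position 1.

The background distribution maps the final-list probabilities to logits
ln(p/(1−p)), applies a fixed-bandwidth (0.5, logit units) Gaussian KDE on a
uniform logit grid padded by ±4 bandwidths (512 points), and returns the
p-scale density with the change-of-variables factor 1/(p(1−p)). Only this
Jacobian form integrates to one on (0, 1), which is what makes the
"support stays inside (0, 1)" rationale of the logit transform meaningful
for display.

## Synthetic cohort

The generator emulates the structure of the (private) development cohort:
n = 800, target N0 prevalence 64.5% (intercept calibrated by root finding
on the latent logistic model), tumor size log-normal (median 15 mm), age
truncated normal (62 ± 12, [25, 95]), Ki67 scaled-beta (mean ≈ 31%),
screening detection 57%, and plausible categorical rates for the rest.
Effect directions follow the cohort's reported contrasts (larger size,
multifocality, VI, higher Ki67 → N+; screening detection → N0; ER-negative
leaning N0); magnitudes were fixed once so a default build lands in the
mid-0.7 fused-AUC regime the original tool operates in. VI additionally
depends on tumor size and Ki67 (marginal rate preserved at 25% by a second
calibrated intercept) so the VI imputation sub-models have signal to learn,
as their real counterparts do. Missingness is MCAR, restricted to
VI/ER/PR/Ki67, with a default VI rate of 30% reflecting the reported
failure rate of VI detection on core needle biopsy; MCAR is the weakest
mechanism and keeps routing tests unconfounded.

What passing tests on this cohort do **not** show: the generator draws all
other variables independently, has no measurement error, no informative
missingness, and its outcome model is exactly logistic in the encoded
features — so synthetic AUC/HL values characterize the pipeline, not any
real population, and nothing here asserts the private cohort's performance.

The 100-subject technical-validation set reproduces the interface-check
design: four groups of 25 covering the four missingness pathways (groups
3–4 mask exactly one of ER/PR/Ki67 by default, with a multiple-missing
option), plus an optional injection of two records with missing
multifocality to replicate a 98-evaluable concordance scenario.

## Concordance harness

`concordance_check` predicts every record through the full workflow and
through `nils.reference`, a deliberately separate plain-Python
reimplementation (own encoding, own forward pass, no numpy) driven only by
the serialized registry dictionary. A record matches when |Δp| ≤ 1e-8 and
pathway and cut-point agree exactly; in practice agreement is at the
1e-16 level. The harness accepts an external parameter dictionary so drift
between a deployed copy and the reference parameters is detectable (a
single weight perturbed by 1e-3 surfaces as a mismatch).

## Problem sizes

Unit tests run on cohorts of 50–160 patients with 1–2 member rounds and
1–2 CV repeats; the end-to-end acceptance pipeline builds on 800 patients
with the 3-value λ grid, 5 × 5 CV with 3-member fold ensembles, and
30-member final ensembles — the package's test-scale configuration, chosen
so a full build completes in about a minute on one CPU while preserving
every structural element of the procedure. Scientific-scale builds (full
λ grid, `cv_ensemble_repeats = 10`) use the same code paths and scale
runtime roughly linearly in the member count.

## Known limitations

- The optimizer, initialization and λ grid are this package's choices; the
  original tool's are unpublished, so numeric equality with it is neither
  expected nor claimed — the engine reproduces the procedure, not the
  weights.
- The hot-deck stand-in for multiple imputation understates
  between-imputation variance; the reported HL value is a single-replicate
  statistic, labelled as such in the build report.
- Cut-points are cohort-dependent by construction; the deployed tool's
  numeric cut-points are not public.
- DeLong CIs assume large-ish class counts; on very small toy sets the
  interval is clipped to [0, 1].
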