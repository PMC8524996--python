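# Methods

This note documents the models, conventions and calibration choices behind
`cadeval`, in the order the pipeline runs.

## Box geometry and the correctness rule

Boxes are axis-aligned rectangles in continuous pixel coordinates (origin
top-left, x rightward, y downward), stored as `(x_min, y_min, x_max,
y_max)` with strictly positive extent; the `(x, y, width, height)` file
dialect is converted on read. IoU is computed from continuous rectangle
areas, not pixel rasterization — coordinates in annotation files are
real-valued and the continuous formula is the standard reading of
"intersection over union". The test suite checks it against an independent
cell-counting oracle on a lattice where counting is exact.

A mark is correct when IoU with a ground-truth lesion is **at least** 0.3
(the threshold comparison is inclusive). Matching is one-to-one. The
default `greedy_desc_iou` policy accepts candidate pairs in order of
descending IoU, ties broken deterministically by lower annotation index
then lower lesion index, for reproducibility. An `optimal` policy
(maximum pair count, then maximum total IoU, via the Hungarian assignment)
is available; the two agree whenever each lesion has at most one
above-threshold mark, which is the regime of a one-nodule-per-image study.
Multiple lesions per image never occur in the emulated study, so the
multi-lesion matching policy is a documented extension, not an emulated
behaviour.

## Case classification and mFPI

Per image and annotation set: malignant → TP iff ≥ 1 box matches the
lesion, else FN; normal → TN iff no boxes, else FP. A TP case may still
carry extra non-matching boxes: the case definition only requires that a
matching mark exists, while every unmatched mark counts as a
false-positive lesion. mFPI divides total FP lesions by **all** images
(malignant and normal), per its defining formula. Images absent from an
annotation set carry zero boxes — readers mark only suspected nodules —
and are not treated as missing data. The CAD arm is classified by the
identical code path, so standalone CAD metrics and the transition analysis
can never diverge from the reader pipeline.

## Metrics, pooling, display

sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/N, PPV = TP/(TP+FP), NPV = TN/(TN+FN). Group and overall panels
are micro-averages (confusion counts summed across readers before the
metric is computed), which is the aggregation a marginal (GEE) model
estimates. A zero denominator yields an explicit `None` — never a silent
zero — and propagates through ratios. Full precision is kept everywhere;
rounding happens only in report frames, half-up to two decimals for
metrics/ratios and to integer percent for demographics.

The eligibility cascade applies exclusions in a fixed order — metastasis,
mass > 30 mm, non-nodular appearance, not visible on the radiograph (a
ground-glass nodule under 5 mm counts as not visible) — counting each
candidate once at its first failing criterion so the cascade conserves the
cohort.

## Transition analysis

For each reader, each image falls in one of four tracked discordant cells
(CAD TP/pre FN, CAD TN/pre FP, CAD FN/pre TP, CAD FP/pre TN) or in a
single concordant tally kept for conservation checking. "Changed" means
the case state flipped between arms; box edits that leave the state
unchanged do not count, since all quoted switch rates are case-state
transitions. Group switch rates are changed/(changed+unchanged) on counts
summed within the group.

## GEE estimation

Outcome records are binary "correct" indicators per (reader, arm, case),
with metric-specific subsets: malignant cases for sensitivity, normal for
specificity, all for accuracy, and the arm-specific sets of
positive/negative calls for PPV/NPV — the PPV and NPV subsets legitimately
differ between arms because CAD reference changes which cases a reader
calls positive.

The mean model is log μ = β₀ + β₁·arm with binary variance μ(1−μ), solved
by iteratively reweighted scoring of the estimating equations
Σᵢ Dᵢᵀ Vᵢ⁻¹ (yᵢ−μᵢ) = 0. The default cluster is the reader (each reader
contributes many correlated case outcomes in both arms; the paired re-read
of a case by the same reader is absorbed into the cluster rather than
modelled as explicit pairing — a known simplification), with
(reader, image) clustering available. Working correlation is exchangeable
by default with independence as an option; the exchangeable α uses the
moment estimator of standardized-residual cross-products with the same
degrees-of-freedom conventions as statsmodels, so the cross-check test can
demand agreement to 1e-6. Numerical choices: μ clamped to (1e-10, 1−1e-10)
during iteration (the log link does not respect the (0,1) domain);
convergence when the max coefficient update falls below 1e-8 (relative),
at most 100 iterations, with non-convergence flagged rather than silently
reported; an arm whose outcomes are constant raises a separation error
naming the arm. Inference is the robust sandwich A⁻¹BA⁻¹ (scale-free, so
no dispersion estimate enters), 95% Wald bounds exp(β₁ ∓ 1.959964·se),
two-sided normal p-values displayed with a "< 0.001" floor. With
independence weights and a saturated two-level covariate the estimating
equations are solved exactly by the arm means, which gives the closed-form
oracle (ratio = pooled-proportion ratio) used in the tests.

## The synthetic-study generator

The generator emulates a fixed single-institution test set:
59 malignant + 253 normal images of 2000×2000 px at 5 px/mm (an arbitrary
but reproducible scale). Because the emulated design evaluates one fixed
cohort, categorical composition is **apportioned exactly** (largest
remainder) rather than sampled: size bins 7/33/19 (≤10 / 11–20 / 21–30 mm,
diameters uniform within bin), laterality 39/20, location 23/31/5, overlap
structures 2/6/1/3, vendor mixes 6/89, 31/113, 22/110 malignant/total.
Only detection outcomes are stochastic. Lesion boxes are squares of the
nodule diameter placed uniformly in the lung-field sub-region for their
laterality (patient right = image left) and location band.

Operating points: the CAD detects each nodule independently with
probability 0.66 and adds Poisson(0.05) false-positive boxes per image
(Poisson rather than Bernoulli so mFPI can exceed 1 in stress tests),
placed below the matching threshold by construction. Readers draw a
baseline sensitivity from a Beta distribution with group mean 0.47
(general physicians) or 0.51 (radiologists) and concentration 150
(sd ≈ 0.04, mimicking observed per-reader spread; no variance parameter is
published, so this is a calibration choice), and call a normal image
positive with probability 1 − 0.96. Detection boxes get a target IoU drawn
uniformly from (0.4, 0.9), realized by random isotropic rescaling plus
bisection on translation distance (IoU is monotone under translation) with
accept–reject verification against a ±0.05 band — so every generated
detection passes, and every generated FP box fails, the 0.3 rule.

**Shared conspicuity.** A two-point per-nodule detectability multiplier is
applied to both the CAD's and every reader's detection probability:
21 of 59 nodules are "subtle" (multiplier 0.127) and the rest carry the
complementary multiplier (≈ 1.48) that makes the mixture mean exactly 1,
leaving every marginal operating point untouched while giving
E[m²] ≈ 1.42. The subtle fraction and multiplier are calibrated to the
emulated study's own transition-table counts: its joint frequencies of
(reader miss, CAD hit) on malignant reads — 116/531 for general
physicians, 101/531 for radiologists — are far below the independence
values (0.53·0.66 and 0.49·0.66), and solving either the joint counts or
the post-CAD sensitivity of 0.60 per group for E[m²] gives the same value
(≈ 1.41). Without this shared-difficulty term no independent-detection
model can jointly reproduce the baseline sensitivities, the switch rates
and the post-CAD operating point. The multiplier is deliberately
independent of nodule size; tying conspicuity to size/overlap is left as a
hook, off by default.

**Post-CAD arm.** Modelled purely as case-state switching conditioned on
the realized (CAD state, pre state) cell — exactly the structure the
transition analysis estimates — rather than as a perceptual model. Default
switch probabilities are the emulated study's exact group proportions
(68/116, 29/81, 14/95; 49/101, 24/82, 21/95), with the rare TP→FN cell set
to a loose 0.02 for both groups (the event is observed but too rare to
estimate per group). A FN→TP flip adopts the CAD's detection box; a TN→FP
flip adopts the CAD's false-positive boxes; FP→TN and TP→FN flips delete
boxes.

Identical config + seed gives a byte-identical serialized bundle.

What the generator does **not** emulate: pixel content and perceptual
difficulty beyond the two-point mixture, reader-specific specificity
spread, correlation between reader and CAD false positives on normal
images, intra-reader drift, and multiple nodules per image. Passing tests
therefore demonstrate that the analysis machinery is correct and that the
pipeline recovers configured operating points — not that the generator
reproduces every joint property of real reader behaviour.

## Problem sizes in tests and the acceptance script

Stochastic calibration checks use 200 replicated full-size studies (the
acceptance script and the end-to-end acceptance test) and 40 replicates
for the per-component Monte-Carlo checks; the GEE coverage property uses
500 replicates of a 40-cluster design with within-arm exchangeable binary
correlation 0.2 built by the Bernoulli-mixture construction
y = c·b_cluster + (1−c)·fresh with P(c) = √0.2, which yields the target
correlation exactly while keeping marginal means (0.5 vs 0.6, true ratio
1.2) exact. These sizes give Monte-Carlo standard errors comfortably
below the two-decimal reporting resolution of the calibrated quantities.

## Known limitations

- The GEE treats the pre/post pairing only through the reader cluster; an
  explicit paired-arm covariance structure is not modelled.
- Pooled (micro-averaged) metrics weight every read equally; no
  reader-level variance decomposition (Obuchowski–Rockette / DBM) is
  provided, and no multiplicity adjustment is applied across the five
  metrics.
- FROC analysis beyond the single mFPI operating point is out of scope, as
  readers and CAD produce binary localizations without confidence scores.
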