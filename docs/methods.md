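# Methods

This package models a two-step multi-cancer early detection (MCED)
strategy: a cheap blood test based on seven protein tumor markers (PTMs)
screens everyone; only initial positives receive the expensive
sequencing-based multi-omics test. It implements (i) a synthetic
case–control cohort generator, (ii) the two classifiers and their cascade,
(iii) the ROC/comparison statistics, and (iv) a closed-form projection of
the cascade onto a population-scale screening program with its costs.

## 1. Synthetic case–control cohort

No raw measurements ship with the package; the generator produces cohorts
whose *summary behaviour* matches the published case–control study: 617
cancer and 580 noncancer participants, cancer stage mix I 26.3% / II 18.6%
/ III 21.4% / IV 22.2% / not-expected-to-be-staged 5.3% / missing 6.2%,
age means 56.0 (SD 13.7) vs 48.3 (SD 12.9) years, and male fractions
56.9% vs 51.0%. Age and sex are generated for realism but are not used by
any classifier.

### Genomic feature scores

Each of the four cfDNA features (copy-number aberration `cna`, fragment
size `fs`, end motif `endmotif`, oncogenic virus `virus`) is a
unit-variance Gaussian score. Noncancer mean is 0; the cancer mean is the
binormal shift

    delta = sqrt(2) * Phi^-1(AUC_target),

so each feature's theoretical AUC equals its target exactly (defaults
0.797, 0.865, 0.877, 0.654). The sequencing-level pipelines that produce
these scores in practice (CNA calling, fragmentomics, motif counting,
viral detection) are deliberately out of scope — only the per-sample
scores are emulated.

Features are *not* independent: all four load on a latent per-subject
"tumor burden" factor with equicorrelation `feature_corr = 0.80`. This
matters. With independent features at the marginal AUCs above, any
reasonable linear combination reaches an integrated AUC near 0.95–0.97;
the published integrated score reaches 0.899, which is only possible if
the features share information. Biologically they do — every cfDNA-derived
signal co-varies with circulating tumor fraction — so the correlated model
is both the calibrated and the mechanistically sensible choice. The
correlation is a single exchangeable parameter; a full inter-feature
correlation matrix is not identifiable from the published summaries.

### Protein tumor markers

Marker concentrations (AFP, CA125, CA15-3, CA19-9, CA72-4, CEA,
CYFRA 21-1) are log-normal. Healthy baselines sit near the middle of
clinical reference ranges (e.g. AFP median 3 ng/mL, CA125 median 12 U/mL)
with log10 SDs of 0.135–0.225, so only a small healthy tail crosses the
usual upper reference limits (AFP 7 ng/mL, CA125 35 U/mL, CA15-3 25 U/mL,
CA19-9 37 U/mL, CA72-4 6.9 U/mL, CEA 5 ng/mL, CYFRA 21-1 3.3 ng/mL).

Cancer changes markers through two mechanisms:

* a mild graded elevation of every marker
  (`cancer_continuous_shift = 0.25` baseline SDs on the log scale), and
* a discrete per-marker "elevation" event — the clinically familiar
  pattern that a given tumor strongly secretes some markers and not
  others — with stage-dependent probability (I 0.147, II 0.203, III 0.259,
  IV 0.343; unstaged/missing 0.231) and a log10 shift of 1.0 ± 0.25.
  Elevation events are coupled to the latent burden factor through a
  probit link (`burden_corr = 0.45`), so marker-positive cancers also tend
  to carry stronger genomic signal; the marginal elevation probability is
  preserved exactly by the probit construction.

Noncancer subjects have benign elevations (probability 0.05 per marker,
shift scaled by 0.9) — tumor markers are famously nonspecific (hepatitis,
endometriosis, smoking, etc.). Benign elevations cluster within a subject
through their *own* latent factor, independent of the genomic scores: a
benign CA19-9 elevation says nothing about cfDNA fragmentation. This
independence is what lets the second test veto most first-step false
positives, reproducing a cascade specificity (≈99.3%) above the CRS
standalone specificity (98%).

These PTM parameters were tuned once, by simulation, so the downstream
marker model reaches the published panel-level behaviour (AUC ≈ 0.79,
sensitivity ≈ 50% at 91% specificity), and then frozen; they are exposed
in the configuration for sensitivity analyses but the defaults are the
study conditions. With the defaults, marker positivity (any marker above
its reference limit) rises monotonically with stage, a property the test
suite checks.

What the generator does *not* emulate: per-cancer-type marker signatures
(27 tumor types collapse to one generic cancer process with stage
effects), assay measurement error as a separate component, longitudinal
sampling, and covariate effects of age/sex on marker levels. Passing tests
therefore show that the *pipeline* recovers the operating characteristics
it was calibrated to — not that it would reproduce them on real patients.

## 2. Probability of cancer (POC)

The marker panel is summarized by a binomial GLM with logit link on the
seven log10 concentrations. Before the log transform, concentrations are
winsorized at the training pool's 99.9th percentile (clinical analyzers
saturate; capping keeps the fit stable), and the caps are stored in the
model file so scoring is reproducible.

The slope coefficients are maximum likelihood. The intercept is then
re-anchored so that POC = 0.5 falls at the 91st percentile of the
training-noncancer linear predictor — an offset-only recalibration. The
rationale: the deployed test's 0.5 cutoff is documented to operate at
about 91% specificity and ~50% sensitivity, whereas a raw case–control
MLE fit on a near-balanced cohort places its 0.5 cutoff at the
posterior-0.5 boundary (≈65% sensitivity at ≈82% specificity) — correct
for the training prevalence, but not how the screening product is
operated. Anchoring affects the cutoff placement only; AUCs and score
ordering are unchanged. Pass `anchor_specificity=None` to `fit_poc` for
the textbook fit.

If the cohort is perfectly separable, the MLE diverges; a ridge-penalized
logistic fit (scikit-learn, C=1) is substituted and flagged on the model.

POC ≥ 0.5 is screen-positive, inclusively.

## 3. Cancer risk score (CRS)

The CRS integrates five per-subject features — the four genomic scores and
the POC index:

    CRS_raw = a·cna + b·fs + c·endmotif + d·virus + e·poc.

Choices the published formula leaves open, and how they are fixed here:

* **Standardization.** Each feature is z-scored against the training
  noncancer mean/SD, so the weights compare likes with likes.
* **Weight constraint.** AUC is invariant to positive rescaling, so only
  the weight direction matters; weights are restricted to the unit simplex
  (nonnegative, sum 1).
* **Search.** Exhaustive enumeration of the step-0.05 simplex lattice
  (10,626 tuples), maximizing the empirical Mann–Whitney AUC. Ties break
  to the lexicographically smallest tuple in (a,b,c,d,e) order, making the
  result deterministic. A leaderboard of the top tuples is available for
  audit. The trained weights of the original product were never published;
  only the *procedure* is reproducible.
* **Calibration.** The weighted score is mapped affinely so that the
  training-noncancer median sits at 0 and the noncancer 98th percentile at
  2.0. The published rule fixes only the (98% specificity → 2.0) pair; the
  median anchor is this package's choice to make the map identifiable, and
  it is recorded in the model file. Percentiles are linearly interpolated
  (type 7, the numpy/R default) everywhere, so the calibration and the
  `threshold_at_specificity` helper agree bit-for-bit.

CRS ≥ 2.0 is positive, inclusively. The CRS is trained on the full cohort
(cases and controls), matching how the standalone test is evaluated, and
then reused unchanged as the cascade's second step.

## 4. Two-step cascade

Everyone gets the POC test. POC < 0.5 stops at step 1 (predicted
noncancer, CRS never measured). POC ≥ 0.5 proceeds to the CRS; CRS ≥ 2.0
is predicted cancer, otherwise predicted noncancer at step 2. Structural
consequences, which hold on any input and are enforced by property tests:
cascade positives are a subset of step-1 positives, cascade specificity ≥
step-1 specificity, cascade sensitivity ≤ step-1 sensitivity, and the
number of second-step tests equals the number of step-1 positives.
Unstaged and missing-stage cancers count as cancer in every performance
figure (they are pathology-confirmed cases).

## 5. Performance statistics

* Empirical AUC is the Mann–Whitney statistic (ties credit 0.5), computed
  by midranks in O(n log n) and cross-checked in the tests against an
  all-pairs count and scikit-learn.
* The DeLong test compares two AUCs measured on the same subjects via
  placement-value covariances; two-sided p against the standard normal.
  Identical score vectors return z = 0, p = 1; a zero-variance contrast
  with a nonzero AUC difference is flagged degenerate with the p-value
  reported absent. The test suite checks the p-value against a
  100,000-replicate paired bootstrap.
* Sensitivity/specificity at a cutoff use the same inclusive (≥) boundary
  as the classifiers, with exact Clopper–Pearson 95% intervals (the
  standard epidemiology-package convention for proportions).

## 6. Screening projection

Case–control (retrospective) sensitivity overstates prospective screening
sensitivity. Lacking real-world data for these tests, the projection
scales each strategy's case–control sensitivity by the
prospective/retrospective ratio observed for the comparator test in its
two published studies (28.9% / 51.5%); specificities are carried over
unchanged (the published specificities agree closely across settings).

The rounding pipeline is part of the contract, chosen so the projected
table is exactly reproducible at the printed precision: the adjusted
sensitivity is rounded half-up to one decimal in percent *before* any
count is formed (95,000 × 0.224 = 21,280; the unrounded 0.22391 would
give 21,271); the expected cancer count is population × incidence
(5,000,000 × 1.9% = 95,000, treated as exact); TP and FP are rounded
half-up and TN/FN filled by complement so the 2×2 cells always sum to the
population; percentages print to one decimal; likelihood ratios to one
decimal; NNS = 1/(incidence × sensitivity) to the nearest integer.

The two-step scenario's operating point (39.9% / 99.3%) enters the
projection as a measured input from the case–control cascade, not as an
analytic composition of the two stages — the projection reproduces what
was measured, it does not re-derive it.

## 7. Cost model

A single-test strategy costs population × price. The two-step strategy
costs population × step-1 price plus (projected step-1 positives) ×
follow-up price, where the step-1 positive volume is the OncoSeek
scenario's TP + FP (26,600 + 441,450 = 468,050) and the follow-up price
($670) is below the standalone price ($750) because the marker results
carry over. Cost per cancer case detected divides the total by true
positives only (dividing by all screen positives is a different, also
defensible, convention; the true-positive convention is the one that
reproduces the published per-case figures). Totals render in $ millions to
one decimal; unit costs to the nearest dollar. Currency is unit-agnostic;
no discounting or downstream-workup costs are modeled.

## 8. Determinism and problem sizes

Every stochastic step flows from one integer seed through
`numpy.random.default_rng`; identical configuration + seed reproduces the
entire report bundle byte-for-byte (no timestamps inside artifacts). The
default study sizes are the published ones: 1,197 subjects per cohort,
three seeds for calibration-recovery checks, a 10,626-point weight
lattice, and a five-million-person closed-form projection; the whole
pipeline runs in a few seconds on one CPU.

## Known limitations

* Calibration targets are printed summary statistics only; the real joint
  distribution of markers and genomic scores is unknown, so agreement is
  at the level of AUCs and operating points, not score distributions.
* The exchangeable-correlation burden model is the simplest structure
  consistent with the published integrated AUC; richer dependence (e.g.
  cancer-type-specific signatures) would change cascade overlap patterns.
* The projection is a closed-form expected-value calculation; it carries
  no sampling uncertainty, stage-shift, overdiagnosis, or mortality model,
  and no quality-adjusted life-year analysis.
* Whether the second-step threshold should be recalibrated on the
  step-1-positive subpopulation in a deployed product is an open design
  question; here the standalone calibration is reused, matching the
  published evaluation.
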