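# Methods

This note documents the models and procedures implemented in `aptox`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic data does and does not establish.

## The prediction problem

The endpoint is binary: a CTCAE grade ≥ 2 (APT2) or ≥ 3 (APT3) acute
pulmonary toxicity event within six months of the start of VMAT
radiotherapy for locally advanced lung cancer. Event rates around 20–25 %
make the classes imbalanced enough that plain accuracy is misleading;
balanced accuracy (mean of sensitivity and specificity) is the primary
score throughout. Models are built on a training cohort only — feature
selection, fitting and threshold choice never see the test cohort — and
evaluated once on the held-out cohort.

## Synthetic cohorts

The generator is a pure function of `CohortConfig` (including its seed):
identical config ⇒ identical cohort. It emulates the *statistical
structure* the analysis assumes, not anatomy.

**Geometry.** Arrays are indexed (z, y, x), default 48³ voxels at 4 mm
(tests and examples use 12–16³ for speed). Organs are jittered ellipsoids:
two disjoint lungs (the homolateral one on the patient's right), a heart,
and a Pmap sub-region defined as the posterior third of the homolateral
lung (by y-coordinate quantile), which guarantees the containment
invariant `pmap_region ⊆ lungs` on any grid. Masks are uint8 0/1 volumes
sharing one frame; the registration step a real study needs is replaced by
construction in a common frame.

**Dose.** A VMAT-like plan: prescription-dose ellipsoidal target inside
the homolateral lung, exponential falloff with the distance-to-target
(e-folding length 25 mm, jittered ±15 % per patient as plan-quality
variation), plus a broad low-dose bath (4 Gy, 120 mm scale), multiplied
by a correlated noise field (5 % relative, smoothing σ = 1 voxel), then
normalized so the in-target peak equals the prescription dose — mirroring
clinical plan normalization and making the peak condition exact by
construction. Falloff length → 0 with zero bath gives zero dose off
target, which the tests exploit analytically.

**Covariates.** Age ~ N(66, 8) truncated to [40, 90]; 70 % male; WHO
performance status 0/1/2 with probabilities 0.35/0.50/0.15; chemotherapy
80 %; AJCC stage IIIA/IIIB/IIIC uniform; MEVS ~ N(2.0, 0.6) L/s truncated
to [0.6, 4.0]; smoking never/former/current 0.10/0.45/0.45; COPD 30 %.
These marginals are declared, clinically plausible defaults — nothing in
the emulated setting pins them down — and all are configurable.

**Outcome model.** Logistic with additive effects:
`logit P(APT2) = β₀ + β_pmap·DMean_Pmap + β_lung·DMean_2Lungs + Σ β_c·x_c`,
the simplest model consistent with a monotone dose–toxicity relationship.
APT3 is a Bernoulli(0.25) subset of APT2 cases (≈ 9/37 in the emulated
training cohort). The intercept is calibrated by bisection so that the
mean predicted probability over a sample of generated patients (default
n = 2000) matches the target marginal rate of 22.4 %, to within 0.005.
Default effect sizes are β_pmap = 0.35 and β_lung = 0.30 per Gy with a
COPD log-odds of 0.8: these were calibrated, by simulation of the true
linear predictor, so the *oracle* AUC of the generating model is ≈ 0.85 —
the midpoint of the test-cohort discrimination (0.83–0.90) reported for
models of this kind. Weaker defaults would produce cohorts in which no
method could demonstrate anything.

**What the generator does not emulate:** anatomy beyond ellipsoids,
breathing motion, DICOM-RT plan structure, inter-institution protocol
variation, or the correlation structure of real clinical covariates with
dose. Passing tests therefore demonstrate correctness and statistical
calibration of the *methods*, not clinical performance on real patients.

## Dose features

**DVH features.** `Vx` = percent of a structure's voxels receiving ≥ x Gy;
`Dmean` = mean masked dose. Implemented parametrically for any x and
structure; defaults cover V5/V10/V13 of the homolateral lung, V30 of both
lungs, V40 of the heart, and the mean doses to the homolateral lung, both
lungs and the Pmap region.

**Discretization.** Grey level = `floor(dose / 1 Gy) + 1`, anchored at
0 Gy, with doses at or above the top edge clamped into the last level;
`n_levels = ceil(max masked dose / bin width)`, minimum 1. ("One grey
level per Gy" is taken as a fixed bin *width* of 1 Gy; the bin width is
configurable.)

**GLCM.** One merged symmetric co-occurrence matrix per structure,
accumulated over all 13 unique 3D offsets at distance 1 and both
orientations, using only voxel pairs entirely inside the mask (no dose is
invented outside the organ), normalized to sum 1. Features follow IBSI
definitions with log base 2 and 0·log 0 = 0: joint variance
Σp(i,j)(i−μ)², difference variance (variance of the |i−j| distribution),
contrast Σp(i,j)(i−j)², entropy −Σp log₂ p, and
IC1 = (HXY − HXY1)/HX with HXY1 = −Σp(i,j)log₂(p_x(i)p_y(j)); IC1 is
defined 0 when HX = 0 (single-level degenerate matrix). Histogram energy
is Σᵢpᵢ² over the masked grey-level histogram. All six are cross-checked
against an independent pure-loop implementation, and against a hand
enumeration of a two-voxel volume (contrast 1, entropy 1 bit, variance
0.25, difference variance 0, IC1 −1).

**Kernel maps.** Voxel-wise texture maps recompute a feature on each
masked voxel's kernel³ neighbourhood (default 3), restricted to in-mask
voxels and clipped at volume borders; grey levels keep the global
discretization so values are comparable across voxels. Voxels whose
neighbourhood holds fewer than 2 valid voxels (or no adjacent pair, for
co-occurrence features) are flagged invalid rather than padded.

## Voxel-based significance mapping

Patients must share one grid frame (synthetic data is born aligned; real
data must be registered upstream — deformable registration is outside
this package's scope). Per valid voxel, a Welch (unequal-variance)
two-sample *t* contrasts the event vs no-event groups; "t-test" alone
does not pin the variant down and Welch is the safer default. Zero
variance in both groups gives t = 0 and a degeneracy flag.

Family-wise error is controlled by the permutation distribution of the
maximum |t| over voxels (max-T, Westfall–Young style): labels are
permuted, and `p_fwe(v) = (1 + #{max|t*| ≥ |t(v)|}) / (n_perm + 1)`, the
+1/+1 convention counting the observed labelling so p > 0 always. When
`n_perm` reaches the number of distinct label assignments the null is
enumerated exhaustively and p is exact. The test is two-sided; the t map
carries effect direction. Significant voxels are post-processed by
26-connectivity component labelling with a minimum cluster size. Region
overlap uses DICE = 2|A∩B|/(|A|+|B|), defined 0 when both masks are
empty. Desk-scale default is 500–1000 permutations; study-scale 10 000 is
a parameter away.

## Model pipeline

**SMOTE.** Synthetic minority rows `x_i + λ(x_nn − x_i)`, λ ~ U(0,1),
with `x_nn` among the k = 5 nearest minority neighbours (Euclidean
distance on z-scored features; interpolation is affine-invariant, so rows
are generated in the original feature space). The minority class is
oversampled to parity; originals are preserved. SMOTE is applied *after*
the train/evaluation split — inside each bootstrap replication, to the
in-bag rows only — never to evaluation rows, so evaluation is
leakage-free.

**Classifier.** A single-hidden-layer perceptron on z-scored inputs
(scikit-learn `MLPClassifier`), hidden width `ceil((n_features + 2)/2)`
by default, trained with L-BFGS and an L2 penalty (α = 0.01). L-BFGS was
chosen over SGD-with-early-stopping because at cohort scale (n ≈ 165) it
is both faster and exactly reproducible given the seed; the L2 penalty
plays the regularizing role a validation split would.

**Importance.** Permutation importance: mean drop in (balanced) accuracy
over R = 10 column shuffles, floored at 0 and normalized to sum 1 (the
importance algorithm of the original proprietary tool is undocumented;
permutation importance is model-agnostic and testable). If no feature
shows a positive drop the importances fall back to uniform.

**Decremental selection.** From the full set down to one feature: score
the current set by the mean out-of-bag balanced accuracy over B bootstrap
replications (train on the bootstrap sample, evaluate on out-of-bag rows;
single-class replications are redrawn, capped at 100 attempts), then drop
the least important feature and retrain. The retained set maximizes the
mean bootstrap score, ties resolving to the smaller set. Balanced
accuracy is the default score because the endpoint is imbalanced; plain
accuracy is a flag away. Study-scale B = 1000 is the config default;
desk-scale analyses use B = 10–100, which the selection-consistency test
(Monte-Carlo s.e. shrinks with B) justifies.

**Threshold.** The probability cut-off maximizes the Youden index over
midpoints between adjacent distinct predicted probabilities
(classification rule: positive when p > threshold); ties take the lowest
threshold, favouring sensitivity. Thresholds are printable as whole
percentages, as clinical reports do.

## Evaluation

`ConfusionSummary` carries exact fractions (se, sp, bacc = (se+sp)/2,
ppv, npv, f1 = 2tp/(2tp+fp+fn), Youden). Ratios with zero denominators
are flagged `None`, not returned as 0. The *printed* form rounds
percentages half-up to one decimal and computes the printed balanced
accuracy as the mean of the rounded Se and Sp — the convention under
which published tables of this kind are internally consistent at every
row (the raw mean differs in the second decimal for two of the twelve
benchmark rows). ROC AUC is the Mann–Whitney statistic with ties counted
½. Decision curves use `NB(p) = TP/n − FP/n · p/(1−p)` against treat-all
and treat-none; precision–recall points are enumerated at every distinct
score; calibration uses equal-width bins with empty bins omitted.

The published six-model benchmark rows (training n = 165, testing n = 42)
ship in `aptox.reference_tables`; four of the twelve printed F1 values
are consistent with their own confusion cells and only those are asserted.

## Simulation studies (`aptox.studies`)

Four end-to-end studies, each generating its own inputs, with desk-scale
defaults chosen to run on a single CPU in minutes:

* **FWE null** — 200 datasets of 20 patients on 8³ grids with no
  outcome-linked signal, 500 permutations: the observed family-wise error
  at α = 0.05 must stay within Monte-Carlo noise of the nominal level.
* **Region recovery** — 80 patients, a planted 5³ sensitive sub-region
  whose dose scales with a patient factor (10 % relative spread) on top
  of 5 % voxel noise, outcome logistic in the region's mean dose with a
  1 /Gy slope: the significance map should recover the region with
  DICE ≥ 0.5.
* **Selection retention** — 20 seeded cohorts (n = 165, 16³ grids) whose
  outcome depends only on `DMean_Pmap` (β = 0.3) and `DMean_2Lungs`
  (β = 0.5); the decremental search sees those two plus four clinical
  noise features (B = 25) and should keep both drivers in ≥ 80 % of runs.
* **SMOTE benefit** — 20 seeded imbalanced cohorts (event rate 0.2,
  n = 165/42), full combined-model procedure (selection with B = 10, then
  the Youden threshold) with vs without SMOTE; compared by the median
  held-out balanced accuracy.

## Known limitations

* Ellipsoidal anatomy and an isotropic dose model; no DICOM-RT, no
  registration, no breathing motion.
* The kernel-map computation is a per-voxel Python loop: fine at
  desk-scale grids, slow for 512³ clinical volumes.
* Permutation significance maps assume exchangeability of patients under
  the null; covariate-adjusted voxel models are not implemented.
* The decremental search is greedy; with strongly collinear dosimetric
  features (e.g. V30 of both lungs vs their mean dose) it may keep a
  proxy of a driver rather than the driver itself.
* Real-cohort performance figures (test AUC 0.83–0.90, DICE 0.35 between
  dose- and texture-derived sensitive regions) require the original
  patient data and are deliberately out of scope; the studies above are
  property checks, not clinical replications.
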