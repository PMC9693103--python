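# aptox

Prediction of acute pulmonary toxicity (APT) after lung VMAT radiotherapy,
from the planning dose distribution alone.

Roughly one patient in four treated with (chemo)radiotherapy for locally
advanced lung cancer develops CTCAE grade ≥ 2 acute pulmonary toxicity
within six months, even when every organ-based dose constraint is met.
Classical dose–volume histogram (DVH) features ignore *where* and *how
heterogeneously* dose is deposited. This package implements, end to end, a
modelling approach that adds two spatial signals on top of the usual
clinical and DVH features:

* **dose-map radiomics** — grey-level co-occurrence (GLCM) texture features
  computed on the 3D dose grid discretized at 1 Gy per grey level
  (variance, difference variance, contrast, entropy, the IC1 information
  measure of correlation, and histogram energy);
* **functional radiosensitivity (Pmap)** — the mean dose to a
  toxicity-sensitive lung sub-region identified by voxel-based analysis:
  per-voxel Welch *t* statistics contrasting patients with vs without APT,
  with family-wise error (FWE) control by max-T permutation.

Features are combined by an imbalance-aware neural-network procedure:
optional SMOTE oversampling, a single-hidden-layer perceptron, decremental
feature elimination stabilized by bootstrap out-of-bag balanced accuracy,
and a probability cut-off maximizing the Youden index `YI = Se + Sp − 1`.
Evaluation covers Se/Sp/balanced accuracy/PPV/NPV/F1, ROC AUC,
precision–recall, calibration, and decision-curve net benefit
`NB(p) = TP/n − FP/n · p/(1−p)`.

Patient-level imaging data of this kind is not publicly distributable, so
the package ships a **synthetic cohort generator**: ellipsoidal lungs,
heart and a posterior Pmap sub-region on a common grid; a VMAT-like dose
model (ellipsoidal target, exponential falloff, low-dose bath,
correlated multiplicative noise, peak normalized to the prescription);
clinically plausible covariates; and a logistic outcome model whose risk
rises with the mean Pmap dose and the two-lung mean dose, calibrated to a
22.4 % marginal event rate and to the discrimination (oracle AUC ≈ 0.85)
reported for cohorts of this kind. Every stage of the pipeline is
exercisable, and tested, without any download.

## Worked example

```python
from aptox import (CohortConfig, VoxelStack, dice, extract_region,
                   generate_planted_voxel_data, max_t_permutation)

config = CohortConfig(n_patients=2, grid_shape=(16, 16, 16))
data, lungs, labels, planted = generate_planted_voxel_data(
    config, n_patients=80, region_size=(5, 5, 5), effect=1.0, seed=5)
stack = VoxelStack(data=data, valid_mask=lungs, labels=labels)
sig = max_t_permutation(stack, n_perm=500, seed=5, alpha=0.05)
region = extract_region(sig, alpha=0.05, min_cluster=2)
print(int(lungs.sum()), int(planted.sum()), int(region.sum()),
      round(dice(region, planted), 2))
```

prints

```
440 81 81 1.0
```

i.e. of 440 lung voxels analysed, the 81-voxel planted sensitive region is
recovered exactly (DICE 1.0) by the permutation significance map at
FWE-corrected α = 0.05 — and under a global null the same machinery keeps
the family-wise error at the nominal level (see `aptox.studies`).

The `examples/` directory walks through each capability: cohort
generation, feature extraction, voxel significance mapping, decremental
feature selection, and the six-model comparison (radiomics / Pmap /
combined, each with and without SMOTE) with its report files.

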