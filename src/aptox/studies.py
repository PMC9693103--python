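"""Self-contained simulation studies exercising the whole pipeline.

Each function generates its own synthetic inputs, runs the method under
study and returns the measured quantity. They are the reproducible
counterparts of the properties the pipeline is meant to have: family-wise
error control under the null, localization of a planted sensitive region,
retention of truly informative features by the decremental search, and
the held-out benefit of SMOTE on imbalanced cohorts.

Problem sizes are desk-scale defaults (small grids, hundreds of
permutations, tens of bootstrap replications); every knob is an argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import CohortConfig, generate_cohort, generate_planted_voxel_data
from .features import extract_feature_table
from .metrics import confusion_from_predictions
from .pipeline import (
    PipelineConfig,
    decremental_selection,
    train_classifier,
    youden_threshold,
)
from .pmap import VoxelStack, dice, extract_region, max_t_permutation
from .workflow import fit_thresholded

__all__ = [
    "fwe_null_study",
    "region_recovery_study",
    "selection_recovery_study",
    "smote_benefit_study",
]


def fwe_null_study(
    n_datasets: int = 200,
    n_patients: int = 20,
    grid_shape: tuple[int, int, int] = (8, 8, 8),
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Observed family-wise error rate under a global null.

    Dose maps carry no outcome-linked signal (``effect=0``); the FWER is
    the fraction of datasets in which any voxel reaches p_fwe <= alpha.
    """
    cfg = CohortConfig(n_patients=2, grid_shape=grid_shape)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_datasets):
        ds_seed = int(rng.integers(2**31))
        data, lungs, labels, _ = generate_planted_voxel_data(
            cfg, n_patients=n_patients, effect=0.0, seed=ds_seed
        )
        if labels.sum() < 2 or (~labels).sum() < 2:
            labels = labels.copy()
            labels[: 2] = True
            labels[-2:] = False
        stack = VoxelStack(data=data, valid_mask=lungs, labels=labels)
        sig = max_t_permutation(stack, n_perm=n_perm,
                                seed=int(rng.integers(2**31)), alpha=alpha)
        if np.any(sig.p_fwe[lungs] <= alpha):
            rejections += 1
    return rejections / n_datasets


def region_recovery_study(
    n_patients: int = 80,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    region_size: tuple[int, int, int] = (5, 5, 5),
    effect: float = 1.0,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 5,
) -> float:
    """DICE between the recovered significance region and a planted one."""
    cfg = CohortConfig(n_patients=2, grid_shape=grid_shape)
    data, lungs, labels, planted = generate_planted_voxel_data(
        cfg, n_patients=n_patients, region_size=region_size,
        effect=effect, seed=seed,
    )
    stack = VoxelStack(data=data, valid_mask=lungs, labels=labels)
    sig = max_t_permutation(stack, n_perm=n_perm, seed=seed, alpha=alpha)
    region = extract_region(sig, alpha=alpha, min_cluster=2)
    return dice(region, planted)


_SELECTION_FEATURES = ("DMean_Pmap", "DMean_2Lungs", "age", "MEVS",
                       "smoking", "PS")


def selection_recovery_study(
    n_seeds: int = 20,
    n_patients: int = 165,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    bootstrap_B: int = 25,
    seed: int = 0,
) -> float:
    """Fraction of seeded runs whose retained set keeps both dose drivers.

    Cohorts are generated with the outcome depending only on the mean Pmap
    dose and the two-lung mean dose (strong effects, no clinical terms);
    the decremental search sees those two features plus clinical noise.
    """
    hits = 0
    for i in range(n_seeds):
        cfg = CohortConfig(
            n_patients=n_patients, grid_shape=grid_shape,
            beta_pmap=0.3, beta_lung=0.5, beta_clinical={},
            calibration_n=400, seed=seed + 1000 * (i + 1),
        )
        table = extract_feature_table(generate_cohort(cfg))
        X = table[list(_SELECTION_FEATURES)]
        y = table["apt2"].to_numpy()
        pipe = PipelineConfig(bootstrap_B=bootstrap_B, seed=seed + i,
                              importance_repeats=5, max_epochs=300)
        trace = decremental_selection(X, y, pipe)
        if {"DMean_Pmap", "DMean_2Lungs"} <= set(trace.chosen_features):
            hits += 1
    return hits / n_seeds


def smote_benefit_study(
    n_seeds: int = 20,
    n_train: int = 165,
    n_test: int = 42,
    event_rate: float = 0.2,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    bootstrap_B: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Held-out balanced accuracy with vs without SMOTE, over seeded cohorts.

    Runs the full combined-model procedure (decremental selection with
    bootstrap stabilization, then the Youden threshold) on imbalanced
    planted cohorts; SMOTE, when on, acts inside each bootstrap
    replication and on the final training fit. Returns the per-arm
    medians on the percent scale.
    """
    from .workflow import family_features

    baccs = {"smote": [], "nosmote": []}
    for i in range(n_seeds):
        base = dict(
            grid_shape=grid_shape, target_event_rate=event_rate,
            calibration_n=400,
        )
        train_cfg = CohortConfig(n_patients=n_train, seed=seed + 7000 + 13 * i,
                                 **base)
        test_cfg = dataclasses.replace(
            train_cfg, n_patients=n_test, seed=seed + 8000 + 13 * i,
            intercept=None,
        )
        train_tab = extract_feature_table(generate_cohort(train_cfg))
        test_tab = extract_feature_table(generate_cohort(test_cfg))
        cols = family_features("combined", train_tab)
        y_train = train_tab["apt2"].to_numpy()
        y_test = test_tab["apt2"].to_numpy()
        for arm, use_smote in (("smote", True), ("nosmote", False)):
            pipe = PipelineConfig(use_smote=use_smote, seed=seed + i,
                                  bootstrap_B=bootstrap_B,
                                  importance_repeats=3, max_epochs=300)
            clf, _ = fit_thresholded(train_tab[cols], y_train, pipe,
                                     select=True)
            pred = clf.predict(test_tab[cols])
            cm = confusion_from_predictions(y_test, pred)
            baccs[arm].append(100.0 * cm.bacc)
    return {
        "median_bacc_smote": float(np.median(baccs["smote"])),
        "median_bacc_nosmote": float(np.median(baccs["nosmote"])),
    }
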