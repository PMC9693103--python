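"""Synthetic-cohort generator: determinism, geometry, outcome model."""

import numpy as np
import pytest
from scipy.stats import binom

from aptox import (
    CohortConfig,
    calibrate_intercept,
    generate_cohort,
    generate_dose_grid,
    generate_structures,
    plant_outcome,
)
from aptox.cohort import (
    InvalidStructureError,
    StructureSet,
    _sample_outcome_features,
)


def test_cohort_is_pure_function_of_config(small_config):
    a = generate_cohort(small_config)
    b = generate_cohort(small_config)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.dose.values, rb.dose.values)
        assert ra.covariates == rb.covariates
        assert (ra.apt2, ra.apt3) == (rb.apt2, rb.apt3)


def test_structure_invariants_hold_for_random_configs():
    """Disjoint lungs, union, pmap containment, nonempty masks."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        shape = tuple(int(s) for s in rng.integers(6, 20, size=3))
        cfg = CohortConfig(n_patients=2, grid_shape=shape,
                           seed=int(rng.integers(2**31)))
        st = generate_structures(cfg, np.random.default_rng(cfg.seed))
        st.validate()  # raises on violation
        assert st.masks["pmap_region"].sum() >= 1


def test_structure_set_rejects_overlapping_lungs():
    m = np.ones((4, 4, 4), np.uint8)
    masks = {n: m.copy() for n in StructureSet.REQUIRED}
    with pytest.raises(InvalidStructureError):
        StructureSet(masks, spacing=(4.0, 4.0, 4.0))


def test_dose_noise_free_is_deterministic_and_homolateral_hotter():
    cfg = CohortConfig(n_patients=2, grid_shape=(16, 16, 16), noise_sd=0.0)
    st = generate_structures(cfg, np.random.default_rng(1))
    d1 = generate_dose_grid(cfg, st, np.random.default_rng(5)).values
    d2 = generate_dose_grid(cfg, st, np.random.default_rng(5)).values
    assert np.array_equal(d1, d2)
    homo = st.masks["lung_homo"].astype(bool)
    contra = st.masks["lung_contra"].astype(bool)
    assert d1[homo].mean() > d1[contra].mean()


def test_dose_peak_matches_prescription_and_nonnegative():
    cfg = CohortConfig(n_patients=2, grid_shape=(16, 16, 16))
    st = generate_structures(cfg, np.random.default_rng(3))
    d = generate_dose_grid(cfg, st, np.random.default_rng(3)).values
    assert np.all(d >= 0)
    assert 0.9 * cfg.prescription_dose <= d.max() <= 1.1 * cfg.prescription_dose


def test_vanishing_falloff_kills_dose_outside_target():
    """With zero bath and noise, dose ~ Rx exp(-d/lambda) -> 0 off-target."""
    cfg = CohortConfig(n_patients=2, grid_shape=(16, 16, 16),
                       noise_sd=0.0, bath_dose=0.0)
    st = generate_structures(cfg, np.random.default_rng(9))
    d = generate_dose_grid(cfg, st, np.random.default_rng(9),
                           falloff_mm=1e-6).values
    # voxels at the grid corner are far from any in-lung target
    assert d[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
    assert d.max() == pytest.approx(cfg.prescription_dose)


def test_plant_outcome_null_rate_is_half():
    cfg = CohortConfig(n_patients=2, beta_pmap=0.0, beta_lung=0.0,
                       beta_clinical={}, intercept=0.0)
    rng = np.random.default_rng(11)
    feats = {"DMean_Pmap": 10.0, "DMean_2Lungs": 5.0}
    draws = [plant_outcome(feats, cfg, rng)[0] for _ in range(4000)]
    assert np.mean(draws) == pytest.approx(0.5, abs=0.03)


def test_plant_outcome_requires_named_features():
    cfg = CohortConfig(n_patients=2)
    with pytest.raises(KeyError, match="DMean_2Lungs"):
        plant_outcome({"DMean_Pmap": 1.0}, cfg, np.random.default_rng(0))


def test_apt2_rate_increases_over_pmap_dose_tertiles():
    """Monte-Carlo check of the monotone logistic dependence."""
    cfg = CohortConfig(n_patients=2, beta_pmap=0.2, beta_lung=0.0,
                       beta_clinical={}, intercept=-4.0)
    rng = np.random.default_rng(17)
    doses = rng.uniform(5.0, 35.0, size=3000)
    events = np.array([
        plant_outcome({"DMean_Pmap": d, "DMean_2Lungs": 0.0}, cfg, rng)[0]
        for d in doses
    ])
    tertiles = np.digitize(doses, np.quantile(doses, [1 / 3, 2 / 3]))
    rates = [events[tertiles == k].mean() for k in range(3)]
    assert rates[0] < rates[1] < rates[2]


def test_apt3_implies_apt2(small_cohort):
    for r in small_cohort:
        assert r.apt2 or not r.apt3


def test_calibrated_intercept_hits_target_event_rate():
    """Bisection calibration reproduces the 22.4% marginal rate."""
    cfg = CohortConfig(n_patients=2, grid_shape=(8, 8, 8),
                       target_event_rate=0.224, calibration_n=2000, seed=31)
    intercept = calibrate_intercept(cfg)
    rng = np.random.default_rng(99)
    events = []
    for _ in range(5000):
        feats = _sample_outcome_features(cfg, rng)[0]
        events.append(plant_outcome(feats, cfg, rng, intercept=intercept)[0])
    assert np.mean(events) == pytest.approx(0.224, abs=0.02)


def test_cohort_event_count_within_binomial_band():
    """Pooled over 5 cohorts so a single unlucky binomial draw cannot
    dominate; the pooled count must sit in the 99% band at n = 5 x 165."""
    total = 0
    for seed in range(5):
        cfg = CohortConfig(n_patients=165, grid_shape=(12, 12, 12), seed=seed,
                           calibration_n=400)
        total += sum(r.apt2 for r in generate_cohort(cfg))
    n = 5 * 165
    lo, hi = binom.ppf([0.005, 0.995], n, 0.224)
    assert lo <= total <= hi


def test_two_patient_cohort_structure():
    cfg = CohortConfig(n_patients=2, grid_shape=(10, 10, 10), seed=1,
                       intercept=-2.0)
    cohort = generate_cohort(cfg)
    assert len(cohort) == 2
    for r in cohort:
        homo = r.structures.masks["lung_homo"]
        contra = r.structures.masks["lung_contra"]
        assert not np.any(homo & contra)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_patients=1)
    with pytest.raises(ValueError):
        CohortConfig(grid_shape=(3, 8, 8))
    with pytest.raises(ValueError):
        CohortConfig(target_event_rate=1.2)


def test_null_betas_give_chance_level_downstream_auc():
    """All-zero effects: a model trained downstream cannot beat chance."""
    from aptox.metrics import roc_auc
    from aptox.pipeline import PipelineConfig, train_classifier

    cfg = CohortConfig(n_patients=2, grid_shape=(8, 8, 8), beta_pmap=0.0,
                       beta_lung=0.0, beta_clinical={}, intercept=0.0)
    rng = np.random.default_rng(4)
    rows, labels = [], []
    for _ in range(1000):
        feats = _sample_outcome_features(cfg, rng)[0]
        labels.append(plant_outcome(feats, cfg, rng)[0])
        rows.append([feats["DMean_Pmap"], feats["DMean_2Lungs"]])
    X = np.asarray(rows)
    y = np.asarray(labels, dtype=int)
    model = train_classifier(X[:500], y[:500], PipelineConfig(seed=0))
    auc = roc_auc(model.predict_proba(X[500:]), y[500:])
    assert auc == pytest.approx(0.5, abs=0.07)
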