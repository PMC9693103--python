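"""Evaluation metrics, including the published six-model benchmark rows."""

import numpy as np
import pytest

import oracles
from aptox.metrics import (
    calibration_curve,
    confusion_from_predictions,
    confusion_metrics,
    decision_curve,
    precision_recall_curve,
    roc_auc,
    round_half_up,
)
from aptox.reference_tables import (
    COHORT_SIZES,
    PRINTED_F1_CONSISTENT,
    TESTING_ROWS,
    TRAINING_ROWS,
)

ALL_ROWS = [("training", k, v) for k, v in TRAINING_ROWS.items()] + [
    ("testing", k, v) for k, v in TESTING_ROWS.items()
]


# ------------------------------------------------------ confusion fixtures

@pytest.mark.parametrize("cohort,model,row", ALL_ROWS,
                         ids=[f"{c}-{m}" for c, m, _ in ALL_ROWS])
def test_published_rows_reproduce_from_their_confusion_cells(cohort, model, row):
    cm = confusion_metrics(tp=row["tp"], fp=row["fp"], tn=row["tn"], fn=row["fn"])
    printed = cm.printed()
    assert printed["se"] == row["se"]
    assert printed["sp"] == row["sp"]
    assert printed["bacc"] == row["bacc"]
    if "ppv" in row:
        assert printed["ppv"] == row["ppv"]
    if "npv" in row:
        assert printed["npv"] == row["npv"]
    if (cohort, model) in PRINTED_F1_CONSISTENT:
        assert printed["f1"] == row["f1"]


def test_published_event_rates_recompute_from_cohort_counts():
    train = COHORT_SIZES["training"]
    test = COHORT_SIZES["testing"]
    assert round_half_up(100 * train["events"] / train["n"]) == 22.4
    # 8/42 = 19.048%: the printed 19.1 reflects a double rounding (19.05 -> 19.1)
    assert abs(100 * test["events"] / test["n"] - test["printed_rate"]) < 0.06


def test_confusion_counts_are_internally_consistent():
    for _, _, row in ALL_ROWS:
        cohort_n = row["tp"] + row["fp"] + row["tn"] + row["fn"]
        assert cohort_n in (165, 42)
        assert row["tp"] + row["fn"] in (37, 8)  # event counts


def test_perfect_classifier_metrics():
    cm = confusion_metrics(tp=5, fp=0, tn=10, fn=0)
    assert cm.se == cm.sp == cm.bacc == 1.0
    assert cm.youden == 1.0


def test_undefined_ppv_flagged_not_zero():
    cm = confusion_metrics(tp=0, fp=0, tn=5, fn=3)
    assert cm.ppv is None
    assert cm.npv == pytest.approx(5 / 8)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        confusion_metrics(tp=-1, fp=0, tn=1, fn=1)


def test_confusion_from_predictions_roundtrip():
    y = np.array([1, 1, 0, 0, 1, 0])
    pred = np.array([1, 0, 0, 1, 1, 0])
    cm = confusion_from_predictions(y, pred)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)


# ----------------------------------------------------------------- AUC

def test_auc_perfect_and_reversed():
    y = [0, 0, 1, 1]
    assert roc_auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
    assert roc_auc([0.9, 0.8, 0.2, 0.1], y) == 0.0


def test_auc_with_ties_matches_allpairs_oracle(rng):
    scores = rng.integers(0, 5, size=30) / 4.0  # forces ties
    y = (rng.random(30) < 0.4).astype(int)
    if y.sum() in (0, 30):
        y[0] = 1 - y[0]
    assert roc_auc(scores, y) == pytest.approx(oracles.allpairs_auc(scores, y))


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(50)
    y = (rng.random(50) < 0.3).astype(int)
    y[0], y[1] = 0, 1
    assert roc_auc(np.exp(3 * scores), y) == pytest.approx(roc_auc(scores, y))


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


# ----------------------------------------------------------------- DCA

def test_decision_curve_boundaries():
    p = np.array([0.1, 0.4, 0.6, 0.9])
    y = np.array([0, 0, 1, 1])
    dc = decision_curve(p, y, thresholds=[0.0, 0.95])
    assert dc.nb_all[0] == pytest.approx(0.5)  # prevalence at p=0
    assert dc.nb_model[1] == 0.0               # nobody above 0.95
    assert np.all(dc.nb_none == 0.0)


def test_decision_curve_matches_published_arithmetic():
    """n=42, TP=8, FP=7 at p=0.12 gives net benefit 0.168."""
    # scores: 8 events and 7 non-events above 0.12, 27 non-events below
    p = np.array([0.5] * 15 + [0.05] * 27)
    y = np.array([1] * 8 + [0] * 7 + [0] * 27)
    dc = decision_curve(p, y, thresholds=[0.12])
    assert dc.nb_model[0] == pytest.approx(0.168, abs=5e-4)


def test_decision_curve_dominance_near_zero_threshold(rng):
    p = rng.random(100)
    y = (rng.random(100) < 0.3).astype(int)
    dc = decision_curve(p, y, thresholds=[0.001])
    assert dc.nb_model[0] <= dc.nb_all[0] + 1e-9


def test_decision_curve_rejects_threshold_one():
    with pytest.raises(ValueError):
        decision_curve([0.5], [1], thresholds=[1.0])


# --------------------------------------------------- PR and calibration

def test_perfect_classifier_pr_reaches_one_one():
    pr = precision_recall_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    has = any(np.isclose(prec, 1) and np.isclose(rec, 1)
              for _, prec, rec in pr)
    assert has


def test_single_bin_calibration_returns_prevalence(rng):
    p = rng.uniform(0, 1, 200)
    y = (rng.random(200) < 0.25).astype(int)
    cal = calibration_curve(p, y, bins=1)
    assert cal.shape[0] == 1
    assert cal[0, 2] == pytest.approx(y.mean())


def test_self_calibrated_probabilities_are_calibrated():
    """Outcomes drawn from their own probabilities land within 0.05 per bin."""
    rng = np.random.default_rng(3)
    p = rng.uniform(0.02, 0.98, 5000)
    y = (rng.random(5000) < p).astype(int)
    cal = calibration_curve(p, y, bins=10)
    assert np.all(np.abs(cal[:, 1] - cal[:, 2]) <= 0.05)
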