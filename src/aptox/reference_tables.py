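"""Published benchmark tables for six APT2 prediction models.

Reference confusion cells reported for a two-cohort lung-VMAT study
(training n = 165 with 37 grade >= 2 events, prospective testing n = 42
with 8 events) across six models: radiomics-only, Pmap (functional
radiosensitivity) and combined feature sets, each with and without SMOTE
imbalance correction. Useful as a comparison benchmark and as ground
truth for the metric arithmetic in this package.

Counts follow the reporting layout (positive = above the probability
cut-off, event = APT >= grade 2): tp = events above, fp = non-events
above, tn = non-events below, fn = events below.

``PRINTED_F1_CONSISTENT`` lists the rows whose printed F1 equals
2tp/(2tp+fp+fn) from their own cells; the remaining printed F1 values are
not reproducible from the published counts.
"""

from __future__ import annotations

__all__ = [
    "TRAINING_ROWS",
    "TESTING_ROWS",
    "PRINTED_F1_CONSISTENT",
    "COHORT_SIZES",
]

#: model -> dict(tp, fp, tn, fn, printed Se/Sp/Bacc/F1 and cut-off %)
TRAINING_ROWS = {
    "rad_nosmote": dict(tp=32, fp=20, tn=108, fn=5, se=86.5, sp=84.4,
                        bacc=85.5, f1=0.72, auc=0.91, cutoff=18),
    "rad_smote": dict(tp=28, fp=28, tn=100, fn=9, se=75.7, sp=78.1,
                      bacc=76.9, f1=0.66, auc=0.85, cutoff=24),
    "pmap_nosmote": dict(tp=37, fp=2, tn=126, fn=0, se=100.0, sp=98.4,
                         bacc=99.2, f1=1.00, auc=0.99, cutoff=8),
    "pmap_smote": dict(tp=37, fp=11, tn=117, fn=0, se=100.0, sp=91.4,
                       bacc=95.7, f1=0.96, auc=0.99, cutoff=6),
    "comb_nosmote": dict(tp=37, fp=2, tn=126, fn=0, se=100.0, sp=98.4,
                         bacc=99.2, f1=1.00, auc=0.99, cutoff=8),
    "comb_smote": dict(tp=30, fp=10, tn=118, fn=7, se=81.1, sp=92.2,
                       bacc=86.7, f1=0.85, auc=0.91, cutoff=12),
}

TESTING_ROWS = {
    "rad_nosmote": dict(tp=7, fp=8, tn=26, fn=1, se=87.5, sp=76.5,
                        bacc=82.0, f1=0.63, auc=0.83, cutoff=18),
    "rad_smote": dict(tp=6, fp=6, tn=28, fn=2, se=75.0, sp=82.4,
                      bacc=78.7, f1=0.60, auc=0.83, cutoff=24),
    "pmap_nosmote": dict(tp=7, fp=8, tn=26, fn=1, se=87.5, sp=76.5,
                         bacc=82.0, f1=0.61, auc=0.81, cutoff=8),
    "pmap_smote": dict(tp=8, fp=12, tn=22, fn=0, se=100.0, sp=64.7,
                       bacc=82.4, f1=0.57, auc=0.79, cutoff=6),
    "comb_nosmote": dict(tp=5, fp=8, tn=26, fn=3, se=62.5, sp=76.5,
                         bacc=69.5, f1=0.57, auc=0.83, cutoff=8),
    "comb_smote": dict(tp=8, fp=7, tn=27, fn=0, se=100.0, sp=79.4,
                       bacc=89.7, f1=0.71, auc=0.90, cutoff=12,
                       ppv=53.3, npv=100.0),
}

#: (cohort, model) rows whose printed F1 matches 2tp/(2tp+fp+fn)
PRINTED_F1_CONSISTENT = (
    ("training", "rad_nosmote"),
    ("testing", "rad_smote"),
    ("testing", "pmap_nosmote"),
    ("testing", "pmap_smote"),
)

COHORT_SIZES = {
    "training": dict(n=165, events=37, printed_rate=22.4),
    "testing": dict(n=42, events=8, printed_rate=19.1),
}
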