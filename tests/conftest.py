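"""Shared fixtures.

The heavyweight simulation studies (threshold recovery, method ordering,
CNN recovery) are session-scoped: several tests assert different properties
of the same experiment, which therefore runs once.
"""

from __future__ import annotations

import numpy as np
import pytest

from aoqc import (
    CnnConfig,
    classify_by_thresholds,
    estimate_thresholds,
    fit_linear_model,
    fit_random_forest,
    predict_linear,
    probability_curves,
)
from aoqc import cnn_classifier, focus_metric, grading_agreement, synthetic_mosaic
from aoqc.patch import Patch

# ---------------------------------------------------------------------------
# Threshold-recovery study design (frozen):
# scores are class-conditional Gaussians, sd 3, centered inside the planted
# bands [0,8), [8,35), [35,75] at (3.5, 14.5, 54.0), class mix
# (0.30, 0.55, 0.15). With these centers both the forest probability-curve
# crossings (analytic 8.50, 34.55) and the OLS implied boundaries (analytic
# 7.21, 35.54) identify the planted cuts (8, 35).
PLANTED_T12, PLANTED_T23 = 8.0, 35.0
RECOVERY_CENTERS = {1: 3.5, 2: 14.5, 3: 54.0}
RECOVERY_MIX = (0.30, 0.55, 0.15)
RECOVERY_SD = 3.0
#: analytic Bayes crossings for the design above
BAYES_T12, BAYES_T23 = 8.504, 34.546


def simulate_band_scores(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (scores, labels) from the frozen recovery design."""
    rng = np.random.default_rng(seed)
    labels = rng.choice([1, 2, 3], size=n, p=RECOVERY_MIX)
    centers = np.array([np.nan] + [RECOVERY_CENTERS[c] for c in (1, 2, 3)])
    scores = centers[labels] + rng.normal(0, RECOVERY_SD, n)
    return np.clip(scores, 0.0, 75.0), labels


@pytest.fixture(scope="session")
def threshold_recovery():
    """Fit both LAPE classifiers on one simulated training set (n=3000) and
    evaluate on an independent draw; returns everything downstream tests need."""
    s_train, y_train = simulate_band_scores(3000, seed=7)
    s_test, y_test = simulate_band_scores(3000, seed=8)

    linear = fit_linear_model(s_train, y_train)
    forest = fit_random_forest(s_train, y_train, seed=7)
    curves = probability_curves(forest)
    thresholds = estimate_thresholds(curves)

    forest_acc = float(np.mean(classify_by_thresholds(s_test, thresholds) == y_test))
    linear_acc = float(np.mean(predict_linear(linear, s_test) == y_test))
    bayes = classify_by_thresholds(
        s_test,
        type(thresholds)(t12=BAYES_T12, t23=BAYES_T23),
    )
    bayes_acc = float(np.mean(bayes == y_test))
    return {
        "linear": linear,
        "thresholds": thresholds,
        "curves": curves,
        "forest_acc": forest_acc,
        "linear_acc": linear_acc,
        "bayes_acc": bayes_acc,
    }


# ---------------------------------------------------------------------------
# Rendered-cohort experiments

LIGHT_CNN = dict(conv_blocks=((16, 5), (16, 5), (32, 5)), fc_widths=(32,))


def _split_masks(frame, seed, train_fraction=0.6):
    train_subj, _ = grading_agreement.subjectwise_split(frame, train_fraction, seed)
    tr = frame["subject_id"].isin(train_subj).to_numpy()
    return tr, ~tr


@pytest.fixture(scope="session")
def ordering_experiment():
    """Common moderate-overlap cohort: LAPE linear, LAPE forest and CNN
    graders trained on the same training subjects and evaluated on the same
    held-out subjects."""
    cohort = synthetic_mosaic.generate_cohort(30, seed=23, patches_per_subject=30)
    frame = synthetic_mosaic.cohort_frame(cohort)
    patches = [lp.patch for lp, _ in cohort]
    labels = frame["category"].to_numpy()
    subjects = frame["subject_id"].to_numpy()
    scores = np.array([focus_metric.lape(p) for p in patches])
    tr, va = _split_masks(frame, seed=23)

    linear = fit_linear_model(scores[tr], labels[tr])
    linear_acc = 100.0 * float(np.mean(predict_linear(linear, scores[va]) == labels[va]))

    forest = fit_random_forest(scores[tr], labels[tr], seed=23)
    thresholds = estimate_thresholds(probability_curves(forest))
    forest_acc = 100.0 * float(
        np.mean(classify_by_thresholds(scores[va], thresholds) == labels[va])
    )

    cfg = CnnConfig(**LIGHT_CNN, epochs=8, early_stop_patience=3, seed=23)
    model, history = cnn_classifier.train(
        [p for p, m in zip(patches, tr) if m],
        labels[tr].tolist(),
        cfg,
        subject_ids=subjects[tr].tolist(),
    )
    pred, _ = cnn_classifier.predict_batch(model, [p for p, m in zip(patches, va) if m])
    cnn_acc = 100.0 * float(np.mean(pred == labels[va]))

    return {
        "linear_acc": linear_acc,
        "forest_acc": forest_acc,
        "cnn_acc": cnn_acc,
        "scores": scores,
        "labels": labels,
        "history": history,
    }


@pytest.fixture(scope="session")
def cnn_recovery_experiment():
    """Clear-separation cohort (1,500 patches): CNN trained normally and on
    label-shuffled data, both evaluated subject-wise on held-out subjects."""
    cohort = synthetic_mosaic.generate_cohort(
        50,
        seed=11,
        patches_per_subject=30,
        scene_sampler=synthetic_mosaic.scene_for_category_clear,
    )
    frame = synthetic_mosaic.cohort_frame(cohort)
    patches = [lp.patch for lp, _ in cohort]
    labels = frame["category"].to_numpy()
    subjects = frame["subject_id"].to_numpy()
    tr, va = _split_masks(frame, seed=11, train_fraction=0.7)

    cfg = CnnConfig(**LIGHT_CNN, epochs=6, early_stop_patience=3, seed=11)
    train_patches = [p for p, m in zip(patches, tr) if m]
    val_patches = [p for p, m in zip(patches, va) if m]

    model, history = cnn_classifier.train(
        train_patches, labels[tr].tolist(), cfg, subject_ids=subjects[tr].tolist()
    )
    pred, _ = cnn_classifier.predict_batch(model, val_patches)
    acc = 100.0 * float(np.mean(pred == labels[va]))

    rng = np.random.default_rng(99)
    shuffled = rng.permutation(labels[tr])
    model_s, _ = cnn_classifier.train(
        train_patches, shuffled.tolist(), cfg, subject_ids=subjects[tr].tolist()
    )
    pred_s, _ = cnn_classifier.predict_batch(model_s, val_patches)
    # the cohort is unbalanced (~56% category 2), so chance level is only
    # 1/3 on the *balanced* scale: use mean per-class recall for the control
    true_va = labels[va]
    shuffled_balanced_acc = 100.0 * float(
        np.mean([np.mean(pred_s[true_va == c] == c) for c in (1, 2, 3)])
    )

    return {
        "accuracy": acc,
        "shuffled_balanced_accuracy": shuffled_balanced_acc,
        "history": history,
    }


# ---------------------------------------------------------------------------
# Small fixtures


@pytest.fixture(scope="session")
def random_patches():
    """100 random positive 65x65 patches for oracle-equivalence checks."""
    rng = np.random.default_rng(505)
    return [
        Patch(intensities=rng.uniform(0.05, 1.0, (65, 65)), pixel_scale=50 / 65)
        for _ in range(100)
    ]


@pytest.fixture(scope="session")
def mosaic_patches():
    """20 seeded pristine synthetic mosaics at varied eccentricity."""
    out = []
    for seed in range(20):
        params = synthetic_mosaic.SceneParams(
            cone_spacing=2.5 + 0.55 * (1 + seed % 10), psf_sigma=0.0, seed=seed
        )
        out.append(synthetic_mosaic.generate_patch(params).patch)
    return out
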