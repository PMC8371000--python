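"""Manual grading model: adjudication, agreement and performance statistics.

Three graders assign each patch an ordinal category in {1, 2, 3}; the
reference standard is formed by adjudicating disagreements. Classifier and
grader performance against the reference is summarized by a 3x3 confusion
matrix and overall accuracy; pairwise agreement by (unweighted) Cohen's
kappa; and the ability of a focus score to separate categories by the
Kruskal-Wallis rank test. Training/validation machinery (subject-wise
splits, subject-stratified k-fold CV) also lives here because the unit of
independence is the subject, not the patch.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GradingRecord",
    "ConfusionMatrix",
    "adjudicate",
    "confusion",
    "accuracy",
    "cohens_kappa",
    "subjectwise_split",
    "kfold_cv",
    "kruskal_wallis_by_category",
]

CATEGORIES = (1, 2, 3)


@dataclass(frozen=True)
class GradingRecord:
    """One grader's category for one patch."""

    patch_id: str
    grader_id: str
    category: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be in {CATEGORIES}, got {self.category}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows = reference standard, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValueError("counts must be a nonnegative 3x3 integer matrix")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def render(self) -> str:
        """Plain-text render, reference categories as rows."""
        lines = ["ref\\pred " + " ".join(f"{c:>6d}" for c in CATEGORIES)]
        for i, c in enumerate(CATEGORIES):
            lines.append(f"{c:>8d} " + " ".join(f"{v:>6d}" for v in self.counts[i]))
        lines.append(f"accuracy: {accuracy(self):.1f}%")
        return "\n".join(lines)


def adjudicate(
    records: Sequence[GradingRecord],
    senior_grader: str,
    on_tie: str = "senior",
) -> int:
    """Reference-standard category for one patch from >= 2 graders.

    Unanimity or majority rules directly. A full three-way split is settled
    by the designated senior grader's label (a computational stand-in for
    the facilitated consensus discussion used with human graders); with
    ``on_tie="flag"`` it raises instead so the patch can be routed to
    manual review.
    """
    if len(records) < 2:
        raise ValueError("adjudication needs records from at least 2 graders")
    patch_ids = {r.patch_id for r in records}
    if len(patch_ids) != 1:
        raise ValueError(f"records span multiple patches: {sorted(patch_ids)}")
    graders = [r.grader_id for r in records]
    if len(set(graders)) != len(graders):
        raise ValueError("duplicate grader for this patch")
    if senior_grader not in graders:
        raise ValueError(f"senior grader {senior_grader!r} did not grade this patch")

    votes = Counter(r.category for r in records)
    top, top_n = votes.most_common(1)[0]
    if top_n > len(records) / 2:
        return top
    if on_tie == "flag":
        raise ValueError(f"no majority for patch {records[0].patch_id}: {dict(votes)}")
    return next(r.category for r in records if r.grader_id == senior_grader)


def confusion(
    reference: Sequence[int], predicted: Sequence[int]
) -> ConfusionMatrix:
    """Cross-tabulate reference vs predicted categories."""
    ref = np.asarray(reference, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if ref.shape != pred.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {pred.shape}")
    for name, arr in (("reference", ref), ("predicted", pred)):
        if not np.isin(arr, CATEGORIES).all():
            raise ValueError(f"{name} labels must be in {CATEGORIES}")
    counts = np.zeros((3, 3), dtype=int)
    for r, p in zip(ref, pred):
        counts[r - 1, p - 1] += 1
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of correctly classified patches: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def cohens_kappa(rater_a: Sequence[int], rater_b: Sequence[int]) -> float:
    """Unweighted Cohen's kappa between two label vectors.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement from the product of marginals. In the
    degenerate case p_e = 1 (both raters constant with identical marginals)
    the statistic is defined as 1 when agreement is perfect, and is a
    domain error otherwise.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be equal-length and nonempty")
    labels = np.union1d(a, b)
    n = a.size
    p_o = float(np.mean(a == b))
    pa = np.array([(a == c).mean() for c in labels])
    pb = np.array([(b == c).mean() for c in labels])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 without perfect agreement")
    return (p_o - p_e) / (1.0 - p_e)


def subjectwise_split(
    manifest: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Split subjects (not patches) into disjoint train/validation sets.

    Every patch follows its subject, preventing leakage of within-subject
    correlation across the split. At least one subject lands on each side.
    """
    if not (0 < train_fraction < 1):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    subjects = sorted(manifest["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_train = int(round(train_fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train = sorted(subjects[i] for i in order[:n_train])
    val = sorted(subjects[i] for i in order[n_train:])
    return train, val


def kfold_cv(
    manifest: pd.DataFrame,
    k: int,
    fit_predict: Callable[[pd.DataFrame, pd.DataFrame], Sequence[int]],
    seed: int = 0,
) -> tuple[list[float], float]:
    """Subject-stratified k-fold cross-validation.

    Subjects are shuffled (seeded) and dealt into ``k`` folds; each fold is
    held out once. ``fit_predict(train_rows, test_rows)`` must return
    predicted categories for the test rows, which are scored against the
    ``category`` column. Returns the per-fold accuracies (percent) and
    their mean.
    """
    subjects = sorted(manifest["subject_id"].unique())
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} available subjects")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(subjects[idx])

    accs = []
    for fold in folds:
        test_mask = manifest["subject_id"].isin(fold)
        train_rows = manifest[~test_mask]
        test_rows = manifest[test_mask]
        pred = np.asarray(fit_predict(train_rows, test_rows), dtype=int)
        accs.append(100.0 * float(np.mean(pred == test_rows["category"].to_numpy())))
    return accs, float(np.mean(accs))


def kruskal_wallis_by_category(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across the score groups defined by
    category labels, with the chi-square p-value (df = groups - 1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = [scores[labels == c] for c in np.unique(labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
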