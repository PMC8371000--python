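"""Category classification from a single LAPE score.

Two multiclass schemes operate on the scalar focus score:

* **linear-regression rounding** — ordinary least squares of the numeric
  category (1, 2, 3) on the score; a prediction is the fitted value rounded
  to the nearest category. Because rounding cuts the fitted line at 1.5 and
  2.5, the implied score-axis boundaries are ``(1.5 - b)/a`` and
  ``(2.5 - b)/a`` — necessarily equidistant.

* **random forest + probability curves** — a 1,000-tree classification
  forest on the score alone; class-probability curves are evaluated on the
  score grid 0-75 in 0.1 steps (751 points), Loess-smoothed, and the
  category cut points are read off where adjacent class curves intersect
  (equivalently, where the winning class's probability passes 50%).

Either route yields a pair of thresholds (t12, t23) partitioning [0, 75]
into the three categories; scores falling exactly on a threshold go to the
middle band, consistent with strict "<" / ">" outer bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import config

__all__ = [
    "LapeThresholds",
    "ProbabilityCurves",
    "LinearModel",
    "ForestModel",
    "fit_linear_model",
    "predict_linear",
    "fit_random_forest",
    "probability_curves",
    "estimate_thresholds",
    "classify_by_thresholds",
]

SCORE_GRID = np.round(np.arange(0, 75.0 + 1e-9, 0.1), 1)  # 751 points


@dataclass(frozen=True)
class LapeThresholds:
    """Two cut points partitioning the LAPE axis into categories 1 | 2 | 3."""

    t12: float
    t23: float

    def __post_init__(self) -> None:
        if not (0 <= self.t12 < self.t23 <= 75):
            raise ValueError(
                f"need 0 <= t12 < t23 <= 75, got ({self.t12}, {self.t23})"
            )


@dataclass(frozen=True)
class ProbabilityCurves:
    """Class-probability curves over the 751-point score grid."""

    grid: np.ndarray
    raw: np.ndarray  # (751, 3), rows sum to 1
    smoothed: np.ndarray  # (751, 3), Loess-smoothed per class


@dataclass(frozen=True)
class LinearModel:
    """OLS of numeric category on score: category ≈ slope * score + intercept."""

    slope: float
    intercept: float

    @property
    def implied_boundaries(self) -> tuple[float, float]:
        """Score values where the rounded prediction changes category."""
        if self.slope == 0:
            raise ValueError("flat model has no category boundaries")
        return ((1.5 - self.intercept) / self.slope, (2.5 - self.intercept) / self.slope)


@dataclass(frozen=True)
class ForestModel:
    """1,000-tree classification forest on the single LAPE feature."""

    forest: RandomForestClassifier
    classes: tuple[int, ...]


def _check_training_data(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if np.unique(s).size < 2:
        raise ValueError("degenerate design: scores are constant")
    if set(np.unique(y)) != {1, 2, 3}:
        raise ValueError("all three categories must be represented in training data")
    return s, y


def fit_linear_model(scores, labels) -> LinearModel:
    """Least-squares fit of numeric category (1, 2, 3) on LAPE score."""
    s, y = _check_training_data(scores, labels)
    slope, intercept = np.polyfit(s, y, 1)
    return LinearModel(slope=float(slope), intercept=float(intercept))


def predict_linear(model: LinearModel, score) -> np.ndarray | int:
    """Rounded, clamped category prediction. Half-integers round up."""
    s = np.asarray(score, dtype=float)
    value = model.slope * s + model.intercept
    cat = np.clip(np.floor(value + 0.5), 1, 3).astype(int)
    return int(cat) if np.isscalar(score) else cat


def fit_random_forest(
    scores, labels, n_trees: int = 1000, seed: int = 0
) -> ForestModel:
    """Classification forest on the single score feature (deterministic
    under ``seed``)."""
    s, y = _check_training_data(scores, labels)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(s.reshape(-1, 1), y)
    return ForestModel(forest=forest, classes=tuple(int(c) for c in forest.classes_))


def probability_curves(
    model: ForestModel, loess_span: float = config.LOESS_SPAN
) -> ProbabilityCurves:
    """Class probabilities over the 0-75 score grid, raw and Loess-smoothed.

    Smoothing is applied independently per class over the grid; smoothed
    values are clipped to [0, 1] but deliberately not renormalized, so each
    curve remains a smooth function of the raw one.
    """
    raw = model.forest.predict_proba(SCORE_GRID.reshape(-1, 1))
    smoothed = np.column_stack(
        [
            lowess(
                raw[:, j],
                SCORE_GRID,
                frac=loess_span,
                it=0,
                return_sorted=False,
            )
            for j in range(raw.shape[1])
        ]
    )
    return ProbabilityCurves(
        grid=SCORE_GRID.copy(), raw=raw, smoothed=np.clip(smoothed, 0.0, 1.0)
    )


def _crossings(diff: np.ndarray, grid: np.ndarray) -> list[float]:
    """Grid positions where ``diff`` crosses from <0 to >=0 (interpolated)."""
    out = []
    for i in range(1, len(diff)):
        if diff[i - 1] < 0 <= diff[i]:
            d0, d1 = diff[i - 1], diff[i]
            frac = -d0 / (d1 - d0) if d1 != d0 else 0.0
            out.append(float(grid[i - 1] + frac * (grid[i] - grid[i - 1])))
    return out


def estimate_thresholds(curves: ProbabilityCurves) -> LapeThresholds:
    """Read category cut points off the smoothed probability curves.

    t12 is the first score where the class-2 curve rises above class-1's;
    t23 the last score where class-3 rises above class-2. If either
    intersection is absent the training data could not order the classes
    and estimation fails.
    """
    p = curves.smoothed
    up12 = _crossings(p[:, 1] - p[:, 0], curves.grid)
    up23 = _crossings(p[:, 2] - p[:, 1], curves.grid)
    if not up12 or not up23:
        raise ValueError("probability curves do not intersect; cannot place thresholds")
    t12, t23 = up12[0], up23[-1]
    if not t12 < t23:
        raise ValueError(f"degenerate curve intersections: t12={t12:.2f} >= t23={t23:.2f}")
    return LapeThresholds(t12=t12, t23=t23)


def classify_by_thresholds(score, th: LapeThresholds) -> np.ndarray | int:
    """1 below t12, 3 above t23, else 2 (boundaries go to the middle band)."""
    s = np.asarray(score, dtype=float)
    cat = np.where(s < th.t12, 1, np.where(s > th.t23, 3, 2))
    return int(cat) if np.isscalar(score) else cat
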