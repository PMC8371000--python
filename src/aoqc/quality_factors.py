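"""Factors driving poor image quality: binary logistic regression and
per-location frequency summaries.

The outcome is *poor quality* (category 2) versus *acceptable* (category 3);
truncated patches (category 1) carry no usable content and are excluded.
Covariates are a healthy-vs-diseased indicator, retinal eccentricity
(degrees), age (years), axial length (mm), spherical equivalent (D), visual
acuity (ETDRS letters), and fixation stability (BCEA63, deg²). Effects are
reported as odds ratios with Wald 95% confidence intervals,
``OR = exp(beta)``, ``CI = exp(beta ± 1.96 SE)``.

The fit is a plain (non-clustered) maximum-likelihood logistic regression;
cluster-robust standard errors by subject are available via
``cov_type="cluster"`` because patches within a subject are correlated, but
are off by default to keep the model definition minimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SubjectMeta",
    "FactorModel",
    "COVARIATE_COLUMNS",
    "fit_quality_logistic",
    "category_frequency_by_location",
    "subject_fraction_poor",
]

log = logging.getLogger(__name__)

GROUPS = ("healthy", "DSM", "HCQ")

#: Covariate columns expected in the analysis frame, in report order.
COVARIATE_COLUMNS = (
    "healthy",
    "eccentricity",
    "age",
    "axial_length",
    "spherical_equivalent",
    "bcva",
    "bcea63",
)


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject biometry and demographics.

    age in years; axial_length in mm; spherical_equivalent in dioptres;
    bcva as ETDRS letter score; bcea63 (fixation stability) in degrees².
    """

    subject_id: str
    age: float
    axial_length: float
    spherical_equivalent: float
    bcva: float
    bcea63: float
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.axial_length > 1.82:
            raise ValueError("axial_length out of domain")
        if self.bcea63 < 0:
            raise ValueError("bcea63 must be nonnegative")

    @property
    def healthy(self) -> bool:
        return self.group == "healthy"


@dataclass(frozen=True)
class FactorModel:
    """Fitted logistic model: per-term coefficients, SEs and odds ratios."""

    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    n_obs: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - 1.96 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + 1.96 * self.se)

    def report(self) -> pd.DataFrame:
        """Model report: term, coefficient, SE, OR and 95% CI bounds."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _analysis_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Restrict to categories {2,3} and drop rows with missing covariates."""
    eligible = frame[frame["category"].isin([2, 3])].copy()
    if "healthy" not in eligible.columns:
        eligible["healthy"] = (eligible["group"] == "healthy").astype(float)
    cols = list(COVARIATE_COLUMNS) + ["category"]
    n_before = len(eligible)
    eligible = eligible.dropna(subset=cols)
    dropped = n_before - len(eligible)
    if dropped:
        log.warning("dropped %d rows with missing covariates", dropped)
    return eligible


def fit_quality_logistic(
    frame: pd.DataFrame, cov_type: str = "nonrobust"
) -> FactorModel:
    """Fit poor-quality (category 2 = 1) on subject/eye/location covariates.

    Parameters
    ----------
    frame
        Patch-level table with columns ``category`` (in {2, 3}; category-1
        rows, if present, are dropped), ``group`` or ``healthy``,
        ``eccentricity``, ``age``, ``axial_length``, ``spherical_equivalent``,
        ``bcva`` and ``bcea63``. A ``subject_id`` column is required for
        ``cov_type="cluster"``.
    cov_type
        ``"nonrobust"`` (plain Wald SEs, default) or ``"cluster"`` for
        subject-clustered robust SEs.

    Raises
    ------
    ValueError
        If only one outcome class is present, or the likelihood does not
        converge (e.g. perfect separation).
    """
    data = _analysis_frame(frame)
    y = (data["category"] == 2).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant: both categories 2 and 3 required")
    X = sm.add_constant(data[list(COVARIATE_COLUMNS)].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    kwargs = {}
    if cov_type == "cluster":
        kwargs = {
            "cov_type": "cluster",
            "cov_kwds": {"groups": data["subject_id"].to_numpy()},
        }
    try:
        res = model.fit(disp=False, maxiter=200, **kwargs)
    except Exception as exc:  # statsmodels raises several error types here
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        # name the covariate most associated with separation
        sep = max(
            COVARIATE_COLUMNS,
            key=lambda c: abs(res.params.get(c, 0.0)),
        )
        raise ValueError(
            f"logistic fit did not converge (possible separation on {sep!r})"
        )
    return FactorModel(
        terms=tuple(res.params.index),
        coef=res.params.to_numpy(),
        se=res.bse.to_numpy(),
        n_obs=int(res.nobs),
    )


def category_frequency_by_location(
    frame: pd.DataFrame, max_eccentricity: float = 10.0
) -> pd.DataFrame:
    """Fraction of category-2 patches among {2,3} per (eccentricity, group).

    Category-1 patches and loci beyond ``max_eccentricity`` degrees are
    excluded. Cells with no eligible patches are absent from the output.
    """
    eligible = frame[
        frame["category"].isin([2, 3])
        & (frame["eccentricity"] <= max_eccentricity)
    ]
    out = (
        eligible.assign(poor=lambda d: (d["category"] == 2).astype(float))
        .groupby(["eccentricity", "group"], as_index=False)
        .agg(n=("poor", "size"), fraction_poor=("poor", "mean"))
    )
    return out


def subject_fraction_poor(frame: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-subject fraction of category 2 among {2,3}, plus the cohort share
    of subjects with fraction >= 0.5 ("half or more images poor").

    Subjects with no category-2/3 patches are excluded with a warning.
    """
    eligible = frame[frame["category"].isin([2, 3])]
    excluded = set(frame["subject_id"]) - set(eligible["subject_id"])
    if excluded:
        log.warning(
            "excluded %d subjects with no category-2/3 patches", len(excluded)
        )
    per_subject = (
        eligible.assign(poor=lambda d: (d["category"] == 2).astype(float))
        .groupby("subject_id", as_index=False)
        .agg(n=("poor", "size"), fraction_poor=("poor", "mean"))
    )
    share = float((per_subject["fraction_poor"] >= 0.5).mean())
    return per_subject, share
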