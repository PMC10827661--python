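"""Clinical correlates of a methylation profile score.

Links a per-sample MPS to symptom severity (Pearson correlation among cases)
and to treatment response.  The response model regresses the pre-to-post
severity change (negative = improvement) on the baseline severity score and
its interaction with the MPS, adjusting for age, sex and medication;
predictors are standardized before the interaction is formed to limit
collinearity.  A median split on the MPS fits the per-group model
``delta ~ baseline + mps + age + sex + medication`` separately for low and
high scorers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TreatmentRecord",
    "RegressionSummary",
    "severity_correlation",
    "treatment_response_model",
    "median_split_analysis",
    "records_from_phenotypes",
]


@dataclass(frozen=True)
class TreatmentRecord:
    """One treated case with pre/post severity and an MPS value."""

    sample_id: str
    ybocs_baseline: float
    ybocs_post: float
    mps: float
    age: float
    sex: str
    medication: str

    def __post_init__(self) -> None:
        if self.ybocs_baseline < 0 or self.ybocs_post < 0:
            raise ValueError("severity scores must be non-negative")

    @property
    def delta(self) -> float:
        """Pre-to-post change; negative means improvement."""
        return self.ybocs_post - self.ybocs_baseline


@dataclass(frozen=True)
class RegressionSummary:
    terms: tuple
    coefficients: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        for name in ("coefficients", "t_statistics", "p_values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.terms) == self.coefficients.size == self.t_statistics.size == self.p_values.size):
            raise ValueError("summary arrays not aligned to terms")
        if self.n <= len(self.terms):
            raise ValueError("n must exceed the number of terms")

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def p(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": self.coefficients,
                "t": self.t_statistics,
                "p": self.p_values,
            }
        )


class ZeroVarianceError(ValueError):
    pass


def severity_correlation(
    mps_scores: np.ndarray, severity: np.ndarray, case_mask: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Pearson correlation of MPS with symptom severity among cases.

    Controls (and samples with missing severity) are excluded.  Returns
    (r, p, n).  Symmetric in its two score arguments.
    """
    mps_scores = np.asarray(mps_scores, dtype=float)
    severity = np.asarray(severity, dtype=float)
    if case_mask is not None:
        mps_scores = mps_scores[case_mask]
        severity = severity[case_mask]
    ok = ~np.isnan(mps_scores) & ~np.isnan(severity)
    x, y = mps_scores[ok], severity[ok]
    if x.size < 3:
        raise ValueError("need at least 3 non-missing case pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ZeroVarianceError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        raise ZeroVarianceError(f"predictor {name!r} is constant")
    return (x - x.mean()) / sd


def _frame_from_records(records: Sequence[TreatmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "delta": [r.delta for r in records],
            "baseline": [r.ybocs_baseline for r in records],
            "mps": [r.mps for r in records],
            "age": [r.age for r in records],
            "sex": [1.0 if r.sex == "male" else 0.0 for r in records],
            "medication": [1.0 if r.medication == "yes" else 0.0 for r in records],
        }
    )


def _fit_ols(y: np.ndarray, X: pd.DataFrame) -> RegressionSummary:
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = np.corrcoef(design.to_numpy().T)
        guilty = [
            c
            for i, c in enumerate(design.columns)
            if i > 0 and np.any(np.abs(corr[i, :i]) > 1 - 1e-10)
        ]
        raise ZeroVarianceError(f"collinear model terms: {guilty or list(design.columns)}")
    fit = sm.OLS(y, design).fit()
    return RegressionSummary(
        terms=tuple(design.columns),
        coefficients=fit.params.to_numpy(),
        t_statistics=fit.tvalues.to_numpy(),
        p_values=fit.pvalues.to_numpy(),
        n=int(len(y)),
    )


def treatment_response_model(
    records: Sequence[TreatmentRecord], include_mps_main: bool = True
) -> RegressionSummary:
    """OLS of pre-to-post severity change on baseline, baseline x MPS, and covariates.

    Baseline and MPS are standardized before the interaction is formed.  By
    default the MPS main effect is included alongside the interaction
    (hierarchical principle); ``include_mps_main=False`` fits the reduced
    model with baseline and the interaction only.
    """
    if len(records) <= 6:
        raise ValueError("need more than 6 complete records")
    frame = _frame_from_records(list(records))
    baseline = _standardize(frame["baseline"].to_numpy(), "baseline")
    mps = _standardize(frame["mps"].to_numpy(), "mps")
    X = pd.DataFrame({"baseline": baseline})
    if include_mps_main:
        X["mps"] = mps
    X["baseline_x_mps"] = baseline * mps
    X["age"] = _standardize(frame["age"].to_numpy(), "age")
    X["sex"] = frame["sex"].to_numpy()
    X["medication"] = frame["medication"].to_numpy()
    return _fit_ols(frame["delta"].to_numpy(), X)


def median_split_analysis(
    records: Sequence[TreatmentRecord], min_group_size: int = 8
) -> tuple[RegressionSummary, RegressionSummary, float, tuple]:
    """Fit the per-group response model below and above the median MPS.

    Ties at the median go to the low group.  Each group gets
    ``delta ~ baseline + mps + age + sex + medication`` (standardized
    continuous predictors).  Returns (summary_low, summary_high, split value,
    (n_low, n_high)).
    """
    records = list(records)
    mps = np.array([r.mps for r in records], dtype=float)
    if np.unique(mps).size == 1:
        raise ValueError("all MPS values equal; no median split possible")
    split = float(np.median(mps))
    low = [r for r in records if r.mps <= split]
    high = [r for r in records if r.mps > split]
    if len(low) < min_group_size or len(high) < min_group_size:
        raise ValueError(
            f"median split groups too small: n_low={len(low)}, n_high={len(high)}"
        )

    def fit(group: list) -> RegressionSummary:
        frame = _frame_from_records(group)
        X = pd.DataFrame(
            {
                "baseline": _standardize(frame["baseline"].to_numpy(), "baseline"),
                "mps": _standardize(frame["mps"].to_numpy(), "mps"),
                "age": _standardize(frame["age"].to_numpy(), "age"),
                "sex": frame["sex"].to_numpy(),
                "medication": frame["medication"].to_numpy(),
            }
        )
        return _fit_ols(frame["delta"].to_numpy(), X)

    return fit(low), fit(high), split, (len(low), len(high))


def records_from_phenotypes(
    phenotypes: pd.DataFrame, mps_scores: dict
) -> list:
    """Treatment records for cases with pre+post severity, an MPS and complete covariates."""
    records = []
    for _, row in phenotypes.iterrows():
        if row["status"] != "case":
            continue
        if pd.isna(row["severity"]) or pd.isna(row["severity_post"]):
            continue
        if row["sample_id"] not in mps_scores or pd.isna(row["medication"]):
            continue
        records.append(
            TreatmentRecord(
                sample_id=row["sample_id"],
                ybocs_baseline=float(row["severity"]),
                ybocs_post=float(row["severity_post"]),
                mps=float(mps_scores[row["sample_id"]]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                medication=str(row["medication"]),
            )
        )
    return records
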