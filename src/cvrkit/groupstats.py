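"""Group-level regression models linking transition rate to the next CVR response.

Two linear models are fitted per ROI on subject-level records:

* **Model 1**: ``CVR-2 ~ transition_rate_1 + age + sex + group + design`` —
  does the hyper-to-normocapnia washout rate predict the response to the
  following hypercapnia challenge, adjusting for demographics and paradigm?
* **Model 2**: adds CVR-1 as an explanatory variable and replaces the
  transition rate with its component orthogonal to CVR-1, so the rate's
  contribution is the variance it explains beyond the shared
  challenge-to-challenge similarity.

Continuous variables (outcome included) are z-scored, so the reported
parameter estimates are standardized; sex / group / design enter as 0/1
indicators.  Significance uses a Bonferroni-corrected threshold
(``alpha / m``; 0.05 / 4 ROIs = 0.0125 by default, significant at ``p <=``
threshold).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "standardize",
    "orthogonalize",
    "RegressionResult",
    "fit_model1",
    "fit_model2",
    "bonferroni_flag",
    "correlation_matrix",
]

_BINARY_CODES = {
    "sex": {"F": 0.0, "M": 1.0},
    "group": {"cognitive": 0.0, "sleep_apnea": 1.0},
    "design": {"A": 0.0, "B": 1.0},
}


def standardize(column) -> np.ndarray:
    """Z-score: zero mean, unit sample standard deviation (ddof = 1)."""
    x = np.asarray(column, dtype=float)
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def orthogonalize(a, b) -> np.ndarray:
    """Residual of OLS of ``a`` on ``[1, b]``; uncorrelated with ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(b) == 0:
        raise ValueError("cannot orthogonalize against a constant column")
    X = np.column_stack([np.ones_like(b), b])
    beta, *_ = np.linalg.lstsq(X, a, rcond=None)
    return a - X @ beta


@dataclass(frozen=True)
class RegressionResult:
    """Standardized PEs, p-values and adjusted R² of one fitted model."""

    model_id: str                       # "model1" or "model2"
    roi: str
    params: Dict[str, float]            # term -> standardized PE
    pvalues: Dict[str, float]
    adj_r_squared: float
    r_squared: float
    n_used: int
    n_dropped: int

    def term(self, name: str) -> Tuple[float, float]:
        """(standardized PE, p-value) of a term."""
        return self.params[name], self.pvalues[name]


def _prepare(records: pd.DataFrame, roi: str, needed: Sequence[str]):
    df = records
    if "roi" in df.columns:
        df = df[df["roi"] == roi]
    if df.empty:
        raise ValueError(f"no records for roi {roi!r}")
    df = df.copy()
    for col, codes in _BINARY_CODES.items():
        if df[col].dtype == object:
            unknown = set(df[col]) - set(codes)
            if unknown:
                raise ValueError(f"unknown {col} levels: {sorted(unknown)}")
            df[col] = df[col].map(codes)
    n_before = len(df)
    df = df.dropna(subset=list(needed))
    n_dropped = n_before - len(df)
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete records, got {len(df)}")
    return df, n_dropped


def _fit(y: np.ndarray, X: pd.DataFrame, model_id: str, roi: str,
         n_dropped: int) -> RegressionResult:
    mat = X.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(X)), mat])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient design; collinear terms among: " + ", ".join(X.columns)
        )
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    params = {t: float(fit.params[t]) for t in X.columns}
    pvalues = {t: float(fit.pvalues[t]) for t in X.columns}
    return RegressionResult(
        model_id=model_id,
        roi=roi,
        params=params,
        pvalues=pvalues,
        adj_r_squared=float(fit.rsquared_adj),
        r_squared=float(fit.rsquared),
        n_used=int(fit.nobs),
        n_dropped=n_dropped,
    )


def fit_model1(
    records: pd.DataFrame,
    roi: str = "global",
    transition_col: str = "transition_rate_1",
    outcome_col: str = "cvr2",
) -> RegressionResult:
    """CVR-2 on the preceding transition rate plus covariates.

    Records with missing modeled values are dropped listwise
    (``n_dropped`` reports the count).
    """
    needed = [outcome_col, transition_col, "age", "sex", "group", "design"]
    df, n_dropped = _prepare(records, roi, needed)
    y = standardize(df[outcome_col])
    X = pd.DataFrame(
        {
            "transition_rate": standardize(df[transition_col]),
            "age": standardize(df["age"]),
            "sex": df["sex"].to_numpy(float),
            "group": df["group"].to_numpy(float),
            "design": df["design"].to_numpy(float),
        },
        index=df.index,
    )
    return _fit(y, X, "model1", roi, n_dropped)


def fit_model2(
    records: pd.DataFrame,
    roi: str = "global",
    transition_col: str = "transition_rate_1",
    outcome_col: str = "cvr2",
    cvr1_col: str = "cvr1",
    orthogonalize_against: str = "cvr1",
) -> RegressionResult:
    """CVR-2 on CVR-1 plus the orthogonalized transition rate and covariates.

    The transition rate is residualized against CVR-1 by default (the
    co-regressor), removing the variance shared between successive
    challenges before asking whether the washout rate still explains CVR-2.
    ``orthogonalize_against="cvr2"`` residualizes against the outcome
    instead; this trivially distorts inference and exists only for
    sensitivity checks.
    """
    needed = [outcome_col, transition_col, cvr1_col, "age", "sex", "group", "design"]
    df, n_dropped = _prepare(records, roi, needed)
    if orthogonalize_against == "cvr1":
        target = df[cvr1_col]
    elif orthogonalize_against == "cvr2":
        target = df[outcome_col]
    else:
        raise ValueError("orthogonalize_against must be 'cvr1' or 'cvr2'")
    orth = orthogonalize(df[transition_col], target)
    if orth.std(ddof=1) < 1e-10 * np.asarray(df[transition_col], float).std(ddof=1):
        raise ValueError(
            "transition rate has no unique variance beyond the "
            "orthogonalization target"
        )
    y = standardize(df[outcome_col])
    X = pd.DataFrame(
        {
            "cvr1": standardize(df[cvr1_col]),
            "transition_rate_orth": standardize(orth),
            "age": standardize(df["age"]),
            "sex": df["sex"].to_numpy(float),
            "group": df["group"].to_numpy(float),
            "design": df["design"].to_numpy(float),
        },
        index=df.index,
    )
    return _fit(y, X, "model2", roi, n_dropped)


def bonferroni_flag(p_values, alpha: float = 0.05, m: int = 4) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected threshold ``alpha / m``.

    Defaults give the 4-ROI threshold 0.0125; a p-value exactly at the
    threshold counts as significant (``p <= alpha/m``).
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1) or m < 1:
        raise ValueError("need 0 < alpha < 1 and m >= 1")
    return p <= alpha / m


def correlation_matrix(
    records: pd.DataFrame,
    roi: Optional[str] = None,
    columns: Sequence[str] = ("transition_rate_1", "cvr1", "cvr2", "cope_cvr"),
) -> pd.DataFrame:
    """Pairwise Pearson r among temporal CVR metrics (listwise per pair).

    Entries for constant columns are NaN (undefined correlation); the
    diagonal is 1.  Square the result elementwise for the R² view.
    """
    df = records
    if roi is not None and "roi" in df.columns:
        df = df[df["roi"] == roi]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = df[list(columns)].astype(float)
    if len(sub.dropna()) < 3:
        raise ValueError("need at least 3 complete records per pair")
    corr = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr
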