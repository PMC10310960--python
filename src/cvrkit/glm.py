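"""Conventional HRF-convolved GLM comparator and AIC model comparison.

The conventional CVR estimate regresses the BOLD series on a boxcar of the
breathing paradigm convolved with a single-gamma hemodynamic response
function; the fitted regressor coefficient is the COPE (contrast of parameter
estimates).  To compare the parametric fit with the non-parametric Sen line
on equal footing, both are scored with the Gaussian pseudo-likelihood AIC

    AIC = n * ln(RSS / n) + 2k

with the additive constant dropped consistently, so AIC *differences* are
convention-free.  Both fits estimate two parameters (slope/coefficient and
intercept), k = 2.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .metrics import sen_intercept, sens_slope, tsnr
from .paradigm import CO2, BlockParadigm, build_boxcar
from .series import SampledSeries

__all__ = [
    "HrfKernel",
    "gamma_hrf",
    "convolve_regressor",
    "GlmResult",
    "glm_cope",
    "aic_ols",
    "aic_sen",
    "ModelFitComparison",
    "compare_models",
]


@dataclass(frozen=True)
class HrfKernel:
    """Discrete unit-sum HRF weights sampled at the BOLD TR."""

    samples: np.ndarray
    mean_lag_s: float
    sd_s: float
    tr: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, float)
        if (s < 0).any() or abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("HRF weights must be non-negative and sum to 1")


def gamma_hrf(
    tr: float,
    mean_lag_s: float = 6.0,
    sd_s: float = 3.0,
    length_s: float = 30.0,
) -> HrfKernel:
    """Single-gamma HRF by moment matching.

    The gamma density with mean ``mean_lag_s`` and standard deviation
    ``sd_s`` has shape ``k = mean² / sd²`` and scale ``θ = sd² / mean``
    (defaults: k = 4, θ = 1.5 s, mode at 4.5 s).  It is sampled at the TR,
    truncated at ``length_s`` and renormalized to unit sum.
    """
    if not (tr > 0 and mean_lag_s > 0 and sd_s > 0 and length_s > 0):
        raise ValueError("tr, mean_lag_s, sd_s and length_s must all be positive")
    shape = (mean_lag_s / sd_s) ** 2
    scale = sd_s**2 / mean_lag_s
    t = np.arange(0.0, length_s, tr)
    weights = stats.gamma.pdf(t, a=shape, scale=scale)
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate HRF: no mass within length_s")
    return HrfKernel(samples=weights / total, mean_lag_s=mean_lag_s, sd_s=sd_s, tr=tr)


def convolve_regressor(boxcar: SampledSeries, hrf: HrfKernel) -> SampledSeries:
    """Causal convolution of the paradigm boxcar with the HRF kernel."""
    values = np.convolve(boxcar.values, hrf.samples)[: len(boxcar)]
    return SampledSeries(values, tr=boxcar.tr, t0=boxcar.t0)


@dataclass(frozen=True)
class GlmResult:
    """OLS fit of a BOLD series on [intercept, HRF-convolved regressor]."""

    cope: float              # a.u. per unit regressor
    intercept: float         # a.u.
    residuals: np.ndarray
    pct_equivalent: Optional[float] = None  # % per mmHg, when normalizers given


def glm_cope(
    series: SampledSeries,
    regressor: SampledSeries,
    hrf: Optional[HrfKernel] = None,
    delta_petco2: Optional[float] = None,
    baseline_mean: Optional[float] = None,
) -> GlmResult:
    """COPE of an OLS fit of ``series`` on the (optionally HRF-convolved) regressor.

    If ``hrf`` is given the regressor is convolved first.  When both
    ``delta_petco2`` and ``baseline_mean`` are supplied, ``pct_equivalent``
    expresses the COPE of a unit boxcar as % BOLD per mmHg; the normalization
    of a COPE-based CVR is otherwise left to the caller.
    """
    if hrf is not None:
        regressor = convolve_regressor(regressor, hrf)
    if len(series) != len(regressor):
        raise ValueError(
            f"series ({len(series)}) and regressor ({len(regressor)}) lengths differ"
        )
    x = regressor.values
    y = series.values
    if np.ptp(x) == 0:
        raise ValueError("constant regressor; COPE undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ beta
    pct_equiv = None
    if delta_petco2 is not None and baseline_mean is not None:
        if not (delta_petco2 > 0 and baseline_mean > 0):
            raise ValueError("delta_petco2 and baseline_mean must be positive")
        pct_equiv = beta[1] / baseline_mean * 100.0 / delta_petco2
    return GlmResult(
        cope=float(beta[1]),
        intercept=float(beta[0]),
        residuals=residuals,
        pct_equivalent=pct_equiv,
    )


def aic_ols(residuals: np.ndarray, k_params: int) -> float:
    """Gaussian AIC ``n * ln(RSS / n) + 2k`` with the constant term dropped."""
    residuals = np.asarray(residuals, float)
    n = residuals.size
    if n <= k_params:
        raise ValueError(f"need n > k_params, got n={n}, k={k_params}")
    rss = float(residuals @ residuals)
    if rss <= 0.0:
        raise ValueError("zero residual sum of squares; AIC degenerate")
    return n * np.log(rss / n) + 2 * k_params


def aic_sen(excerpt: SampledSeries) -> float:
    """AIC of the Sen line fit (slope + median intercept, k = 2).

    Residuals are ``y_k − (slope·k + intercept)`` on sample indices; the
    Gaussian pseudo-likelihood makes this directly comparable with
    :func:`aic_ols` of a parametric fit on the same excerpt.
    """
    y = excerpt.values
    keep = np.isfinite(y)
    y = y[keep]
    k_idx = np.nonzero(keep)[0]
    slope = sens_slope(excerpt)
    intercept = sen_intercept(excerpt, slope)
    residuals = y - (slope * k_idx + intercept)
    return aic_ols(residuals, k_params=2)


@dataclass(frozen=True)
class ModelFitComparison:
    """Parametric vs non-parametric AIC for one simulated epoch."""

    aic_parametric: float
    aic_nonparametric: float
    tsnr: float
    shape: str  # "fast" or "slow"

    @property
    def preferred(self) -> str:
        return "parametric" if self.aic_parametric < self.aic_nonparametric else "nonparametric"


def compare_models(simulated, paradigm: BlockParadigm) -> ModelFitComparison:
    """Fit both models to one simulated normocapnia→hypercapnia epoch.

    The parametric model regresses the series on the gamma-HRF-convolved
    paradigm boxcar; the non-parametric model is the Sen line.  Both AICs are
    computed on the same excerpt with k = 2.  The realized tSNR is taken from
    the pre-onset baseline segment.  A perfect (zero-residual) fit is
    reported as ``-inf``.
    """
    series = simulated.series
    boxcar = build_boxcar(paradigm, n_samples=len(series))
    hrf = gamma_hrf(paradigm.tr)
    try:
        fit = glm_cope(series, boxcar, hrf=hrf)
        aic_par = aic_ols(fit.residuals, k_params=2)
    except ValueError:
        aic_par = float("-inf")
    try:
        aic_sen_value = aic_sen(series)
    except ValueError:
        aic_sen_value = float("-inf")

    onset = min(start for start, _ in paradigm.co2_intervals())
    baseline = series.values[series.times < onset]
    return ModelFitComparison(
        aic_parametric=aic_par,
        aic_nonparametric=aic_sen_value,
        tsnr=tsnr(baseline),
        shape=getattr(simulated, "shape", "unknown"),
    )
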