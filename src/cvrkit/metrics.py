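"""Model-free temporal CVR metrics.

The core quantities of the package:

* **Sen's slope** — the Theil–Sen estimator, the median of all n(n−1)/2
  pairwise slopes of a BOLD excerpt.  Being a median it is robust to the
  occasional gross outlier (breakdown point ≈ 29%) and makes no assumption
  about the shape of the response.
* **%ΔBOLD** — the slope (per sample) times the number of data points in the
  dilation window, divided by the mean baseline signal preceding the
  challenge, times 100.  Index-based slopes times a sample count make the
  percent change unit-less: the sampling interval cancels.
* **CVR** — %ΔBOLD divided by ΔPETCO2, in % per mmHg, computed once per
  hypercapnia challenge so successive challenges can be compared.
* **Transition rate** — the ordinary least-squares rate of BOLD decline
  during the return from hypercapnia to normocapnia (a.u. per second, time in
  seconds so designs with different TR are comparable), normalized by
  ΔPETCO2.
* **tSNR** — mean baseline signal over its sample standard deviation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .capnometry import Petco2Summary
from .paradigm import AnalysisWindows
from .series import SampledSeries, TimeWindow, slice_window

__all__ = [
    "sens_slope",
    "sen_intercept",
    "pct_bold_change",
    "cvr",
    "CvrEstimate",
    "cvr_for_challenge",
    "TransitionFit",
    "transition_fit",
    "transition_fit_for_challenge",
    "tsnr",
]


def _finite_with_index(values: np.ndarray):
    values = np.asarray(values, dtype=float)
    idx = np.nonzero(np.isfinite(values))[0]
    return values[idx], idx


def sens_slope(excerpt: Union[SampledSeries, np.ndarray]) -> float:
    """Median of all pairwise slopes ``(x_j - x_i) / (j - i)``, j > i.

    Indices are sample positions, so the slope is in signal units per sample.
    NaN samples are dropped (their original indices are kept for the index
    differences).  The median of an even pair count is the mean of the two
    central order statistics.
    """
    values = excerpt.values if isinstance(excerpt, SampledSeries) else np.asarray(excerpt, float)
    x, idx = _finite_with_index(values)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 finite samples for Sen's slope, got {n}")
    i, j = np.triu_indices(n, k=1)
    slopes = (x[j] - x[i]) / (idx[j] - idx[i])
    return float(np.median(slopes))


def sen_intercept(excerpt: Union[SampledSeries, np.ndarray], slope: float = None) -> float:
    """Companion intercept ``median(x_k - slope * k)`` for the Sen line."""
    values = excerpt.values if isinstance(excerpt, SampledSeries) else np.asarray(excerpt, float)
    x, idx = _finite_with_index(values)
    if slope is None:
        slope = sens_slope(values)
    return float(np.median(x - slope * idx))


def pct_bold_change(sens_slope: float, n_points: int, baseline_mean: float) -> float:
    """Unit-less BOLD percent signal change of one dilation window.

    ``sens_slope * n_points / baseline_mean * 100``: the per-sample median
    rate scaled to the whole window and normalized to the pre-challenge
    baseline level.
    """
    if n_points < 3:
        raise ValueError(f"n_points must be >= 3, got {n_points}")
    if not baseline_mean > 0:
        raise ValueError(f"baseline_mean must be positive, got {baseline_mean}")
    return sens_slope * n_points / baseline_mean * 100.0


def cvr(pct_bold: float, delta_petco2: float) -> float:
    """CVR in % BOLD per mmHg: percent signal change over the PETCO2 step."""
    if not delta_petco2 > 0:
        raise ValueError(f"delta_petco2 must be positive, got {delta_petco2}")
    return pct_bold / delta_petco2


@dataclass(frozen=True)
class CvrEstimate:
    """Non-parametric CVR of a single hypercapnia challenge."""

    sens_slope: float      # a.u. per sample
    n_points: int          # finite samples in the dilation window
    baseline_mean: float   # a.u.
    pct_bold: float        # %
    delta_petco2: float    # mmHg
    cvr: float             # % per mmHg
    window: TimeWindow
    challenge_index: int


def cvr_for_challenge(
    series: SampledSeries,
    windows: AnalysisWindows,
    challenge_index: int,
    petco2: Union[Petco2Summary, float],
) -> CvrEstimate:
    """Full per-challenge pipeline: window → Sen's slope → normalization.

    ``petco2`` is either a :class:`~cvrkit.capnometry.Petco2Summary` or a
    scalar ΔPETCO2 in mmHg (for targeted-step experiments that report the
    achieved change directly).
    """
    delta = petco2.delta if isinstance(petco2, Petco2Summary) else float(petco2)
    window = windows.cvr(challenge_index)
    excerpt = slice_window(series, window)
    baseline = slice_window(series, windows.baseline(challenge_index))
    baseline_mean = float(np.nanmean(baseline.values))
    slope = sens_slope(excerpt)
    n_points = int(np.isfinite(excerpt.values).sum())
    pct = pct_bold_change(slope, n_points, baseline_mean)
    return CvrEstimate(
        sens_slope=slope,
        n_points=n_points,
        baseline_mean=baseline_mean,
        pct_bold=pct,
        delta_petco2=delta,
        cvr=cvr(pct, delta),
        window=window,
        challenge_index=challenge_index,
    )


@dataclass(frozen=True)
class TransitionFit:
    """Linear read-out of one hyper-to-normocapnia transition period."""

    tau: float              # a.u. per s (OLS slope of signal on time)
    intercept: float        # a.u.
    transition_rate: float  # a.u. per s per mmHg
    r_squared: float
    window: TimeWindow


def transition_fit(
    excerpt: SampledSeries,
    delta_petco2: float,
    window: TimeWindow = None,
) -> TransitionFit:
    """OLS of BOLD signal on time (s) over a transition excerpt.

    Time is absolute post-discard seconds, so ``tau`` is per second and the
    PETCO2-normalized ``transition_rate = tau / delta_petco2`` is comparable
    across designs with different TR.
    """
    if not delta_petco2 > 0:
        raise ValueError(f"delta_petco2 must be positive, got {delta_petco2}")
    t_all = excerpt.times
    y_all = excerpt.values
    keep = np.isfinite(y_all)
    t, y = t_all[keep], y_all[keep]
    if t.size < 3:
        raise ValueError(f"need at least 3 finite samples, got {t.size}")
    t_c = t - t.mean()
    sxx = float(t_c @ t_c)
    if sxx == 0.0:
        raise ValueError("degenerate time axis (zero variance)")
    tau = float(t_c @ (y - y.mean())) / sxx
    intercept = float(y.mean() - tau * t.mean())
    resid = y - (tau * t + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    if window is None:
        window = TimeWindow(float(t_all[0]), float(t_all[-1]) + excerpt.tr)
    return TransitionFit(
        tau=tau,
        intercept=intercept,
        transition_rate=tau / delta_petco2,
        r_squared=r2,
        window=window,
    )


def transition_fit_for_challenge(
    series: SampledSeries,
    windows: AnalysisWindows,
    challenge_index: int,
    delta_petco2: float,
) -> TransitionFit:
    """Slice the design's transition window and fit the linear decline."""
    window = windows.transition(challenge_index)
    return transition_fit(slice_window(series, window), delta_petco2, window=window)


def tsnr(baseline_excerpt: Union[SampledSeries, np.ndarray]) -> float:
    """Temporal SNR: mean over sample standard deviation (ddof = 1)."""
    values = (
        baseline_excerpt.values
        if isinstance(baseline_excerpt, SampledSeries)
        else np.asarray(baseline_excerpt, float)
    )
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite samples for tSNR")
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero temporal standard deviation; tSNR undefined")
    return float(values.mean()) / sd
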