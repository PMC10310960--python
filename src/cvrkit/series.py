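"""Uniformly sampled signals and time-window slicing.

:class:`SampledSeries` is the single carrier used throughout the package for
BOLD ROI-mean time courses (arbitrary scanner units), respiratory CO2 traces
(mmHg) and regressors.  A series is a value array plus a sampling interval
``tr`` (s) and the time ``t0`` (s) of its first sample; sample *k* sits at
``t0 + k * tr``.

Analytical time windows are closed-open intervals ``[start_s, end_s)`` on the
same axis, so adjacent windows never double-count a boundary sample.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeWindow", "SampledSeries", "slice_window"]


@dataclass(frozen=True)
class TimeWindow:
    """Closed-open interval ``[start_s, end_s)`` on the post-discard time axis."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"window start must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"window end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    def second_half(self) -> "TimeWindow":
        """The later half of the window (used for PETCO2 plateau means)."""
        return TimeWindow(self.midpoint_s, self.end_s)


@dataclass
class SampledSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Sample values; NaN marks explicitly flagged missing samples.
    tr : float
        Sampling interval in seconds (> 0).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    tr: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not self.tr > 0:
            raise ValueError(f"sampling interval must be positive, got {self.tr}")
        if np.isinf(self.values).any():
            raise ValueError("values must be finite (NaN allowed for flagged gaps)")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + k * tr`` in seconds."""
        return self.t0 + np.arange(self.values.size) * self.tr

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, ``n * tr``."""
        return self.values.size * self.tr

    @property
    def end_s(self) -> float:
        """Time just past the last sample (open end of the covered span)."""
        return self.t0 + self.duration_s

    def copy(self) -> "SampledSeries":
        return SampledSeries(self.values.copy(), self.tr, self.t0)


def slice_window(series: SampledSeries, window: TimeWindow) -> SampledSeries:
    """Return the samples of ``series`` with ``start_s <= t < end_s``.

    The sampling interval is preserved and ``t0`` of the result is the time of
    the first retained sample.  A window that only partially overlaps the
    series' span is truncated with a warning; an empty overlap is an error.
    """
    t = series.times
    keep = (t >= window.start_s) & (t < window.end_s)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError(
            f"window [{window.start_s}, {window.end_s}) s does not overlap the "
            f"series span [{series.t0}, {series.end_s}) s"
        )
    if window.start_s < series.t0 or window.end_s > series.end_s:
        warnings.warn(
            f"window [{window.start_s}, {window.end_s}) s truncated to series "
            f"span [{series.t0}, {series.end_s}) s ({n_kept} samples retained)",
            stacklevel=2,
        )
    idx = np.nonzero(keep)[0]
    return SampledSeries(series.values[idx], series.tr, t0=float(t[idx[0]]))
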