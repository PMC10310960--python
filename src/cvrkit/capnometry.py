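"""End-tidal CO2 (PETCO2) extraction and the hypercapnic step normalizer.

The CVR metric divides the BOLD percent signal change by the change in
end-tidal CO2 between normocapnia and the hypercapnic plateau.  A raw
capnometer trace oscillates with every breath; the end-tidal value is the
breath-wise expiration peak, so PETCO2 is recovered as the peak envelope of
the trace held constant between breaths (PETCO2 is a per-breath quantity, so
no interpolation across breaths is performed).

When no trace was recorded (e.g. a computer-controlled gas targeting rig
reports the achieved step directly), a scalar ΔPETCO2 may be supplied to the
metrics layer instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .paradigm import AnalysisWindows
from .series import SampledSeries, slice_window

__all__ = ["Petco2Summary", "extract_petco2", "petco2_delta"]

#: minimum capnometer sampling rate (Hz) for reliable peak picking
MIN_SAMPLING_HZ = 4.0


@dataclass(frozen=True)
class Petco2Summary:
    """Baseline and plateau PETCO2 means (mmHg) and their difference."""

    baseline_mean: float
    plateau_mean: float

    @property
    def delta(self) -> float:
        """ΔPETCO2 = plateau − baseline, mmHg."""
        return self.plateau_mean - self.baseline_mean

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(
                f"non-hypercapnic PETCO2 change: plateau {self.plateau_mean} "
                f"mmHg <= baseline {self.baseline_mean} mmHg"
            )


def extract_petco2(
    co2_trace: SampledSeries,
    min_breath_period_s: float = 2.0,
    out_tr: Optional[float] = None,
    out_n: Optional[int] = None,
    min_prominence_mmHg: float = 0.5,
) -> SampledSeries:
    """Peak envelope of a raw CO2 trace, resampled by previous-peak hold.

    Local maxima separated by at least ``min_breath_period_s`` and rising at
    least ``min_prominence_mmHg`` above their surroundings (rejects sensor
    noise; a real expiration swings several mmHg) are detected; the envelope
    holds each peak value until the next breath.  ``out_tr`` / ``out_n``
    resample the envelope onto the BOLD grid (defaults: the trace's own
    grid).  Samples before the first detected breath carry the first peak's
    value.
    """
    if min_breath_period_s < 1.0:
        raise ValueError("min_breath_period_s must be >= 1 s")
    fs = 1.0 / co2_trace.tr
    if fs < MIN_SAMPLING_HZ:
        raise ValueError(
            f"CO2 trace sampled at {fs:.2f} Hz; >= {MIN_SAMPLING_HZ} Hz required"
        )
    distance = max(1, int(round(min_breath_period_s / co2_trace.tr)))
    peaks, _ = find_peaks(
        co2_trace.values, distance=distance,
        prominence=min_prominence_mmHg if min_prominence_mmHg > 0 else None,
    )
    if peaks.size == 0:
        raise ValueError("no expiration peaks found in CO2 trace")

    peak_t = co2_trace.times[peaks]
    peak_v = co2_trace.values[peaks]
    tr = float(out_tr) if out_tr is not None else co2_trace.tr
    n = int(out_n) if out_n is not None else len(co2_trace)
    t_out = co2_trace.t0 + np.arange(n) * tr if out_tr is None and out_n is None \
        else np.arange(n) * tr
    # previous-peak hold; backfill before the first breath
    idx = np.clip(np.searchsorted(peak_t, t_out, side="right") - 1, 0, peak_v.size - 1)
    return SampledSeries(peak_v[idx], tr=tr, t0=float(t_out[0]))


def petco2_delta(
    petco2: SampledSeries,
    windows: AnalysisWindows,
    challenge_index: int,
) -> Petco2Summary:
    """ΔPETCO2 for one challenge from an end-tidal series on the BOLD axis.

    ``baseline_mean`` averages the challenge's baseline window; the plateau
    averages the **second half** of the dilation window, excluding the
    dilatory ramp so the value reflects the steady hypercapnic level.
    """
    baseline = slice_window(petco2, windows.baseline(challenge_index))
    plateau = slice_window(petco2, windows.cvr(challenge_index).second_half())
    return Petco2Summary(
        baseline_mean=float(np.nanmean(baseline.values)),
        plateau_mean=float(np.nanmean(plateau.values)),
    )
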