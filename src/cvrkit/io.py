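"""Reading BOLD / tabular signals and minimal in-scope preprocessing.

Scope is deliberately narrow: ROI-mean extraction from a preprocessed 4-D
NIfTI plus a binary mask on the same grid, discarding of initial equilibrium
volumes, an optional mean-preserving high-pass detrend, and delimited-text
series I/O.  Motion correction, smoothing, slice timing and registration are
assumed to have happened upstream; grids must already match.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .series import SampledSeries

__all__ = [
    "read_bold_roi_series",
    "discard_initial_volumes",
    "highpass_detrend",
    "read_series_csv",
    "write_series_csv",
]

#: masks resampled from anatomical space carry fractional values; voxels
#: above this threshold count as in-ROI
MASK_THRESHOLD = 0.5
#: a series where more than this fraction of volumes contain NaN voxels errors
MAX_NAN_VOLUME_FRACTION = 0.10


def read_bold_roi_series(
    bold_4d: Union[str, Path],
    mask: Union[str, Path],
    tr_override: Optional[float] = None,
) -> SampledSeries:
    """Unweighted ROI-mean time series of a 4-D BOLD image under a mask.

    The mask is binarized at > 0.5 (down-sampled anatomical masks are
    fractional).  NaN voxels are excluded per volume; if more than 10% of
    volumes contain NaNs inside the mask the extraction errors.  The sampling
    interval comes from the NIfTI header unless ``tr_override`` is given.
    """
    bold_img = nib.load(str(bold_4d))
    mask_img = nib.load(str(mask))
    data = np.asanyarray(bold_img.dataobj, dtype=float)
    mask_data = np.asanyarray(mask_img.dataobj, dtype=float)
    while mask_data.ndim > 3 and mask_data.shape[-1] == 1:
        mask_data = mask_data[..., 0]  # drop trailing singleton dims only
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D BOLD image, got shape {data.shape}")
    if mask_data.shape != data.shape[:3]:
        raise ValueError(
            f"grid mismatch: BOLD spatial shape {data.shape[:3]} vs mask shape "
            f"{mask_data.shape}"
        )
    keep = mask_data > MASK_THRESHOLD
    if not keep.any():
        raise ValueError("mask is empty after binarization at > 0.5")

    voxels = data[keep]  # (n_voxels, n_volumes)
    nan_volumes = np.isnan(voxels).any(axis=0)
    if nan_volumes.mean() > MAX_NAN_VOLUME_FRACTION:
        raise ValueError(
            f"{nan_volumes.sum()} of {voxels.shape[1]} volumes contain NaN "
            f"voxels (> {MAX_NAN_VOLUME_FRACTION:.0%} allowed)"
        )
    values = np.nanmean(voxels, axis=0)

    if tr_override is not None:
        tr = float(tr_override)
    else:
        zooms = bold_img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValueError(
                "TR missing or zero in the NIfTI header; pass tr_override"
            )
    return SampledSeries(values, tr=tr, t0=0.0)


def discard_initial_volumes(series: SampledSeries, n_discard: int) -> SampledSeries:
    """Drop the first ``n_discard`` samples (signal-equilibrium volumes).

    The result starts at t = 0: all analytical time windows are defined on
    this post-discard axis.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= len(series):
        raise ValueError(
            f"cannot discard {n_discard} of {len(series)} volumes"
        )
    return SampledSeries(series.values[n_discard:].copy(), series.tr, t0=0.0)


def highpass_detrend(series: SampledSeries, cutoff_hz: float) -> SampledSeries:
    """Remove slow drift via Gaussian-weighted running-line subtraction.

    At every time point a straight line is fitted to the series with Gaussian
    weights of standard deviation ``1 / (2 * cutoff_hz)`` seconds (half the
    cutoff period) and the local fitted value is subtracted.  The series mean
    is added back so that baseline normalization downstream stays meaningful.
    A pure linear drift is removed essentially completely; oscillations much
    faster than the cutoff pass through.
    """
    nyquist = 0.5 / series.tr
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff must be in (0, Nyquist={nyquist:.4g}) Hz, got {cutoff_hz}"
        )
    y = series.values
    if np.isnan(y).any():
        raise ValueError("detrending requires a NaN-free series")
    t = series.times
    sigma_s = 0.5 / cutoff_hz
    # pairwise Gaussian weights (n x n); scans are a few hundred volumes
    w = np.exp(-0.5 * ((t[None, :] - t[:, None]) / sigma_s) ** 2)
    s0 = w.sum(axis=1)
    s1 = w @ t
    s2 = w @ (t * t)
    sy = w @ y
    sty = w @ (t * y)
    denom = s0 * s2 - s1 * s1
    slope = (s0 * sty - s1 * sy) / denom
    intercept = (s2 * sy - s1 * sty) / denom
    trend = slope * t + intercept
    detrended = y - trend + y.mean()
    return SampledSeries(detrended, series.tr, series.t0)


def read_series_csv(
    path: Union[str, Path],
    time_column: Optional[str] = None,
    value_column: Optional[str] = None,
    tr: Optional[float] = None,
    sep: Optional[str] = None,
) -> SampledSeries:
    """Parse a delimited text file into a :class:`SampledSeries`.

    Either a time column (seconds, uniform within 1%) is present — named via
    ``time_column`` or detected as the first column — or an explicit ``tr``
    must be supplied for a single value column.  The delimiter is sniffed
    unless ``sep`` is given.
    """
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 rows, got {df.shape[0]}")

    if time_column is None and value_column is None and df.shape[1] == 1 and tr is None:
        raise ValueError(f"{path}: single column requires an explicit tr")

    if time_column is not None or (df.shape[1] >= 2 and tr is None):
        tcol = time_column if time_column is not None else df.columns[0]
        vcol = value_column if value_column is not None else (
            [c for c in df.columns if c != tcol][0]
        )
        for col in (tcol, vcol):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        t = _numeric(df[tcol], tcol, path)
        values = _numeric(df[vcol], vcol, path)
        dt = np.diff(t)
        if (dt <= 0).any():
            raise ValueError(f"{path}: time column must be strictly increasing")
        tr_est = float(np.mean(dt))
        if np.abs(dt - tr_est).max() > 0.01 * tr_est:
            raise ValueError(
                f"{path}: time spacing non-uniform beyond 1% tolerance"
            )
        return SampledSeries(values, tr=tr_est, t0=float(t[0]))

    vcol = value_column if value_column is not None else df.columns[-1]
    if vcol not in df.columns:
        raise ValueError(f"{path}: missing column {vcol!r}")
    if tr is None:
        raise ValueError(f"{path}: tr required when no time column is present")
    return SampledSeries(_numeric(df[vcol], vcol, path), tr=float(tr), t0=0.0)


def write_series_csv(series: SampledSeries, path: Union[str, Path]) -> None:
    """Write a two-column (t_s, value) CSV."""
    pd.DataFrame({"t_s": series.times, "value": series.values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def _numeric(col: pd.Series, name: str, path) -> np.ndarray:
    out = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    if np.isnan(out).any() and not col.isna().any():
        raise ValueError(f"{path}: non-numeric entries in column {name!r}")
    return out
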