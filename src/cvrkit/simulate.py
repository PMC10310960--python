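"""Synthetic hypercapnia responses, subjects and cohorts.

Three layers of synthesis make every downstream stage testable without any
scanner data:

1. **Single epochs** — one normocapnia→hypercapnia event, either a *fast*
   sigmoidal BOLD rise or a *slow* linear ramp spanning the dilation period,
   plus white noise at a chosen temporal-SNR level.  A grid of
   shapes × noise levels × replicates drives the parametric-vs-non-parametric
   AIC comparison (default 2 × 20 × 100 = 4,000 epochs).
2. **Whole subjects** — a full two-challenge boxcar experiment (Design A or
   B): per-challenge dilation ramps with planted amplitudes, an exponential
   CO2-washout recovery between challenges with a subject-specific time
   constant, white noise, and optionally a breath-resolved PETCO2 trace.
3. **Cohorts** — collections of subjects with Table-3-like demographics and a
   planted linear dependence of the second challenge amplitude on the
   (window-linearized) washout rate, for power/type-I studies of the group
   regression models.

All generators are reproducible: identical parameters and seed give
byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .glm import ModelFitComparison, compare_models
from .paradigm import (
    CO2,
    DISCARD_VOLUMES,
    N_VOLUMES,
    ROOM_AIR,
    AnalysisWindows,
    BlockParadigm,
    design_paradigm,
    windows_for_design,
)
from .series import SampledSeries

__all__ = [
    "simulate_fast",
    "simulate_slow",
    "add_noise",
    "SimulatedResponse",
    "simulate_epoch",
    "epoch_paradigm",
    "SimulationGrid",
    "run_simulation_grid",
    "SyntheticSubject",
    "synthesize_subject",
    "synthesize_cohort",
    "cohort_manifest",
    "subject_to_csv",
]

#: sigmoid steepness factor: the logistic covers 2%→98% of its swing in one
#: rise time
_LOGISTIC_SPAN = 8.0


def _t_axis(t_axis: Union[np.ndarray, Sequence[float]]) -> Tuple[np.ndarray, float]:
    t = np.asarray(t_axis, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t_axis must be a 1-D array with at least 2 samples")
    dt = np.diff(t)
    tr = float(dt.mean())
    if not tr > 0 or np.abs(dt - tr).max() > 1e-6 * tr:
        raise ValueError("t_axis must be uniformly increasing")
    return t, tr


def simulate_fast(
    t_axis: Union[np.ndarray, Sequence[float]],
    amplitude_pct: float,
    baseline_level: float = 1000.0,
    onset_s: float = 60.0,
    rise_time_s: float = 20.0,
) -> SampledSeries:
    """Noise-free fast response: a sigmoidal BOLD rise.

    ``baseline * (1 + (a/100) * logistic((t − onset − rise/2) * 8/rise))``;
    the signal covers 2%→98% of the swing within one ``rise_time_s`` after
    onset and the midpoint of the rise sits at half amplitude.
    """
    if not baseline_level > 0:
        raise ValueError("baseline_level must be positive")
    if not rise_time_s > 0:
        raise ValueError("rise_time_s must be positive")
    t, tr = _t_axis(t_axis)
    z = (t - onset_s - rise_time_s / 2.0) * (_LOGISTIC_SPAN / rise_time_s)
    values = baseline_level * (1.0 + (amplitude_pct / 100.0) / (1.0 + np.exp(-z)))
    return SampledSeries(values, tr=tr, t0=float(t[0]))


def simulate_slow(
    t_axis: Union[np.ndarray, Sequence[float]],
    amplitude_pct: float,
    baseline_level: float = 1000.0,
    onset_s: float = 60.0,
    ramp_duration_s: float = 180.0,
) -> SampledSeries:
    """Noise-free slow response: a linear ramp from onset to plateau."""
    if not baseline_level > 0:
        raise ValueError("baseline_level must be positive")
    if not ramp_duration_s > 0:
        raise ValueError("ramp_duration_s must be positive")
    t, tr = _t_axis(t_axis)
    frac = np.clip((t - onset_s) / ramp_duration_s, 0.0, 1.0)
    values = baseline_level * (1.0 + (amplitude_pct / 100.0) * frac)
    return SampledSeries(values, tr=tr, t0=float(t[0]))


def add_noise(series: SampledSeries, noise_sd: float, seed: int) -> SampledSeries:
    """Add i.i.d. Gaussian noise; seed-reproducible, identity at sd = 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return series.copy()
    rng = np.random.default_rng(seed)
    noisy = series.values + rng.normal(0.0, noise_sd, size=len(series))
    return SampledSeries(noisy, series.tr, series.t0)


@dataclass(frozen=True)
class SimulatedResponse:
    """One simulated normocapnia→hypercapnia epoch with ground truth."""

    shape: str                  # "fast" or "slow"
    amplitude_pct: float
    baseline_level: float
    noise_sd: float
    seed: int
    series: SampledSeries
    true_slope_per_sample: float


def epoch_paradigm(
    tr: float = 1.55,
    baseline_duration_s: float = 60.0,
    dilation_duration_s: float = 180.0,
) -> BlockParadigm:
    """Single-epoch boxcar: one rest block followed by one CO2 block."""
    return BlockParadigm(
        blocks=((ROOM_AIR, baseline_duration_s), (CO2, dilation_duration_s)),
        tr=tr,
    )


def simulate_epoch(
    shape: str,
    noise_sd: float,
    seed: int,
    amplitude_pct: float = 2.0,
    baseline_level: float = 1000.0,
    tr: float = 1.55,
    baseline_duration_s: float = 60.0,
    dilation_duration_s: float = 180.0,
    rise_time_s: float = 20.0,
) -> SimulatedResponse:
    """One noisy epoch of the requested shape on a rest+CO2 paradigm.

    Fast responses rise sigmoidally over ``rise_time_s`` after CO2 onset;
    slow responses ramp linearly over the whole dilation period.
    """
    n = int(round((baseline_duration_s + dilation_duration_s) / tr))
    t = np.arange(n) * tr
    if shape == "fast":
        clean = simulate_fast(t, amplitude_pct, baseline_level,
                              onset_s=baseline_duration_s, rise_time_s=rise_time_s)
        rise_samples = rise_time_s / tr
    elif shape == "slow":
        clean = simulate_slow(t, amplitude_pct, baseline_level,
                              onset_s=baseline_duration_s,
                              ramp_duration_s=dilation_duration_s)
        rise_samples = dilation_duration_s / tr
    else:
        raise ValueError(f"shape must be 'fast' or 'slow', got {shape!r}")
    return SimulatedResponse(
        shape=shape,
        amplitude_pct=amplitude_pct,
        baseline_level=baseline_level,
        noise_sd=noise_sd,
        seed=seed,
        series=add_noise(clean, noise_sd, seed),
        true_slope_per_sample=baseline_level * amplitude_pct / 100.0 / rise_samples,
    )


@dataclass(frozen=True)
class SimulationGrid:
    """Shapes × noise levels × replicates for the AIC comparison study.

    Noise levels are expressed as target tSNR values (baseline over noise
    sd); the default 2 × 20 × 100 grid spans tSNR 5–100 and totals 4,000
    epochs.
    """

    shapes: Tuple[str, ...] = ("fast", "slow")
    tsnr_targets: Tuple[float, ...] = tuple(np.geomspace(5.0, 100.0, 20))
    replicates: int = 100
    base_seed: int = 0
    amplitude_pct: float = 2.0
    baseline_level: float = 1000.0
    tr: float = 1.55
    baseline_duration_s: float = 60.0
    dilation_duration_s: float = 180.0

    @property
    def total(self) -> int:
        return len(self.shapes) * len(self.tsnr_targets) * self.replicates


def run_simulation_grid(grid: SimulationGrid) -> pd.DataFrame:
    """One :class:`~cvrkit.glm.ModelFitComparison` row per simulated epoch.

    Columns: shape, tsnr_target, noise_sd, replicate, tsnr (realized),
    aic_parametric, aic_nonparametric.
    """
    if grid.replicates < 1:
        raise ValueError("replicates must be >= 1")
    paradigm = epoch_paradigm(grid.tr, grid.baseline_duration_s, grid.dilation_duration_s)
    rng = np.random.default_rng(grid.base_seed)
    seeds = rng.integers(0, 2**31, size=grid.total)
    rows = []
    k = 0
    for shape in grid.shapes:
        for target in grid.tsnr_targets:
            noise_sd = grid.baseline_level / target
            for rep in range(grid.replicates):
                sim = simulate_epoch(
                    shape, noise_sd, int(seeds[k]),
                    amplitude_pct=grid.amplitude_pct,
                    baseline_level=grid.baseline_level,
                    tr=grid.tr,
                    baseline_duration_s=grid.baseline_duration_s,
                    dilation_duration_s=grid.dilation_duration_s,
                )
                cmp = compare_models(sim, paradigm)
                rows.append((shape, target, noise_sd, rep, cmp.tsnr,
                             cmp.aic_parametric, cmp.aic_nonparametric))
                k += 1
    return pd.DataFrame(
        rows,
        columns=["shape", "tsnr_target", "noise_sd", "replicate", "tsnr",
                 "aic_parametric", "aic_nonparametric"],
    )


# ---------------------------------------------------------------------------
# whole-subject synthesis


@dataclass(frozen=True)
class SyntheticSubject:
    """A synthetic two-challenge subject with stored ground truth."""

    id: str
    design: str                     # "A" or "B"
    group: str                      # "cognitive" or "sleep_apnea"
    age: float
    sex: str                        # "M" or "F"
    a1_pct: float                   # planted challenge-1 amplitude, %
    a2_pct: float                   # planted challenge-2 amplitude, %
    tau: float                      # window-linearized washout rate, a.u./s (< 0)
    theta_s: Optional[float]        # washout time constant (exponential mode)
    delta_petco2: float             # mmHg
    baseline_level: float
    noise_sd: float
    seed: int
    bold_series: SampledSeries
    petco2_trace: Optional[SampledSeries] = None


def _washout(t: np.ndarray, start_level: float, baseline: float,
             start_s: float, recovery: str, theta_s: float, tau: float) -> np.ndarray:
    """Recovery curve from ``start_level`` back toward baseline for t >= start_s."""
    dt = t - start_s
    if recovery == "exponential":
        return baseline + (start_level - baseline) * np.exp(-dt / theta_s)
    if recovery == "linear":
        return np.maximum(baseline, start_level + tau * dt)
    raise ValueError(f"recovery must be 'exponential' or 'linear', got {recovery!r}")


def _noise_free_bold(
    t: np.ndarray,
    windows: AnalysisWindows,
    baseline: float,
    a1_pct: float,
    a2_pct: float,
    recovery: str,
    theta_s: float,
    tau: float,
) -> np.ndarray:
    p1 = baseline * (1.0 + a1_pct / 100.0)
    p2 = baseline * (1.0 + a2_pct / 100.0)
    y = np.full_like(t, baseline)

    w = windows.cvr1
    in_ramp1 = (t >= w.start_s) & (t < w.end_s)
    y[in_ramp1] = baseline + (p1 - baseline) * (t[in_ramp1] - w.start_s) / w.duration_s

    rec1 = (t >= windows.transition1.start_s) & (t < windows.cvr2.start_s)
    y[rec1] = _washout(t[rec1], p1, baseline, windows.transition1.start_s,
                       recovery, theta_s, tau)

    # level carried into challenge 2 (negligible when washout has completed)
    s2 = float(_washout(np.array([windows.cvr2.start_s]), p1, baseline,
                        windows.transition1.start_s, recovery, theta_s, tau)[0])
    w = windows.cvr2
    in_ramp2 = (t >= w.start_s) & (t < w.end_s)
    y[in_ramp2] = s2 + (p2 - s2) * (t[in_ramp2] - w.start_s) / w.duration_s

    rec2 = t >= windows.transition2.start_s
    y[rec2] = _washout(t[rec2], p2, baseline, windows.transition2.start_s,
                       recovery, theta_s, tau)
    return y


def _windowed_washout_rate(
    windows: AnalysisWindows,
    tr: float,
    baseline: float,
    a1_pct: float,
    recovery: str,
    theta_s: float,
    tau: float,
) -> float:
    """Noise-free OLS slope (a.u./s) of the recovery over transition window 1.

    This is exactly what the transition-rate read-out measures on a clean
    subject, so cohorts plant effects on a quantity the pipeline can recover.
    """
    w = windows.transition1
    k = np.arange(int(np.ceil(w.start_s / tr)), int(np.ceil(w.end_s / tr)))
    t = k * tr
    p1 = baseline * (1.0 + a1_pct / 100.0)
    y = _washout(t, p1, baseline, w.start_s, recovery, theta_s, tau)
    t_c = t - t.mean()
    return float(t_c @ (y - y.mean()) / (t_c @ t_c))


def _petco2_trace(
    t_end: float,
    design: str,
    delta: float,
    seed: int,
    baseline_mmHg: float = 40.0,
    sample_hz: float = 10.0,
    breath_hz: float = 0.25,
    breath_depth_mmHg: float = 8.0,
    washin_s: float = 8.0,
    noise_sd_mmHg: float = 0.2,
) -> SampledSeries:
    """Breath-modulated two-level CO2 trace whose expiration peaks track PETCO2."""
    paradigm = design_paradigm(design)
    discard_s = DISCARD_VOLUMES[design] * paradigm.tr
    dt = 1.0 / sample_hz
    t = np.arange(0.0, t_end, dt)
    gas = np.zeros_like(t)
    for start, end in paradigm.co2_intervals():
        gas[((t + discard_s) >= start) & ((t + discard_s) < end)] = 1.0
    # first-order wash-in/wash-out of the end-tidal level
    alpha = 1.0 - np.exp(-dt / washin_s)
    level = np.empty_like(gas)
    acc = gas[0]
    for k, g in enumerate(gas):
        acc += alpha * (g - acc)
        level[k] = acc
    petco2_level = baseline_mmHg + delta * level
    breath = 0.5 * (1.0 - np.cos(2.0 * np.pi * breath_hz * t))  # 0 at peaks
    rng = np.random.default_rng(seed)
    values = petco2_level - breath_depth_mmHg * breath + rng.normal(0, noise_sd_mmHg, t.size)
    return SampledSeries(values, tr=dt, t0=0.0)


def synthesize_subject(
    design: str = "A",
    a1_pct: float = 2.0,
    a2_pct: float = 2.0,
    delta_petco2: float = 10.0,
    theta_s: Optional[float] = None,
    recovery: str = "exponential",
    tau: Optional[float] = None,
    baseline_level: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    subject_id: str = "sub-000",
    group: str = "cognitive",
    age: float = 70.0,
    sex: str = "F",
    generate_petco2_trace: bool = False,
) -> SyntheticSubject:
    """Build a full paradigm-length synthetic subject.

    The BOLD series (post-discard axis, length and TR of the chosen design)
    is baseline plus a linear dilation ramp spanning each CVR analysis
    window, with recovery back to baseline between and after challenges.
    Default recovery is an exponential CO2 washout with time constant
    ``theta_s`` (default: a fifth of the first transition window); a linear
    decay at rate ``tau`` (a.u./s, clamped at baseline) is available with
    ``recovery="linear"``.  The stored ``tau`` ground truth is the noise-free
    OLS rate over transition window 1 — exactly what the transition-rate
    read-out estimates.
    """
    paradigm = design_paradigm(design)
    design = paradigm.design_label
    windows = windows_for_design(design)
    if not baseline_level > 0:
        raise ValueError("baseline_level must be positive")
    if a1_pct < 0 or a2_pct < 0:
        raise ValueError("challenge amplitudes must be non-negative")
    dur1 = windows.transition1.duration_s
    if theta_s is None:
        theta_s = dur1 / 5.0
    if tau is None:
        tau = -baseline_level * (a1_pct / 100.0) / dur1
    n = N_VOLUMES[design] - DISCARD_VOLUMES[design]
    t = np.arange(n) * paradigm.tr

    clean = _noise_free_bold(t, windows, baseline_level, a1_pct, a2_pct,
                             recovery, theta_s, tau)
    series = add_noise(SampledSeries(clean, paradigm.tr, 0.0), noise_sd, seed)
    tau_true = _windowed_washout_rate(windows, paradigm.tr, baseline_level,
                                      a1_pct, recovery, theta_s, tau)
    trace = None
    if generate_petco2_trace:
        trace = _petco2_trace(t_end=n * paradigm.tr, design=design,
                              delta=delta_petco2, seed=seed + 1)
    return SyntheticSubject(
        id=subject_id,
        design=design,
        group=group,
        age=age,
        sex=sex,
        a1_pct=a1_pct,
        a2_pct=a2_pct,
        tau=tau_true,
        theta_s=theta_s if recovery == "exponential" else None,
        delta_petco2=delta_petco2,
        baseline_level=baseline_level,
        noise_sd=noise_sd,
        seed=seed,
        bold_series=series,
        petco2_trace=trace,
    )


#: demographic strata mirroring a 20 + 20 + 14 two-design cohort:
#: (group, design, fraction, mean age, sd age, P(male))
_STRATA = (
    ("cognitive", "A", 20 / 54, 70.0, 9.0, 0.45),
    ("sleep_apnea", "A", 20 / 54, 59.0, 12.0, 0.65),
    ("cognitive", "B", 14 / 54, 72.0, 11.0, 0.214),
)


def synthesize_cohort(
    n_subjects: int = 54,
    beta: float = -80.0,
    seed: int = 0,
    mean_a1_pct: float = 2.0,
    sd_a1_pct: float = 0.5,
    mean_a2_pct: float = 2.0,
    epsilon_sd_pct: float = 0.15,
    noise_sd: float = 8.0,
    baseline_level: float = 1000.0,
    generate_petco2_trace: bool = False,
) -> list:
    """A cohort with a planted linear washout-rate → CVR-2 dependence.

    Per subject the challenge-1 amplitude ``a1``, washout time constant θ
    (uniform over [dur/10, dur/3.5] of the first transition window) and
    ΔPETCO2 are drawn, the window-linearized washout rate τ (a.u./s) is
    computed, and the challenge-2 amplitude is planted as::

        a2 = mean_a2 + beta * (tau_pct - tau_ref) + eps

    with ``tau_pct = 100 * tau / baseline`` in %/s, ``tau_ref`` the rate of a
    design-typical subject (centring keeps a2 near ``mean_a2``), and
    ``beta`` in % per (%/s).  ``beta < 0`` plants the faster-washout →
    larger-next-response effect; ``beta = 0`` gives a null cohort.
    Age, sex, group and design covariates carry no planted effect.

    ΔPETCO2 is drawn with deliberately small between-subject spread (sd
    0.25 mmHg around the design target): because the same Δ normalizes both
    the transition rate and CVR-2, between-subject Δ variance would couple
    the two metrics and contaminate β = 0 calibration cohorts with a
    spurious association.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    rng = np.random.default_rng(seed)
    # stratum assignment by fixed proportions
    counts = [int(round(frac * n_subjects)) for _, _, frac, *_ in _STRATA]
    counts[0] += n_subjects - sum(counts)
    subjects = []
    sub_idx = 0
    for (group, design, _, age_mu, age_sd, p_male), count in zip(_STRATA, counts):
        windows = windows_for_design(design)
        paradigm = design_paradigm(design)
        dur1 = windows.transition1.duration_s
        theta_lo, theta_hi = dur1 / 16.0, dur1 / 3.5
        tau_ref = _windowed_washout_rate(
            windows, paradigm.tr, baseline_level, mean_a1_pct,
            "exponential", 0.5 * (theta_lo + theta_hi), 0.0,
        ) / baseline_level * 100.0
        for _ in range(count):
            a1 = float(np.clip(rng.normal(mean_a1_pct, sd_a1_pct), 0.5, None))
            theta = float(rng.uniform(theta_lo, theta_hi))
            tau_pct = _windowed_washout_rate(
                windows, paradigm.tr, baseline_level, a1, "exponential", theta, 0.0
            ) / baseline_level * 100.0
            a2 = mean_a2_pct + beta * (tau_pct - tau_ref) + rng.normal(0, epsilon_sd_pct)
            a2 = float(np.clip(a2, 0.2, None))
            if design == "B":
                delta = float(np.clip(rng.normal(10.0, 0.25), 9.0, 11.0))
            else:
                delta = float(np.clip(rng.normal(8.0, 0.25), 7.0, 9.0))
            age = float(np.clip(rng.normal(age_mu, age_sd), 40.0, 90.0))
            sex = "M" if rng.random() < p_male else "F"
            subjects.append(
                synthesize_subject(
                    design=design,
                    a1_pct=a1,
                    a2_pct=a2,
                    delta_petco2=delta,
                    theta_s=theta,
                    baseline_level=baseline_level,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31)),
                    subject_id=f"sub-{sub_idx:03d}",
                    group=group,
                    age=age,
                    sex=sex,
                    generate_petco2_trace=generate_petco2_trace,
                )
            )
            sub_idx += 1
    return subjects


def cohort_manifest(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Ground-truth manifest: one row per subject, truth columns included."""
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "design": [s.design for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "delta_petco2": [s.delta_petco2 for s in subjects],
            "true_a1_pct": [s.a1_pct for s in subjects],
            "true_a2_pct": [s.a2_pct for s in subjects],
            "true_tau": [s.tau for s in subjects],
            "theta_s": [s.theta_s for s in subjects],
            "noise_sd": [s.noise_sd for s in subjects],
            "seed": [s.seed for s in subjects],
        }
    )


def subject_to_csv(subject: SyntheticSubject) -> str:
    """Deterministic CSV serialization of a subject's BOLD series."""
    buf = StringIO()
    pd.DataFrame(
        {"t_s": subject.bold_series.times, "bold": subject.bold_series.values}
    ).to_csv(buf, index=False, float_format="%.10g")
    return buf.getvalue()
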