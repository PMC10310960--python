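"""Per-subject metric extraction and cohort tables.

Glue between the signal layer and the group statistics: run the
window → Sen's-slope → normalization pipeline plus the transition-rate
read-out on one subject's ROI-mean series, and tabulate a cohort of synthetic
subjects into the record format the group models consume.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .capnometry import Petco2Summary
from .glm import gamma_hrf, glm_cope
from .metrics import (
    CvrEstimate,
    TransitionFit,
    cvr_for_challenge,
    transition_fit_for_challenge,
)
from .paradigm import (
    DISCARD_VOLUMES,
    AnalysisWindows,
    build_boxcar,
    design_paradigm,
    windows_for_design,
)
from .series import SampledSeries

__all__ = ["SubjectMetrics", "subject_metrics", "cohort_records"]


@dataclass(frozen=True)
class SubjectMetrics:
    """Both per-challenge CVR estimates and both transition fits."""

    cvr1: CvrEstimate
    cvr2: CvrEstimate
    transition1: TransitionFit
    transition2: TransitionFit
    cope: Optional[float] = None

    def as_row(self) -> dict:
        row = {
            "cvr1": self.cvr1.cvr,
            "cvr2": self.cvr2.cvr,
            "pct_bold_1": self.cvr1.pct_bold,
            "pct_bold_2": self.cvr2.pct_bold,
            "transition_rate_1": self.transition1.transition_rate,
            "transition_rate_2": self.transition2.transition_rate,
            "tau_1": self.transition1.tau,
            "tau_2": self.transition2.tau,
        }
        if self.cope is not None:
            row["cope_cvr"] = self.cope
        return row


def subject_metrics(
    series: SampledSeries,
    design: str,
    petco2: Union[Petco2Summary, float],
    windows: Optional[AnalysisWindows] = None,
    compute_cope: bool = False,
) -> SubjectMetrics:
    """All temporal CVR metrics of one post-discard ROI-mean series.

    ``petco2`` is a :class:`~cvrkit.capnometry.Petco2Summary` or a scalar
    ΔPETCO2 (mmHg) applied to both challenges.  With ``compute_cope`` the
    conventional HRF-convolved GLM coefficient over the whole paradigm is
    added (normalized to % per mmHg using challenge-1's baseline).
    """
    if windows is None:
        windows = windows_for_design(design)
    delta = petco2.delta if isinstance(petco2, Petco2Summary) else float(petco2)
    est1 = cvr_for_challenge(series, windows, 1, petco2)
    est2 = cvr_for_challenge(series, windows, 2, petco2)
    fit1 = transition_fit_for_challenge(series, windows, 1, delta)
    fit2 = transition_fit_for_challenge(series, windows, 2, delta)
    cope = None
    if compute_cope:
        paradigm = design_paradigm(design)
        boxcar = build_boxcar(
            paradigm, n_samples=len(series),
            discard_s=DISCARD_VOLUMES[paradigm.design_label] * paradigm.tr,
        )
        result = glm_cope(series, boxcar, hrf=gamma_hrf(paradigm.tr),
                          delta_petco2=delta, baseline_mean=est1.baseline_mean)
        cope = result.pct_equivalent
    return SubjectMetrics(cvr1=est1, cvr2=est2, transition1=fit1,
                          transition2=fit2, cope=cope)


def cohort_records(
    subjects: Sequence,
    roi: str = "global",
    compute_cope: bool = False,
) -> pd.DataFrame:
    """Run the metrics pipeline on synthetic subjects → group-model records.

    Returns one row per subject with demographic covariates and measured
    metrics; ``roi`` labels the (single, whole-series) region the synthetic
    subjects represent.
    """
    rows = []
    for s in subjects:
        m = subject_metrics(s.bold_series, s.design, s.delta_petco2,
                            compute_cope=compute_cope)
        row = {
            "id": s.id,
            "roi": roi,
            "age": s.age,
            "sex": s.sex,
            "group": s.group,
            "design": s.design,
        }
        row.update(m.as_row())
        rows.append(row)
    return pd.DataFrame(rows)
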