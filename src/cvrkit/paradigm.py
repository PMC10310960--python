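"""Gas-challenge breathing paradigms and analytical time windows.

Two boxcar hypercapnia paradigms are built in:

* **Design A** — 2 min room air, 3 min 6% CO2, 2 min room air, 3 min CO2,
  2 min room air; TR 1.55 s; 478 volumes of which the first 25 are discarded.
* **Design B** — 45 s rest, 45 s CO2, 90 s rest, 120 s CO2, 180 s rest
  (RespirAct-targeted, ~10 mmHg PETCO2 step); TR 2.0 s; 255 volumes,
  first 5 discarded.

All analysis windows (per-challenge dilation windows CVR-1/CVR-2 and the two
hyper-to-normocapnia transition windows) are fixed constants expressed on the
**post-discard** time axis, where t = 0 is the first retained volume.  The
per-challenge baseline window is the 30 s immediately preceding each dilation
window (truncated at t = 0), i.e. late-rest samples least contaminated by the
preceding transition.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

from .series import SampledSeries, TimeWindow, slice_window  # noqa: F401

__all__ = [
    "ROOM_AIR",
    "CO2",
    "BlockParadigm",
    "AnalysisWindows",
    "design_paradigm",
    "windows_for_design",
    "build_boxcar",
    "paradigm_from_config",
    "DISCARD_VOLUMES",
    "N_VOLUMES",
]

ROOM_AIR = "room_air"
CO2 = "co2"
_STATES = (ROOM_AIR, CO2)

#: volumes discarded for signal equilibrium, per design
DISCARD_VOLUMES = {"A": 25, "B": 5}
#: acquired volumes per design
N_VOLUMES = {"A": 478, "B": 255}
_TR = {"A": 1.55, "B": 2.0}

_BLOCKS = {
    "A": (
        (ROOM_AIR, 120.0),
        (CO2, 180.0),
        (ROOM_AIR, 120.0),
        (CO2, 180.0),
        (ROOM_AIR, 120.0),
    ),
    "B": (
        (ROOM_AIR, 45.0),
        (CO2, 45.0),
        (ROOM_AIR, 90.0),
        (CO2, 120.0),
        (ROOM_AIR, 180.0),
    ),
}

# dilation and transition windows, seconds on the post-discard axis
_WINDOWS = {
    "A": dict(cvr1=(40.0, 280.0), cvr2=(360.0, 580.0),
              transition1=(280.0, 360.0), transition2=(580.0, 660.0)),
    "B": dict(cvr1=(10.0, 80.0), cvr2=(135.0, 280.0),
              transition1=(80.0, 135.0), transition2=(280.0, 390.0)),
}


@dataclass(frozen=True)
class BlockParadigm:
    """An ordered boxcar schedule of gas states.

    ``blocks`` is a sequence of ``(gas_state, duration_s)`` pairs on the
    paradigm clock (t = 0 at the scan start, before any volume discard).
    """

    blocks: tuple
    tr: float
    design_label: Union[str, None] = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("paradigm needs at least one block")
        for state, dur in self.blocks:
            if state not in _STATES:
                raise ValueError(f"unknown gas state {state!r}; expected one of {_STATES}")
            if not dur > 0:
                raise ValueError(f"block durations must be strictly positive, got {dur}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.blocks))

    def block_edges(self) -> np.ndarray:
        """Cumulative block boundaries including 0 and the total duration."""
        return np.concatenate([[0.0], np.cumsum([d for _, d in self.blocks])])

    def state_at(self, t_paradigm: float) -> str:
        """Gas state at a paradigm-clock time (closed-open block intervals)."""
        if t_paradigm < 0 or t_paradigm >= self.total_duration_s:
            return ROOM_AIR
        edges = self.block_edges()
        i = int(np.searchsorted(edges, t_paradigm, side="right")) - 1
        return self.blocks[i][0]

    def co2_intervals(self) -> list:
        """Paradigm-clock ``(start, end)`` of every CO2 block."""
        edges = self.block_edges()
        return [
            (float(edges[i]), float(edges[i + 1]))
            for i, (state, _) in enumerate(self.blocks)
            if state == CO2
        ]


def design_paradigm(design_label: str) -> BlockParadigm:
    """The built-in boxcar paradigm for experimental design ``"A"`` or ``"B"``."""
    label = _check_label(design_label)
    return BlockParadigm(blocks=_BLOCKS[label], tr=_TR[label], design_label=label)


@dataclass(frozen=True)
class AnalysisWindows:
    """Per-challenge dilation, transition and baseline windows (post-discard s)."""

    cvr1: TimeWindow
    cvr2: TimeWindow
    transition1: TimeWindow
    transition2: TimeWindow
    baseline1: TimeWindow
    baseline2: TimeWindow

    def __post_init__(self) -> None:
        # each dilation window precedes its own transition window
        if self.cvr1.end_s > self.transition1.start_s:
            raise ValueError("cvr1 must end at or before transition1 starts")
        if self.cvr2.end_s > self.transition2.start_s:
            raise ValueError("cvr2 must end at or before transition2 starts")
        if self.baseline1.end_s > self.cvr1.start_s:
            raise ValueError("baseline1 must precede cvr1")
        if self.baseline2.end_s > self.cvr2.start_s:
            raise ValueError("baseline2 must precede cvr2")

    def cvr(self, challenge_index: int) -> TimeWindow:
        return {1: self.cvr1, 2: self.cvr2}[_check_challenge(challenge_index)]

    def baseline(self, challenge_index: int) -> TimeWindow:
        return {1: self.baseline1, 2: self.baseline2}[_check_challenge(challenge_index)]

    def transition(self, challenge_index: int) -> TimeWindow:
        return {1: self.transition1, 2: self.transition2}[_check_challenge(challenge_index)]


def windows_for_design(design_label: str, baseline_duration_s: float = 30.0) -> AnalysisWindows:
    """Analytical time windows for a built-in design.

    The dilation (CVR-1/CVR-2) and hyper-to-normocapnia transition windows are
    fixed per design; each baseline window is the ``baseline_duration_s``
    seconds immediately preceding the corresponding dilation window, truncated
    at t = 0.
    """
    label = _check_label(design_label)
    if not baseline_duration_s > 0:
        raise ValueError("baseline_duration_s must be positive")
    w = _WINDOWS[label]
    cvr1, cvr2 = TimeWindow(*w["cvr1"]), TimeWindow(*w["cvr2"])
    return AnalysisWindows(
        cvr1=cvr1,
        cvr2=cvr2,
        transition1=TimeWindow(*w["transition1"]),
        transition2=TimeWindow(*w["transition2"]),
        baseline1=TimeWindow(max(0.0, cvr1.start_s - baseline_duration_s), cvr1.start_s),
        baseline2=TimeWindow(max(0.0, cvr2.start_s - baseline_duration_s), cvr2.start_s),
    )


def build_boxcar(paradigm: BlockParadigm, n_samples: int, discard_s: float = 0.0) -> SampledSeries:
    """Sample the paradigm as a 0/1 boxcar on the post-discard time axis.

    Sample *k* (post-discard time ``k * tr``) is 1 when the paradigm clock
    time ``k * tr + discard_s`` falls inside a CO2 block, else 0.  Times past
    the end of the schedule are treated as room air.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if discard_s < 0:
        raise ValueError("discard_s must be >= 0")
    if discard_s >= paradigm.total_duration_s:
        raise ValueError(
            f"discard ({discard_s} s) consumes the whole paradigm "
            f"({paradigm.total_duration_s} s)"
        )
    t_par = np.arange(n_samples) * paradigm.tr + discard_s
    values = np.zeros(n_samples)
    for start, end in paradigm.co2_intervals():
        values[(t_par >= start) & (t_par < end)] = 1.0
    return SampledSeries(values, tr=paradigm.tr, t0=0.0)


def paradigm_from_config(source: Union[str, Path, Mapping]) -> BlockParadigm:
    """Build a paradigm from a YAML/JSON-style mapping or a file path.

    Accepted forms::

        design: A                    # built-in preset ("designA" also works)

        tr_s: 1.55                   # explicit block list
        blocks:
          - {state: room_air, duration_s: 120}
          - {state: co2, duration_s: 180}
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping):
        raise ValueError("paradigm config must be a mapping")
    if "design" in cfg:
        label = str(cfg["design"]).removeprefix("design")
        return design_paradigm(label)
    try:
        blocks = tuple((b["state"], float(b["duration_s"])) for b in cfg["blocks"])
        tr = float(cfg["tr_s"])
    except (KeyError, TypeError) as exc:
        raise ValueError(
            "paradigm config needs either 'design' or 'blocks' + 'tr_s'"
        ) from exc
    return BlockParadigm(blocks=blocks, tr=tr, design_label=cfg.get("design_label"))


def _check_label(design_label: str) -> str:
    label = str(design_label).upper()
    if label not in _BLOCKS:
        raise ValueError(
            f"unknown design label {design_label!r}; valid labels: "
            + ", ".join(sorted(_BLOCKS))
        )
    return label


def _check_challenge(challenge_index: int) -> int:
    if challenge_index not in (1, 2):
        raise ValueError(f"challenge_index must be 1 or 2, got {challenge_index}")
    return challenge_index
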