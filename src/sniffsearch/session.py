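"""Session containers: the unit of data every pipeline stage consumes.

Coordinates are stored in cm with the origin at the initiation-port wall
corner: the longitudinal axis runs 0 -> 25 cm toward the odor ports and the
lateral axis 0 -> 15 cm.  Frames are 0-based at 80 Hz, times in seconds,
intervals half-open [start, end).  A px-per-cm scale is carried so
pixel-based criteria (e.g. the 100 px/frame glitch threshold) stay
applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sniff import SniffEvents, SniffTrace


@dataclass
class TrialMeta:
    start_s: float
    end_s: float
    side: str                      # stimulus side: "left" | "right"
    ratio: tuple                   # odor concentration ratio, e.g. (80, 20)
    choice: str | None             # chosen side
    correct: bool | None           # None for the 0:0 condition
    decision_time_s: float | None = None
    iti_end_s: float | None = None

    def __post_init__(self) -> None:
        if self.choice is not None and self.choice not in ("left", "right"):
            raise ValueError("choice must be 'left' or 'right'")
        if self.end_s <= self.start_s:
            raise ValueError("trial end must follow start")


@dataclass
class Trial:
    nose: np.ndarray               # (T, 2) cm
    head: np.ndarray
    body: np.ndarray
    frame_times: np.ndarray        # (T,) seconds, session clock
    sniff: SniffEvents | None
    trace: SniffTrace | None
    meta: TrialMeta

    def __post_init__(self) -> None:
        T = self.frame_times.shape[0]
        for arr in (self.nose, self.head, self.body):
            if arr.shape != (T, 2):
                raise ValueError("keypoint arrays must be (T, 2)")

    @property
    def n_frames(self) -> int:
        return self.frame_times.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.meta.end_s - self.meta.start_s)


@dataclass
class SessionBundle:
    mouse_id: str
    session_id: str
    trials: list
    px_per_cm: float
    frame_rate: float = 80.0

    def __post_init__(self) -> None:
        starts = [t.meta.start_s for t in self.trials]
        ends = [t.meta.end_s for t in self.trials]
        for k in range(1, len(self.trials)):
            if starts[k] < ends[k - 1]:
                raise ValueError("trial times must be non-overlapping and increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)
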