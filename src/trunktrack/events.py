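"""Movement-cycle events for gait strides and drop-vertical-jump landings."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EventsNotFound

#: heel height (mm) below which the foot is considered in ground contact
DEFAULT_CONTACT_THRESHOLD_MM = 30.0


@dataclass(frozen=True)
class CycleAnnotation:
    """Event frames delimiting one analysed movement cycle.

    gait: ``heel_strike``, ``toe_off``, ``next_heel_strike`` (one stride).
    dvj:  ``initial_contact``, ``take_off`` of the first landing, plus an
    optional ``max_descent`` frame.
    """

    task: str
    events: dict[str, int] = field(default_factory=dict)

    _ORDER = {
        "gait": ("heel_strike", "toe_off", "next_heel_strike"),
        "dvj": ("initial_contact", "take_off"),
    }

    def __post_init__(self):
        if self.task not in self._ORDER:
            raise ValueError(f"unknown task {self.task!r}")
        seq = [self.events[k] for k in self._ORDER[self.task] if k in self.events]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("event frames must be strictly increasing")
        if any(v < 0 for v in self.events.values()):
            raise ValueError("event frames must be non-negative")

    def __getitem__(self, key: str) -> int:
        return self.events[key]

    @property
    def cycle(self) -> tuple[int, int]:
        """(start, stop) frame indices of the analysed cycle, inclusive."""
        if self.task == "gait":
            return self.events["heel_strike"], self.events["next_heel_strike"]
        return self.events["initial_contact"], self.events["take_off"]


def detect_dvj_events(heel_height: np.ndarray, rate: float,
                      threshold: float = DEFAULT_CONTACT_THRESHOLD_MM,
                      ) -> CycleAnnotation:
    """Detect first-landing initial contact and take-off from heel height.

    Initial contact is the first frame where the height crosses below
    *threshold* while descending; take-off is the first later frame
    crossing back above it while ascending.
    """
    h = np.asarray(heel_height, dtype=float)
    if h.ndim != 1 or h.size < 3:
        raise EventsNotFound("heel height series too short")
    below = h < threshold
    vel = np.diff(h, prepend=h[0])
    down = np.flatnonzero(below[1:] & ~below[:-1] & (vel[1:] < 0)) + 1
    if down.size == 0:
        raise EventsNotFound("no descending crossing below threshold")
    ic = int(down[0])
    up = np.flatnonzero(~below[1:] & below[:-1] & (vel[1:] > 0)) + 1
    up = up[up > ic]
    if up.size == 0:
        raise EventsNotFound("no ascending crossing above threshold after contact")
    to = int(up[0])
    return CycleAnnotation(task="dvj",
                           events={"initial_contact": ic, "take_off": to})


def max_descent_frame(origin_height: np.ndarray,
                      annotation: CycleAnnotation) -> int:
    """Frame of lowest trunk-origin height within [IC, TO]; first index on ties."""
    if annotation.task != "dvj":
        raise ValueError("max descent is defined for DVJ cycles only")
    ic, to = annotation.cycle
    window = np.asarray(origin_height, dtype=float)[ic:to + 1]
    return ic + int(np.nanargmin(window))
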