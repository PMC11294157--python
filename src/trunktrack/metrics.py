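"""Per-cycle trunk-tilt summary measures."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyCycle
from .events import CycleAnnotation, max_descent_frame
from .models import AngleSeries

METRIC_NAMES = ("mean", "max", "min", "rom")


@dataclass(frozen=True)
class TiltMetrics:
    """Mean / max / min / ROM of trunk tilt (degrees) over one cycle.

    For gait, ``mean`` is the average tilt across the stride.  For the
    DVJ, ``mean`` is the tilt recorded at maximum descent of the first
    landing (lowest trunk-origin height between initial contact and
    take-off).  ``rom = max - min`` always.
    """

    mean: float
    max: float
    min: float
    rom: float
    task: str
    cycle: tuple[int, int]

    def as_dict(self) -> dict[str, float]:
        return {"mean": self.mean, "max": self.max,
                "min": self.min, "rom": self.rom}


def compute_metrics(angles: AngleSeries | np.ndarray,
                    annotation: CycleAnnotation,
                    origin_height: np.ndarray | None = None) -> TiltMetrics:
    """Cycle metrics of trunk tilt.

    gait: mean/max/min/ROM over heel-strike to ipsilateral heel-strike.
    dvj: max/min/ROM over [initial contact, take-off]; ``mean`` is the
    tilt at the maximum-descent frame, located from *origin_height*
    (required unless the annotation already carries ``max_descent``).
    """
    if isinstance(angles, AngleSeries):
        tilt = angles.tilt
        if origin_height is None and angles.origin is not None:
            origin_height = angles.origin[:, 2]
    else:
        tilt = np.asarray(angles, dtype=float)
    start, stop = annotation.cycle
    if stop >= tilt.shape[0]:
        raise EmptyCycle("annotation extends past the end of the series")
    window = tilt[start:stop + 1]
    if not np.isfinite(window).any():
        raise EmptyCycle("no valid tilt samples inside the cycle")

    t_max = float(np.nanmax(window))
    t_min = float(np.nanmin(window))
    if annotation.task == "gait":
        t_mean = float(np.nanmean(window))
    else:
        md = annotation.events.get("max_descent")
        if md is None:
            if origin_height is None:
                raise ValueError("DVJ metrics need origin_height or a "
                                 "max_descent event")
            md = max_descent_frame(origin_height, annotation)
        t_mean = float(tilt[md])
    return TiltMetrics(mean=t_mean, max=t_max, min=t_min, rom=t_max - t_min,
                       task=annotation.task, cycle=(start, stop))
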