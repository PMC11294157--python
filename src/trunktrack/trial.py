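"""The universal trial container: labelled 3-D marker trajectories."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GapWarning, MissingMarker

TRIAL_KINDS = ("static", "gait", "dvj", "dynamic")

#: midline trunk markers used by the tracking models
TRUNK_MARKERS = ("CLAV", "XP", "M-STRN", "T1", "T10")


@dataclass
class MarkerTrialSet:
    """Time-indexed labelled marker positions for one trial.

    Parameters
    ----------
    positions
        marker name -> float array of shape ``(n_frames, 3)`` in mm
        (laboratory frame).  Occluded frames hold NaN.
    rate
        Sampling rate in Hz (study hardware: 240 Hz).
    kind
        One of ``static | gait | dvj | dynamic``.
    subject, sex
        Participant identifier and optional sex label (``"F"``/``"M"``).
    occluded
        marker name -> boolean array ``(n_frames,)``; derived from NaNs
        when not supplied.
    """

    positions: dict[str, np.ndarray]
    rate: float
    kind: str = "dynamic"
    subject: str = "S00"
    sex: str | None = None
    occluded: dict[str, np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind not in TRIAL_KINDS:
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if not self.positions:
            raise ValueError("trial has no markers")
        counts = set()
        for name, arr in list(self.positions.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r}: positions must be (n, 3)")
            self.positions[name] = arr
            counts.add(arr.shape[0])
        if len(counts) != 1:
            raise ValueError("all markers must share the same frame count")
        if self.occluded is None:
            self.occluded = {
                name: np.isnan(arr).any(axis=1)
                for name, arr in self.positions.items()
            }
        else:
            for name in self.positions:
                mask = np.asarray(self.occluded.get(name, np.zeros(self.n_frames, bool)))
                mask = mask.astype(bool)
                if mask.shape != (self.n_frames,):
                    raise ValueError(f"marker {name!r}: bad occlusion mask shape")
                self.occluded[name] = mask
                # occluded frames carry no position
                self.positions[name][mask] = np.nan

    # -- basic accessors ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.positions)

    def require(self, names) -> None:
        """Raise :class:`MissingMarker` unless every name is present."""
        for name in names:
            if name not in self.positions:
                raise MissingMarker(name, context=f"trial {self.subject}/{self.kind}")

    def marker(self, name: str) -> np.ndarray:
        self.require([name])
        return self.positions[name]

    def copy(self) -> "MarkerTrialSet":
        return MarkerTrialSet(
            positions={k: v.copy() for k, v in self.positions.items()},
            rate=self.rate, kind=self.kind, subject=self.subject, sex=self.sex,
            occluded={k: v.copy() for k, v in self.occluded.items()},
        )

    # -- gap handling ------------------------------------------------------
    def interpolate_gaps(self, max_gap_s: float = 0.1) -> "MarkerTrialSet":
        """Linearly fill interior occlusion gaps no longer than *max_gap_s*.

        Longer gaps (and leading/trailing gaps) stay missing; a
        :class:`GapWarning` is emitted for each.
        """
        out = self.copy()
        max_gap = int(round(max_gap_s * self.rate))
        frames = np.arange(self.n_frames)
        for name, mask in out.occluded.items():
            if not mask.any():
                continue
            good = ~mask
            if good.sum() < 2:
                warnings.warn(f"{name}: too few visible frames to interpolate",
                              GapWarning)
                continue
            fill = mask.copy()
            # identify interior gap runs and their lengths
            for start, stop in _runs(mask):
                interior = start > 0 and stop < self.n_frames
                if not interior or (stop - start) > max_gap:
                    fill[start:stop] = False
                    warnings.warn(
                        f"{name}: gap of {stop - start} frames at {start} "
                        "left missing", GapWarning)
            if fill.any():
                for axis in range(3):
                    out.positions[name][fill, axis] = np.interp(
                        frames[fill], frames[good], out.positions[name][good, axis])
                out.occluded[name] = mask & ~fill
        return out


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)
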