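"""Trunk anatomical/technical frame construction, calibration and tracking.

The anatomical trunk segment is defined in the static trial from the four
midline markers CLAV (jugular notch), XP (xiphoid process), T1 and T10
(1st/10th thoracic spinous processes).  Three tracking variants replace or
drop markers that are hard to place or easily occluded, especially with a
sports bra: the Mid-Sternum model swaps XP for M-STRN (midpoint of CLAV and
XP), the No-Thorax model drops T10 and the No-Sternum model drops the
sternum marker entirely.

Four-marker models build their axes from virtual midpoint markers; the
three-marker models build them from vectors between the surface markers.
In every case the longitudinal (inferior-to-superior) direction is the
primary axis because it is the best-conditioned direction for midline
markers; the anterior reference is orthogonalised against it.  Whatever
recipe a tracking model uses, a constant calibration rotation measured in
the static trial maps its technical frame onto the anatomical frame, so on
a rigid trunk every model reproduces the anatomical orientation exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometry, EmptyTrial, GimbalWarning
from .geometry import _frames_from_references, is_rotation, orthonormal_frame
from .trial import MarkerTrialSet

#: tilt/obliquity/axial extraction: intrinsic rotations, first (permanent)
#: axis = mediolateral lab Y, then anteroposterior X, then longitudinal Z.
EULER_SEQUENCE = "YXZ"

GIMBAL_TOL_DEG = 1e-6


class TrunkModel(str, Enum):
    DEFINITION = "definition"
    M_STRN = "m-strn"
    NO_THORAX = "no-thorax"
    NO_STERNUM = "no-sternum"

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    TrunkModel.DEFINITION: "Definition",
    TrunkModel.M_STRN: "M-STRN",
    TrunkModel.NO_THORAX: "No-Thorax",
    TrunkModel.NO_STERNUM: "No-Sternum",
}

#: tracking models compared against the Definition Model, in report order
TRACKING_MODELS = (TrunkModel.M_STRN, TrunkModel.NO_THORAX, TrunkModel.NO_STERNUM)


@dataclass(frozen=True)
class TrunkModelSpec:
    """Marker list and axis recipe of one trunk model."""

    model: TrunkModel
    markers: tuple[str, ...]
    recipe: str  # "four-marker-midpoint" | "three-marker-surface"

    def __post_init__(self):
        expected = 4 if self.recipe == "four-marker-midpoint" else 3
        if len(self.markers) != expected:
            raise ValueError(f"{self.model}: expected {expected} markers")


MODEL_SPECS: dict[TrunkModel, TrunkModelSpec] = {
    TrunkModel.DEFINITION: TrunkModelSpec(
        TrunkModel.DEFINITION, ("CLAV", "XP", "T1", "T10"), "four-marker-midpoint"),
    TrunkModel.M_STRN: TrunkModelSpec(
        TrunkModel.M_STRN, ("CLAV", "M-STRN", "T1", "T10"), "four-marker-midpoint"),
    TrunkModel.NO_THORAX: TrunkModelSpec(
        TrunkModel.NO_THORAX, ("CLAV", "M-STRN", "T1"), "three-marker-surface"),
    TrunkModel.NO_STERNUM: TrunkModelSpec(
        TrunkModel.NO_STERNUM, ("CLAV", "T1", "T10"), "three-marker-surface"),
}


@dataclass
class SegmentBasis:
    """Origin (mm) and right-handed orthonormal orientation of a trunk frame."""

    origin: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if not is_rotation(self.orientation, tol=1e-8):
            raise DegenerateGeometry("orientation is not a rotation matrix")


@dataclass
class Calibration:
    """Static-trial rotation offset aligning a technical frame with anatomy."""

    spec: TrunkModelSpec
    r_offset: np.ndarray  # technical -> anatomical
    anatomical_static: SegmentBasis
    technical_static: SegmentBasis


@dataclass
class AngleSeries:
    """Per-frame trunk angles in degrees; NaN where the frame is missing.

    ``tilt`` is signed flexion-positive (negative = extension), following
    the laboratory convention that flexion is a positive rotation about
    the mediolateral Y axis.
    """

    tilt: np.ndarray
    obliquity: np.ndarray
    axial: np.ndarray
    rate: float
    valid: np.ndarray
    origin: np.ndarray | None = None  # tracked frame origin path (n, 3) mm
    gimbal: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.tilt.shape[0]


# ---------------------------------------------------------------------------
# reference-vector recipes

def _reference_vectors(pos: dict[str, np.ndarray], spec: TrunkModelSpec):
    """Longitudinal/anterior reference vectors and origin for *spec*.

    Works on single points (3,) or trajectories (n, 3).
    """
    m = spec.model
    if spec.recipe == "four-marker-midpoint":
        sternal = "XP" if m is TrunkModel.DEFINITION else "M-STRN"
        sup = 0.5 * (pos["CLAV"] + pos["T1"])
        inf = 0.5 * (pos[sternal] + pos["T10"])
        ant = 0.5 * (pos["CLAV"] + pos[sternal])
        post = 0.5 * (pos["T1"] + pos["T10"])
        longitudinal = sup - inf
        anterior = ant - post
    elif m is TrunkModel.NO_THORAX:
        longitudinal = 0.5 * (pos["CLAV"] + pos["T1"]) - pos["M-STRN"]
        anterior = 0.5 * (pos["CLAV"] + pos["M-STRN"]) - pos["T1"]
    elif m is TrunkModel.NO_STERNUM:
        longitudinal = 0.5 * (pos["CLAV"] + pos["T1"]) - pos["T10"]
        anterior = pos["CLAV"] - 0.5 * (pos["T1"] + pos["T10"])
    else:  # pragma: no cover - specs above are exhaustive
        raise ValueError(f"unknown recipe {spec.recipe!r}")
    origin = sum(pos[name] for name in spec.markers) / len(spec.markers)
    return longitudinal, anterior, origin


def build_anatomical_frame(markers: dict[str, np.ndarray]) -> SegmentBasis:
    """Anatomical trunk frame from CLAV/XP/T1/T10 at a single time point.

    Virtual midpoints: superior = mid(CLAV, T1), inferior = mid(XP, T10),
    anterior = mid(CLAV, XP), posterior = mid(T1, T10).  Longitudinal axis
    (superior - inferior) maps to segment Z, anterior reference to X.
    """
    return build_technical_frame(markers, MODEL_SPECS[TrunkModel.DEFINITION])


def build_technical_frame(markers: dict[str, np.ndarray],
                          spec: TrunkModelSpec) -> SegmentBasis:
    """Technical frame of *spec* from its marker positions at one frame."""
    for name in spec.markers:
        if name not in markers:
            from .errors import MissingMarker
            raise MissingMarker(name, context=f"{spec.model.label} model")
    pos = {k: np.asarray(v, dtype=float) for k, v in markers.items()}
    longitudinal, anterior, origin = _reference_vectors(pos, spec)
    R = orthonormal_frame(longitudinal, anterior, order=("z", "x"))
    return SegmentBasis(origin=origin, orientation=R)


# ---------------------------------------------------------------------------
# calibration and tracking

def calibrate(static_trial: MarkerTrialSet, spec: TrunkModelSpec) -> Calibration:
    """Static-trial calibration of *spec* against the Definition Model.

    Both frames are built on the time-averaged static marker positions
    (over frames where every needed marker is visible); the offset
    ``R_offset = R_technical^T @ R_anatomical`` then satisfies
    ``technical_static @ R_offset == anatomical_static`` by construction.
    """
    needed = sorted(set(MODEL_SPECS[TrunkModel.DEFINITION].markers) | set(spec.markers))
    static_trial.require(needed)
    visible = np.ones(static_trial.n_frames, dtype=bool)
    for name in needed:
        visible &= ~static_trial.occluded[name]
    if not visible.any():
        raise EmptyTrial("static trial has no frames with all markers visible")
    mean_pos = {name: static_trial.positions[name][visible].mean(axis=0)
                for name in needed}
    anatomical = build_anatomical_frame(mean_pos)
    technical = build_technical_frame(mean_pos, spec)
    r_offset = technical.orientation.T @ anatomical.orientation
    return Calibration(spec=spec, r_offset=r_offset,
                       anatomical_static=anatomical, technical_static=technical)


def extract_angles(A: np.ndarray) -> tuple[float, float, float]:
    """Decompose ``A = R_Y(tilt) @ R_X'(obliquity) @ R_Z''(axial)``.

    Intrinsic sequence whose first, lab-fixed axis is the mediolateral Y
    axis; tilt positive = flexion.  Angles in degrees, in (-180, 180].
    Emits :class:`GimbalWarning` when obliquity is within 1e-6 deg of 90.
    """
    tilt, obliquity, axial = Rotation.from_matrix(np.asarray(A, float)).as_euler(
        EULER_SEQUENCE, degrees=True)
    if abs(abs(obliquity) - 90.0) < GIMBAL_TOL_DEG:
        warnings.warn("obliquity at gimbal lock", GimbalWarning)
    return float(tilt), float(obliquity), float(axial)


def _extract_angles_batch(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Euler angles (n, 3) [tilt, obliquity, axial] plus gimbal-proximity mask."""
    angles = Rotation.from_matrix(R).as_euler(EULER_SEQUENCE, degrees=True)
    angles = np.atleast_2d(angles)
    gimbal = np.abs(np.abs(angles[:, 1]) - 90.0) < GIMBAL_TOL_DEG
    return angles, gimbal


def track_trial(trial: MarkerTrialSet, calibration: Calibration) -> AngleSeries:
    """Track trunk orientation through a dynamic trial.

    Per frame the anatomical orientation is estimated as
    ``A(t) = R_technical(t) @ R_offset`` and decomposed into tilt,
    obliquity and axial rotation.  Frames with occluded markers or
    degenerate geometry become NaN gaps rather than errors.
    """
    spec = calibration.spec
    trial.require(spec.markers)
    pos = {name: trial.positions[name] for name in spec.markers}
    longitudinal, anterior, origin = _reference_vectors(pos, spec)
    R_tech, valid = _frames_from_references(longitudinal, anterior, ("z", "x"))

    n = trial.n_frames
    tilt = np.full(n, np.nan)
    obliquity = np.full(n, np.nan)
    axial = np.full(n, np.nan)
    gimbal = np.zeros(n, dtype=bool)
    if valid.any():
        A = R_tech[valid] @ calibration.r_offset
        angles, gim = _extract_angles_batch(A)
        tilt[valid] = angles[:, 0]
        obliquity[valid] = angles[:, 1]
        axial[valid] = angles[:, 2]
        gimbal[valid] = gim
        if gim.any():
            warnings.warn("obliquity near gimbal lock in tracked trial",
                          GimbalWarning)
    origin = np.where(valid[:, None], origin, np.nan)
    return AngleSeries(tilt=tilt, obliquity=obliquity, axial=axial,
                       rate=trial.rate, valid=valid, origin=origin,
                       gimbal=gimbal)
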