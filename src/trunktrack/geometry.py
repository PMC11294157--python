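"""Vector and rotation primitives plus the laboratory frame convention.

All positions are in millimetres, all public angles in degrees.  The
laboratory frame is right-handed with X along the direction of progression
(anterior during straight walking), Y to the subject's left and Z vertical.
With that convention a forward lean (trunk flexion) is a positive rotation
about the laboratory Y axis, so trunk tilt is signed flexion-positive.
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometry

#: orthonormality / determinant tolerance for rotation matrices
ORTHONORMALITY_TOL = 1e-9
#: two reference directions closer than this angle (radians) are "parallel"
PARALLEL_TOL_RAD = 1e-6

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

# Lab frame axes as rows, for readability where callers need them.
LAB_X = np.array([1.0, 0.0, 0.0])  # direction of progression (anterior)
LAB_Y = np.array([0.0, 1.0, 0.0])  # subject's left
LAB_Z = np.array([0.0, 0.0, 1.0])  # vertical up


def is_rotation(matrix: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> bool:
    """True when *matrix* is orthonormal with determinant +1 within *tol*."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3) or not np.all(np.isfinite(matrix)):
        return False
    err = np.abs(matrix.T @ matrix - np.eye(3)).max()
    return err <= tol and abs(np.linalg.det(matrix) - 1.0) <= tol


def _frames_from_references(primary, secondary, order):
    """Vectorised frame construction; returns ``(R, valid)``.

    ``primary``/``secondary`` have shape (..., 3).  Invalid rows (zero or
    parallel references) yield NaN matrices and ``valid=False`` instead of
    raising, so per-frame tracking can mark gaps.
    """
    primary = np.asarray(primary, dtype=float)
    secondary = np.asarray(secondary, dtype=float)
    p_idx = _AXIS_INDEX[order[0].lower()]
    s_idx = _AXIS_INDEX[order[1].lower()]
    if p_idx == s_idx:
        raise ValueError("primary and secondary axis tags must differ")
    t_idx = 3 - p_idx - s_idx

    n1 = np.linalg.norm(primary, axis=-1, keepdims=True)
    n2 = np.linalg.norm(secondary, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u1 = primary / n1
        # remove the component of secondary along u1 (Gram-Schmidt)
        proj = np.sum(secondary * u1, axis=-1, keepdims=True)
        resid = secondary - proj * u1
        nr = np.linalg.norm(resid, axis=-1, keepdims=True)
        u2 = resid / nr
        # sin(angle between references); small => (anti)parallel
        sin_angle = nr[..., 0] / np.where(n2[..., 0] > 0, n2[..., 0], np.nan)

    valid = (
        np.isfinite(primary).all(axis=-1)
        & np.isfinite(secondary).all(axis=-1)
        & (n1[..., 0] > 0)
        & (n2[..., 0] > 0)
        & (sin_angle > PARALLEL_TOL_RAD)
    )

    R = np.full(primary.shape[:-1] + (3, 3), np.nan)
    R[..., :, p_idx] = u1
    R[..., :, s_idx] = u2
    # complete the right-handed triad: col_t = col_{t+1} x col_{t+2} (cyclic)
    a = R[..., :, (t_idx + 1) % 3]
    b = R[..., :, (t_idx + 2) % 3]
    R[..., :, t_idx] = np.cross(a, b)
    R[~valid] = np.nan
    return R, valid


def orthonormal_frame(primary, secondary, order=("z", "x")) -> np.ndarray:
    """Right-handed orthonormal frame from two reference directions.

    The axis named by ``order[0]`` is ``normalize(primary)`` exactly; the
    axis named by ``order[1]`` is *secondary* orthogonalised against it;
    the remaining axis completes the right-handed triad by cross product.
    Columns of the returned matrix are the frame axes expressed in the
    parent (laboratory) frame.

    Raises
    ------
    DegenerateGeometry
        If either reference is zero or the two are parallel within
        :data:`PARALLEL_TOL_RAD`.
    """
    R, valid = _frames_from_references(
        np.asarray(primary, float), np.asarray(secondary, float), order
    )
    if R.ndim != 2:
        raise ValueError("orthonormal_frame expects single 3-vectors; "
                         "use _frames_from_references for batches")
    if not valid:
        raise DegenerateGeometry(
            "reference vectors are zero, non-finite or parallel"
        )
    return R


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit *axis* by *angle_deg* degrees."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isfinite(n) or n == 0:
        raise DegenerateGeometry("rotation axis must be a non-zero vector")
    u = axis / n
    theta = np.deg2rad(angle_deg)
    K = np.array([
        [0.0, -u[2], u[1]],
        [u[2], 0.0, -u[0]],
        [-u[1], u[0], 0.0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)
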