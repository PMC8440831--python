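"""Rotation and rigid-transform helpers.

All orientations in this package follow a body-fixed (intrinsic) x-y-z Euler
sequence: R = Rx(a) @ Ry(b) @ Rz(c), angles in degrees at the API surface.
The x axis points mediolaterally, y inferosuperiorly and z posteroanteriorly,
so the three angles correspond to flexion-extension (FE), axial rotation (AR)
and lateroflexion (LF).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

#: intrinsic (body-fixed) x-y-z sequence, scipy notation
EULER_SEQ = "XYZ"

#: middle-angle magnitude (deg) beyond which Euler extraction is flagged
GIMBAL_WARN_DEG = 80.0


class GimbalWarning(UserWarning):
    """Middle Euler angle close to +/-90 deg; angles are ill-conditioned."""


def euler_to_matrix(euler_deg) -> np.ndarray:
    """3x3 rotation matrix from body-fixed xyz Euler angles (degrees)."""
    return Rotation.from_euler(EULER_SEQ, np.asarray(euler_deg, dtype=float),
                               degrees=True).as_matrix()


def matrix_to_euler(matrix) -> np.ndarray:
    """Body-fixed xyz Euler angles (degrees) from a rotation matrix.

    Warns when the middle (axial-rotation) angle approaches gimbal lock;
    physiological spine angles never get there.
    """
    ang = Rotation.from_matrix(np.asarray(matrix, dtype=float)).as_euler(
        EULER_SEQ, degrees=True)
    if np.any(np.abs(np.atleast_2d(ang)[:, 1]) > GIMBAL_WARN_DEG):
        warnings.warn(
            "middle Euler angle exceeds %.0f deg; xyz angles are near gimbal "
            "lock" % GIMBAL_WARN_DEG, GimbalWarning, stacklevel=2)
    return ang


def make_transform(position, euler_deg) -> np.ndarray:
    """Homogeneous 4x4 transform from position (mm) and xyz Euler (deg)."""
    T = np.eye(4)
    T[:3, :3] = euler_to_matrix(euler_deg)
    T[:3, 3] = np.asarray(position, dtype=float)
    return T


def rotation_part(T) -> np.ndarray:
    return np.asarray(T)[:3, :3]


def translation_part(T) -> np.ndarray:
    return np.asarray(T)[:3, 3]


def transform_inverse(T) -> np.ndarray:
    T = np.asarray(T)
    Ti = np.eye(4)
    R = T[:3, :3]
    Ti[:3, :3] = R.T
    Ti[:3, 3] = -R.T @ T[:3, 3]
    return Ti


def apply_transform(T, points) -> np.ndarray:
    """Apply a 4x4 transform to one point or an (..., 3) array of points."""
    p = np.asarray(points, dtype=float)
    return p @ np.asarray(T)[:3, :3].T + np.asarray(T)[:3, 3]


def mean_rotation(matrices) -> np.ndarray:
    """Chordal L2 mean of rotations (quaternion largest-eigenvector method).

    Unique and order-independent for the small dispersions (a few degrees)
    produced by operator variability; delegates to scipy's Rotation.mean,
    which implements exactly this estimator with hemisphere alignment.
    """
    return Rotation.from_matrix(np.asarray(matrices, dtype=float)).mean().as_matrix()


def relative_euler(R_ref, R) -> np.ndarray:
    """Body-fixed xyz Euler angles (deg) of the rotation taking R_ref to R."""
    return matrix_to_euler(np.asarray(R_ref).T @ np.asarray(R))
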