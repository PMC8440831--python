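"""Marker trajectories -> joint kinematics -> spino-pelvic parameters.

The processing chain mirrors standard motion-lab practice: zero-phase
low-pass Butterworth filtering of the raw marker trajectories, weighted
least-squares inverse kinematics of the 57-DOF chain per frame, time
normalization of the joint-angle series to 100 frames, a three-frame moving
average, conversion of joint to body kinematics, and extraction of the six
sagittal spino-pelvic parameters (LL, TK, SVA, PT, T1-SPI, T9-SPI) with
their ranges of motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .model import (
    N_BODIES,
    N_JOINTS,
    N_MARKERS,
    SpineModel,
    alignment_offsets,
    forward_kinematics,
    joint_angle_labels,
    landmark_positions,
)
from .rotations import euler_to_matrix

BASE_LABELS = ["base_tx", "base_ty", "base_tz", "base_rx", "base_ry", "base_rz"]

SPINO_PELVIC_CHANNELS = ["LL", "TK", "SVA", "PT", "T1_SPI", "T9_SPI"]
SPINO_PELVIC_UNITS = {"LL": "deg", "TK": "deg", "SVA": "cm", "PT": "deg",
                      "T1_SPI": "deg", "T9_SPI": "deg"}


class IKConvergenceError(RuntimeError):
    """Too many frames failed to converge within the iteration cap."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MotionTrial:
    """3D marker trajectories of one recorded motion.

    positions: (n_frames, n_markers, 3) in mm; mask True where a sample is
    valid (blank TRC cells are masked out).
    """

    marker_names: list
    positions: np.ndarray
    rate: float
    mask: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.marker_names):
            raise ValueError("marker_names / positions mismatch")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.n_frames < 2:
            raise ValueError("trial needs at least 2 frames")
        if self.mask is None:
            self.mask = np.isfinite(self.positions).all(axis=2)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


@dataclass
class JointKinematicsSeries:
    """51 intervertebral joint angles + 6 base DOFs over frames.

    angles: (n, 51) deg; base: (n, 6) mm/deg; time in seconds for raw series
    or percent of motion (0..100, exactly 100 frames) when normalized.
    """

    angles: np.ndarray
    base: np.ndarray
    time: np.ndarray
    residual_rms: np.ndarray = None
    normalized: bool = False
    channel_names: list = field(default_factory=joint_angle_labels)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.base = np.asarray(self.base, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.angles.shape[1] != 3 * N_JOINTS:
            raise ValueError("expected 51 joint-angle channels")
        if self.base.shape != (self.angles.shape[0], 6):
            raise ValueError("base must be (n, 6)")
        if self.residual_rms is None:
            self.residual_rms = np.full(self.angles.shape[0], np.nan)
        if self.normalized and self.angles.shape[0] != 100:
            raise ValueError("normalized series must have exactly 100 frames")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.hstack([self.base, self.angles]),
            columns=BASE_LABELS + list(self.channel_names))
        df.insert(0, "time", self.time)
        return df


@dataclass
class SpinoPelvicSeries:
    """The six sagittal spino-pelvic parameters over frames.

    LL, TK, PT, T1_SPI, T9_SPI in degrees; SVA in cm.
    """

    data: pd.DataFrame
    time: np.ndarray

    def __post_init__(self):
        missing = [c for c in SPINO_PELVIC_CHANNELS if c not in self.data]
        if missing:
            raise ValueError(f"missing channels {missing}")

    def rom(self) -> pd.Series:
        """Per-channel range of motion: |end - start|."""
        return pd.Series({c: rom(self.data[c].to_numpy())
                          for c in SPINO_PELVIC_CHANNELS})


# ---------------------------------------------------------------------------
# filtering and resampling
# ---------------------------------------------------------------------------

def lowpass_filter(trial: MotionTrial, cutoff_hz: float = 6.0,
                   order: int = 4) -> MotionTrial:
    """Zero-phase low-pass Butterworth filter per marker per axis.

    A 4th-order design applied forward-backward (biomechanics convention);
    the two passes square the magnitude response.
    """
    if cutoff_hz >= trial.rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{trial.rate / 2} Hz")
    sos = signal.butter(order, cutoff_hz, fs=trial.rate, output="sos")
    flat = trial.positions.reshape(trial.n_frames, -1)
    padlen = min(3 * (2 * sos.shape[0] + 1), trial.n_frames - 1)
    out = signal.sosfiltfilt(sos, flat, axis=0, padlen=padlen)
    return MotionTrial(list(trial.marker_names),
                       out.reshape(trial.positions.shape), trial.rate,
                       trial.mask.copy())


def fill_gaps(trial: MotionTrial, max_gap: int = 5) -> MotionTrial:
    """Linear interpolation of missing samples up to ``max_gap`` frames."""
    pos = trial.positions.copy()
    mask = trial.mask.copy()
    t = np.arange(trial.n_frames)
    for m in range(pos.shape[1]):
        valid = mask[:, m]
        if valid.all():
            continue
        if valid.sum() < 2:
            raise ValueError(f"marker {trial.marker_names[m]} has fewer than "
                             "2 valid samples")
        gap_ok = True
        idx = np.where(~valid)[0]
        if idx.size:
            splits = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
            gap_ok = all(len(g) <= max_gap and 0 < g[0] and
                         g[-1] < trial.n_frames - 1 for g in splits)
        if not gap_ok:
            raise ValueError(
                f"marker {trial.marker_names[m]} has a gap longer than "
                f"{max_gap} frames or at the trial boundary")
        for ax in range(3):
            pos[~valid, m, ax] = np.interp(t[~valid], t[valid],
                                           pos[valid, m, ax])
        mask[:, m] = True
    return MotionTrial(list(trial.marker_names), pos, trial.rate, mask)


def time_normalize(values, time, n_frames: int = 100):
    """Linear resampling onto ``n_frames`` equally spaced points.

    Endpoints are preserved exactly, so ranges of motion are invariant.
    Returns (values_out, t_percent) with t_percent in [0, 100].
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    if time.size < 2:
        raise ValueError("need at least 2 input frames to time-normalize")
    tq = np.linspace(time[0], time[-1], n_frames)
    flat = values.reshape(time.size, -1)
    out = np.empty((n_frames, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(tq, time, flat[:, c])
    out[0], out[-1] = flat[0], flat[-1]  # exact endpoints
    return out.reshape((n_frames,) + values.shape[1:]), \
        np.linspace(0.0, 100.0, n_frames)


def normalize_series(series: JointKinematicsSeries,
                     n_frames: int = 100) -> JointKinematicsSeries:
    """Time-normalize a joint kinematics series to ``n_frames`` frames."""
    ang, tq = time_normalize(series.angles, series.time, n_frames)
    base, _ = time_normalize(series.base, series.time, n_frames)
    res, _ = time_normalize(series.residual_rms[:, None], series.time, n_frames)
    return JointKinematicsSeries(ang, base, tq, res[:, 0],
                                 normalized=(n_frames == 100),
                                 channel_names=list(series.channel_names))


def moving_average(values, width: int = 3):
    """Centered moving average; edge windows shrink to stay inside the data.

    Shrunken edge windows (rather than padding) avoid the endpoint bias that
    would corrupt start/end-defined ranges of motion.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError("width must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    flat = values.reshape(values.shape[0], -1)
    out = (pd.DataFrame(flat)
           .rolling(window=width, center=True, min_periods=1)
           .mean()
           .to_numpy())
    return out.reshape(values.shape)


def smooth_series(series: JointKinematicsSeries,
                  width: int = 3) -> JointKinematicsSeries:
    return JointKinematicsSeries(
        moving_average(series.angles, width),
        moving_average(series.base, width),
        series.time.copy(), series.residual_rms.copy(),
        normalized=series.normalized,
        channel_names=list(series.channel_names))


def rom(series_1d) -> float:
    """Range of motion: absolute start-to-end difference of a channel."""
    v = np.asarray(series_1d, dtype=float).reshape(-1)
    if v.size < 2:
        raise ValueError("need at least 2 frames")
    return float(abs(v[-1] - v[0]))


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

def _euler_xyz_batch(q):
    """(k, 3) radians -> (k, 3, 3) Rx@Ry@Rz, plus Rx and Rx@Ry factors."""
    a, b, c = q[:, 0], q[:, 1], q[:, 2]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    k = q.shape[0]
    Rx = np.zeros((k, 3, 3))
    Rx[:, 0, 0] = 1
    Rx[:, 1, 1], Rx[:, 1, 2] = ca, -sa
    Rx[:, 2, 1], Rx[:, 2, 2] = sa, ca
    Ry = np.zeros((k, 3, 3))
    Ry[:, 1, 1] = 1
    Ry[:, 0, 0], Ry[:, 0, 2] = cb, sb
    Ry[:, 2, 0], Ry[:, 2, 2] = -sb, cb
    Rz = np.zeros((k, 3, 3))
    Rz[:, 2, 2] = 1
    Rz[:, 0, 0], Rz[:, 0, 1] = cc, -sc
    Rz[:, 1, 0], Rz[:, 1, 1] = sc, cc
    Rxy = Rx @ Ry
    return Rxy @ Rz, Rx, Rxy


class _IKChain:
    """Precomputed constant transforms + fast FK/Jacobian for one model."""

    def __init__(self, model: SpineModel):
        from .rotations import make_transform
        self.joint_local = np.stack([
            make_transform(j.position, j.euler_xyz) for j in model.joints])
        self.child_offset = np.stack([
            make_transform(j.child_offset_position, j.child_offset_euler)
            for j in model.joints])
        self.marker_body = model.marker_body_indices()
        self.marker_local = model.marker_locals()
        # joint j affects markers on bodies with index >= j+1
        self.active = self.marker_body[None, :] >= \
            (np.arange(N_JOINTS)[:, None] + 1)

    def fk(self, q):
        """q: (57,) radians [tx ty tz rx ry rz | 17x3]. Returns markers,
        per-column axes/origins for the geometric Jacobian, body transforms.
        """
        t, eul = q[:3], q[3:6]
        qj = q[6:].reshape(N_JOINTS, 3)
        Rj, Rx, Rxy = _euler_xyz_batch(qj)
        Rb, Rbx, Rbxy = _euler_xyz_batch(eul[None])
        T = np.empty((N_BODIES, 4, 4))
        T[0] = np.eye(4)
        T[0][:3, :3] = Rb[0]
        T[0][:3, 3] = t
        A = np.empty((N_JOINTS, 4, 4))  # frame just before each joint rotation
        for i in range(N_JOINTS):
            A[i] = T[i] @ self.joint_local[i]
            Tq = np.eye(4)
            Tq[:3, :3] = Rj[i]
            T[i + 1] = A[i] @ Tq @ self.child_offset[i]
        markers = np.einsum("mij,mj->mi", T[self.marker_body, :3, :3],
                            self.marker_local) + T[self.marker_body, :3, 3]
        # rotation axes in ground: intrinsic xyz at each joint
        R_pre = A[:, :3, :3]
        ax1 = R_pre[:, :, 0]
        ax2 = (R_pre @ Rx)[:, :, 1]
        ax3 = (R_pre @ Rxy)[:, :, 2]
        base_axes = np.stack([np.array([1.0, 0.0, 0.0]),
                              Rbx[0] @ np.array([0.0, 1.0, 0.0]),
                              Rbxy[0] @ np.array([0.0, 0.0, 1.0])])
        return markers, T, A[:, :3, 3], np.stack([ax1, ax2, ax3], axis=1), \
            base_axes, t

    def jacobian(self, markers, origins, axes, base_axes, base_origin):
        """(3*n_markers, 57) geometric Jacobian, mm per radian."""
        nm = markers.shape[0]
        J = np.zeros((nm, 3, 6 + 3 * N_JOINTS))
        J[:, 0, 0] = 1.0
        J[:, 1, 1] = 1.0
        J[:, 2, 2] = 1.0
        db = markers - base_origin
        for i in range(3):
            J[:, :, 3 + i] = np.cross(base_axes[i], db)
        diff = markers[None, :, :] - origins[:, None, :]     # (17, m, 3)
        for i in range(3):
            cols = np.cross(axes[:, i, None, :], diff)       # (17, m, 3)
            cols *= self.active[:, :, None]
            J[:, :, 6 + i::3] = np.moveaxis(cols, 0, 2)
        return J.reshape(3 * nm, -1)


def solve_ik(spine_model: SpineModel, trial: MotionTrial, weights=None,
             damping: float = 1e-6, prior_weight: float = 0.1,
             tol: float = 1e-8, max_iter: int = 200,
             max_flagged_frac: float = 0.05) -> JointKinematicsSeries:
    """Weighted least-squares inverse kinematics, frame by frame.

    Per frame, minimizes sum_i w_i ||x_i_obs - x_i_model(q)||^2 over the 57
    generalized coordinates with a damped (Levenberg-style) Gauss-Newton
    iteration. Frame 0 starts from the static model pose; later frames are
    warm-started from the previous solution. A soft quadratic prior of
    weight ``prior_weight`` (mm^2 per rad^2, scaled by the mean marker
    weight) toward the warm start anchors rotation directions the marker
    set observes weakly or not at all -- single-marker axial rotations and
    multi-joint trade-off combinations that move no marker. Its pull on
    well-observed DOFs is ~prior_weight / (marker leverage)^2 of the
    inter-frame step, i.e. parts in 10^4. Angles are returned in degrees
    with per-frame residual RMS in mm.
    """
    if list(trial.marker_names) != spine_model.marker_names:
        raise ValueError("trial marker names do not match the model")
    if weights is None:
        w = np.ones(N_MARKERS)
    else:
        w = np.asarray([weights[m] for m in trial.marker_names]
                       if isinstance(weights, dict) else weights, dtype=float)
        if w.shape != (N_MARKERS,) or (w < 0).any() or not (w > 0).any():
            raise ValueError("need a nonnegative weight per marker, not all 0")

    chain = _IKChain(spine_model)
    n = trial.n_frames
    q = np.zeros(6 + 3 * N_JOINTS)
    q[:3] = spine_model.static_base_pose[:3]
    q[3:6] = np.deg2rad(spine_model.static_base_pose[3:])
    angles = np.empty((n, 3 * N_JOINTS))
    base = np.empty((n, 6))
    residual = np.empty(n)
    flagged = 0

    for f in range(n):
        obs = trial.positions[f]
        valid = trial.mask[f]
        if not valid.any():
            raise ValueError(f"frame {f} has no valid markers")
        wf = np.where(valid, w, 0.0)
        w3 = np.repeat(wf, 3)
        # damping and prior scale with the mean marker weight, so rescaling
        # all weights rescales the whole objective (and every Levenberg
        # iterate with it): the minimizer and the path are scale invariant
        lam0 = damping * float(wf.mean())
        lam = lam0
        mu = prior_weight * float(wf.mean())
        q_ref = q.copy()                 # warm start anchors weak DOFs
        markers, T, origins, axes, base_axes, base_origin = chain.fk(q)
        r = np.where(valid[:, None], obs - markers, 0.0).reshape(-1)
        cost = float(r @ (w3 * r)) + mu * float((q - q_ref) @ (q - q_ref))
        converged = False
        for _ in range(max_iter):
            J = chain.jacobian(markers, origins, axes, base_axes, base_origin)
            JtW = J.T * w3
            H = JtW @ J
            H[np.diag_indices_from(H)] += lam + mu
            g = JtW @ r + mu * (q_ref - q)
            step = np.linalg.solve(H, g)
            q_new = q + step
            markers2, T2, o2, a2, b2, t2 = chain.fk(q_new)
            r2 = np.where(valid[:, None], obs - markers2, 0.0).reshape(-1)
            dq2 = q_new - q_ref
            cost2 = float(r2 @ (w3 * r2)) + mu * float(dq2 @ dq2)
            if cost2 > cost:           # overshoot: damp harder, retry
                lam *= 10.0
                if lam > 1e8:
                    converged = True   # no descent left at any damping
                    break
                continue
            lam = max(lam0, lam / 2.0)
            q = q_new
            markers, T, origins, axes, base_axes, base_origin = \
                markers2, T2, o2, a2, b2, t2
            r = r2
            improved = cost - cost2
            cost = cost2
            if (improved <= tol * max(cost, 1e-12) and
                    np.abs(step).max() < 1e-7) or np.abs(step).max() < 1e-12:
                converged = True
                break
        if not converged:
            flagged += 1
        angles[f] = np.rad2deg(q[6:])
        base[f, :3] = q[:3]
        base[f, 3:] = np.rad2deg(q[3:6])
        nv = max(int(valid.sum()), 1)
        residual[f] = math.sqrt(
            float(np.sum((r.reshape(-1, 3)[valid]) ** 2)) / nv)

    if flagged > max_flagged_frac * n:
        raise IKConvergenceError(
            f"{flagged}/{n} frames failed to converge within {max_iter} "
            "iterations")
    return JointKinematicsSeries(angles, base, trial.times.copy(), residual)


# ---------------------------------------------------------------------------
# body kinematics and spino-pelvic parameters
# ---------------------------------------------------------------------------

def joint_to_body_kinematics(spine_model: SpineModel,
                             series: JointKinematicsSeries) -> np.ndarray:
    """Absolute body poses in ground per frame, (n, 18, 4, 4).

    Serial composition of the base pose and joint rotations; equals
    forward kinematics frame by frame.
    """
    n = series.n_frames
    out = np.empty((n, N_BODIES, 4, 4))
    for f in range(n):
        T, _ = forward_kinematics(spine_model, series.base[f],
                                  series.angles[f])
        out[f] = T
    return out


def _sagittal_inclination(v):
    """Angle (deg) of vector(s) from the vertical +y axis in the sagittal
    (y-z) plane; positive toward anterior (+z). v: (..., 3)."""
    v = np.asarray(v, dtype=float)
    return np.degrees(np.arctan2(v[..., 2], v[..., 1]))


def compute_spino_pelvic(spine_model: SpineModel, body_transforms,
                         time=None) -> SpinoPelvicSeries:
    """The six sagittal spino-pelvic parameters from body kinematics.

    Landmark-based definitions (standard literature conventions; signs are
    package conventions and cancel in ranges of motion):

    - LL: sagittal angle between the sacral plate and the superior endplate
      of L1 (plate normals), positive lordosis.
    - TK: sagittal angle between the superior endplate of T1 and the
      inferior endplate of T12, positive kyphosis.
    - SVA: anteroposterior (z) offset of the T1 body centre from the
      posterior-superior sacral endplate corner, in cm, anterior positive.
    - PT: inclination from vertical of the line from the bicoxofemoral
      midpoint to the sacral plate centre, posterior tilt positive.
    - T1-SPI / T9-SPI: inclination from vertical of the line from the
      bicoxofemoral midpoint to the T1 / T9 body centre, anterior positive.
    """
    Tb = np.asarray(body_transforms)
    if Tb.ndim == 3:
        Tb = Tb[None]
    lm = landmark_positions(spine_model, Tb,
                            offsets=alignment_offsets(spine_model))
    pelvis = lm["pelvis"]
    hip_mid = 0.5 * (pelvis["hip_center_l"] + pelvis["hip_center_r"])

    def plate_normal(body, which):
        return lm[body][f"{which}_normal_tip"] - lm[body][f"{which}_center"]

    sacral_n = pelvis["sacral_plate_normal_tip"] - pelvis["sacral_plate_center"]
    ll = _sagittal_inclination(sacral_n) - \
        _sagittal_inclination(plate_normal("L1", "sup"))
    tk = _sagittal_inclination(plate_normal("T1", "sup")) - \
        _sagittal_inclination(-plate_normal("T12", "inf"))
    sva = (lm["T1"]["body_center"][..., 2] -
           pelvis["sacral_corner_ps"][..., 2]) / 10.0  # mm -> cm
    v_pt = pelvis["sacral_plate_center"] - hip_mid
    pt = np.degrees(np.arctan2(-v_pt[..., 2], v_pt[..., 1]))
    t1 = _sagittal_inclination(lm["T1"]["body_center"] - hip_mid)
    t9 = _sagittal_inclination(lm["T9"]["body_center"] - hip_mid)

    data = pd.DataFrame({"LL": ll, "TK": tk, "SVA": sva, "PT": pt,
                         "T1_SPI": t1, "T9_SPI": t9})
    if time is None:
        time = np.arange(Tb.shape[0], dtype=float)
    return SpinoPelvicSeries(data, np.asarray(time, dtype=float))


def spino_pelvic_from_series(spine_model: SpineModel,
                             series: JointKinematicsSeries) -> SpinoPelvicSeries:
    """Convenience: joint kinematics -> body kinematics -> parameters."""
    return compute_spino_pelvic(
        spine_model, joint_to_body_kinematics(spine_model, series),
        time=series.time)
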