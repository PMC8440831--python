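"""Subject-specific spino-pelvic rigid-body model.

The model is a single serial chain of 18 bodies (pelvis/sacrum, L5..L1,
T12..T1) connected by 17 spherical joints (L5_S1 up to T1_T2), carrying 28
virtual markers and the anatomical landmarks needed for the sagittal
spino-pelvic parameters. A free 6-DOF base joint connects the pelvis to the
ground; its coordinates are solved by inverse kinematics but excluded from
the 51 reported joint angles.

Three groups of model inputs are operator-dependent and form a fixed-layout
294-entry parameter vector: marker positions (28 x 3, expressed in the
attached body's frame), body alignment position + orientation (18 x 6) and
joint position + orientation in the parent frame (17 x 6).

Two poses are kept per segment: the immutable *chain* pose, i.e. the static
model-building pose realised by the joint chain at zero joint angles, and
the operator *alignment* pose. Landmark ground positions are mapped through
the relative transform between the two, so perturbing a body's alignment
re-poses its landmark geometry without touching joint frames or marker
locals, and therefore without any effect on marker-driven inverse
kinematics. Perturbing a joint, conversely, moves the rotation centre/axes
while a compensating update of the fixed child-side offset preserves the
static pose, so joint perturbations act purely on the kinematics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .rotations import (
    euler_to_matrix,
    make_transform,
    matrix_to_euler,
    mean_rotation,
    relative_euler,
    transform_inverse,
)

# chain order, caudal -> cranial
BODY_NAMES = ["pelvis", "L5", "L4", "L3", "L2", "L1",
              "T12", "T11", "T10", "T9", "T8", "T7",
              "T6", "T5", "T4", "T3", "T2", "T1"]

# joint i connects BODY_NAMES[i] (parent, caudal) to BODY_NAMES[i+1] (child)
JOINT_NAMES = ["L5_S1", "L4_L5", "L3_L4", "L2_L3", "L1_L2", "T12_L1",
               "T11_T12", "T10_T11", "T9_T10", "T8_T9", "T7_T8", "T6_T7",
               "T5_T6", "T4_T5", "T3_T4", "T2_T3", "T1_T2"]

DOF_LABELS = ("FE", "AR", "LF")

N_BODIES = 18
N_JOINTS = 17
N_MARKERS = 28
N_PARAMETERS = N_MARKERS * 3 + N_BODIES * 6 + N_JOINTS * 6  # 294

VERTEBRA_LANDMARKS = ("body_center", "sup_center", "sup_normal_tip",
                      "inf_center", "inf_normal_tip")
PELVIS_LANDMARKS = ("body_center", "sacral_plate_center",
                    "sacral_plate_normal_tip", "sacral_corner_ps",
                    "hip_center_l", "hip_center_r")


class ModelStructureError(ValueError):
    """Model topology, naming or landmark set violates the model contract."""


def _vec3(x, name):
    a = np.asarray(x, dtype=float).reshape(-1)
    if a.shape != (3,):
        raise ModelStructureError(f"{name} must be a 3-vector, got {a.shape}")
    return a


@dataclass
class BodySegment:
    """One rigid body of the chain.

    ``position``/``euler_xyz`` is the operator-dependent alignment pose in
    the ground frame (mm / deg); landmarks are fixed points in the body's
    chain frame (mm).
    """

    name: str
    position: np.ndarray
    euler_xyz: np.ndarray
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position = _vec3(self.position, f"{self.name}.position")
        self.euler_xyz = _vec3(self.euler_xyz, f"{self.name}.euler_xyz")
        self.landmarks = {k: _vec3(v, f"{self.name}.landmarks[{k}]")
                          for k, v in self.landmarks.items()}


@dataclass
class SphericalJoint:
    """3-DOF rotational joint between two adjacent bodies.

    ``position``/``euler_xyz`` locate the joint frame in the parent body's
    chain frame (operator-dependent). ``child_offset_*`` is the fixed pose of
    the child body frame in the joint frame at zero joint angles; it is
    derived at model construction and compensated when the joint frame is
    perturbed so the static pose stays put.
    """

    name: str
    parent: str
    child: str
    position: np.ndarray
    euler_xyz: np.ndarray
    child_offset_position: np.ndarray
    child_offset_euler: np.ndarray

    def __post_init__(self):
        self.position = _vec3(self.position, f"{self.name}.position")
        self.euler_xyz = _vec3(self.euler_xyz, f"{self.name}.euler_xyz")
        self.child_offset_position = _vec3(
            self.child_offset_position, f"{self.name}.child_offset_position")
        self.child_offset_euler = _vec3(
            self.child_offset_euler, f"{self.name}.child_offset_euler")


@dataclass
class VirtualMarker:
    """Virtual model marker: a named point fixed in a body's chain frame."""

    name: str
    body: str
    position: np.ndarray

    def __post_init__(self):
        self.position = _vec3(self.position, f"marker {self.name}.position")


@dataclass
class SpineModel:
    segments: list
    joints: list
    markers: list
    static_base_pose: np.ndarray  # 6: pelvis-in-ground model-building pose

    def __post_init__(self):
        self.static_base_pose = np.asarray(
            self.static_base_pose, dtype=float).reshape(-1)
        if self.static_base_pose.shape != (6,):
            raise ModelStructureError("static_base_pose must have 6 entries")
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self):
        names = [s.name for s in self.segments]
        if names != BODY_NAMES:
            raise ModelStructureError(
                f"expected {N_BODIES} bodies in chain order {BODY_NAMES}, "
                f"got {names}")
        jnames = [j.name for j in self.joints]
        if jnames != JOINT_NAMES:
            raise ModelStructureError(
                f"expected {N_JOINTS} joints in chain order, got {jnames}")
        for i, j in enumerate(self.joints):
            if j.parent != BODY_NAMES[i] or j.child != BODY_NAMES[i + 1]:
                raise ModelStructureError(
                    f"joint {j.name} must connect {BODY_NAMES[i]} -> "
                    f"{BODY_NAMES[i + 1]}, got {j.parent} -> {j.child}")
        if len(self.markers) != N_MARKERS:
            raise ModelStructureError(
                f"expected {N_MARKERS} markers, got {len(self.markers)}")
        mnames = [m.name for m in self.markers]
        if len(set(mnames)) != N_MARKERS:
            raise ModelStructureError("marker names must be unique")
        body_set = set(names)
        for m in self.markers:
            if m.body not in body_set:
                raise ModelStructureError(
                    f"marker {m.name} attached to unknown body {m.body}")
        for s in self.segments:
            required = PELVIS_LANDMARKS if s.name == "pelvis" else VERTEBRA_LANDMARKS
            missing = [k for k in required if k not in s.landmarks]
            if missing:
                raise ModelStructureError(
                    f"body {s.name} missing landmarks {missing}")

    # -- convenience -------------------------------------------------------
    @property
    def marker_names(self):
        return [m.name for m in self.markers]

    def segment(self, name) -> BodySegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise ModelStructureError(f"unknown body {name}")

    def joint(self, name) -> SphericalJoint:
        for j in self.joints:
            if j.name == name:
                return j
        raise ModelStructureError(f"unknown joint {name}")

    def marker_body_indices(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(BODY_NAMES)}
        return np.array([idx[m.body] for m in self.markers])

    def marker_locals(self) -> np.ndarray:
        return np.array([m.position for m in self.markers])

    def copy(self) -> "SpineModel":
        return copy.deepcopy(self)


def joint_angle_labels() -> list:
    """The 51 joint-angle channel names, chain order x (FE, AR, LF)."""
    return [f"{j}_{d}" for j in JOINT_NAMES for d in DOF_LABELS]


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def forward_kinematics(model: SpineModel, base_pose, joint_angles):
    """Pose every body and marker for one set of generalized coordinates.

    Parameters
    ----------
    base_pose : (6,) pelvis pose in ground, [tx, ty, tz (mm), rx, ry, rz (deg)]
    joint_angles : (51,) FE/AR/LF per joint in chain order, degrees

    Returns
    -------
    body_transforms : (18, 4, 4) ground pose of each body's chain frame
    marker_positions : (28, 3) marker ground positions, mm
    """
    base_pose = np.asarray(base_pose, dtype=float).reshape(-1)
    q = np.asarray(joint_angles, dtype=float).reshape(-1)
    if base_pose.shape != (6,):
        raise ValueError("base_pose must have 6 entries")
    if q.shape != (3 * N_JOINTS,):
        raise ValueError(f"joint_angles must have {3 * N_JOINTS} entries")

    T = np.empty((N_BODIES, 4, 4))
    T[0] = make_transform(base_pose[:3], base_pose[3:])
    for i, joint in enumerate(model.joints):
        A = T[i] @ make_transform(joint.position, joint.euler_xyz)
        Rq = np.eye(4)
        Rq[:3, :3] = euler_to_matrix(q[3 * i:3 * i + 3])
        T[i + 1] = A @ Rq @ make_transform(joint.child_offset_position,
                                           joint.child_offset_euler)

    bidx = model.marker_body_indices()
    locals_ = model.marker_locals()
    markers = np.einsum("mij,mj->mi", T[bidx, :3, :3], locals_) + T[bidx, :3, 3]
    return T, markers


def chain_static_transforms(model: SpineModel) -> np.ndarray:
    """Ground pose of every chain frame in the static model-building pose."""
    T, _ = forward_kinematics(model, model.static_base_pose,
                              np.zeros(3 * N_JOINTS))
    return T


def alignment_offsets(model: SpineModel) -> np.ndarray:
    """Per-body transform from chain frame to alignment frame (18, 4, 4).

    Identity for an unperturbed model; after a body-alignment perturbation it
    carries the landmark re-posing required by the isolation contract.
    """
    chain = chain_static_transforms(model)
    D = np.empty((N_BODIES, 4, 4))
    for i, s in enumerate(model.segments):
        align = make_transform(s.position, s.euler_xyz)
        D[i] = transform_inverse(chain[i]) @ align
    return D


def landmark_positions(model: SpineModel, body_transforms,
                       offsets=None) -> dict:
    """Ground positions of every landmark, given body chain poses.

    ``body_transforms`` may be (18, 4, 4) for one frame or (n, 18, 4, 4).
    Returns {body_name: {landmark_name: (3,) or (n, 3)}}.
    """
    if offsets is None:
        offsets = alignment_offsets(model)
    Tb = np.asarray(body_transforms)
    single = Tb.ndim == 3
    if single:
        Tb = Tb[None]
    out = {}
    for i, s in enumerate(model.segments):
        eff = Tb[:, i] @ offsets[i]  # (n, 4, 4)
        body_out = {}
        for k, p in s.landmarks.items():
            g = eff[:, :3, :3] @ p + eff[:, :3, 3]
            body_out[k] = g[0] if single else g
        out[s.name] = body_out
    return out


# ---------------------------------------------------------------------------
# parameter vector
# ---------------------------------------------------------------------------

@dataclass
class ParameterVector:
    """The 294 operator-dependent parameters as signed deviations.

    Fixed block layout: marker positions (28 x 3, mm), body positions
    (18 x 3, mm), body orientations (18 x 3, deg), joint positions
    (17 x 3, mm), joint orientations (17 x 3, deg); each entry tagged by
    component (marker/body/joint), parameter (position/orientation) and
    direction (x/y/z).
    """

    values: np.ndarray
    marker_names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.shape != (N_PARAMETERS,):
            raise ValueError(
                f"parameter vector must have {N_PARAMETERS} entries")
        if len(self.marker_names) != N_MARKERS:
            raise ValueError(f"need {N_MARKERS} marker names")

    @staticmethod
    def layout(marker_names) -> "pd.DataFrame":
        """Tag table (component, parameter, direction, element) per entry."""
        import pandas as pd
        rows = []
        for m in marker_names:
            for d in "xyz":
                rows.append(("marker", "position", d, m))
        for p in ("position", "orientation"):
            for b in BODY_NAMES:
                for d in "xyz":
                    rows.append(("body", p, d, b))
        for p in ("position", "orientation"):
            for j in JOINT_NAMES:
                for d in "xyz":
                    rows.append(("joint", p, d, j))
        return pd.DataFrame(
            rows, columns=["component", "parameter", "direction", "element"])

    def to_frame(self):
        df = self.layout(self.marker_names)
        df["value"] = self.values
        return df

    # block views -----------------------------------------------------------
    @property
    def marker_deltas(self) -> np.ndarray:     # (28, 3) mm
        return self.values[:84].reshape(N_MARKERS, 3)

    @property
    def body_position_deltas(self) -> np.ndarray:   # (18, 3) mm, ground frame
        return self.values[84:138].reshape(N_BODIES, 3)

    @property
    def body_orientation_deltas(self) -> np.ndarray:  # (18, 3) deg, body-fixed
        return self.values[138:192].reshape(N_BODIES, 3)

    @property
    def joint_position_deltas(self) -> np.ndarray:  # (17, 3) mm, parent frame
        return self.values[192:243].reshape(N_JOINTS, 3)

    @property
    def joint_orientation_deltas(self) -> np.ndarray:  # (17, 3) deg
        return self.values[243:294].reshape(N_JOINTS, 3)

    @staticmethod
    def from_blocks(marker_names, marker, body_pos, body_ori,
                    joint_pos, joint_ori) -> "ParameterVector":
        v = np.concatenate([np.asarray(b, dtype=float).reshape(-1)
                            for b in (marker, body_pos, body_ori,
                                      joint_pos, joint_ori)])
        return ParameterVector(v, list(marker_names))


def _check_topology(a: SpineModel, b: SpineModel):
    if a.marker_names != b.marker_names:
        raise ModelStructureError("marker sets differ between models")
    if [m.body for m in a.markers] != [m.body for m in b.markers]:
        raise ModelStructureError("marker attachments differ between models")


def model_to_vector(model: SpineModel, reference: SpineModel) -> ParameterVector:
    """Signed deviations of ``model`` from ``reference``.

    Positions in mm (markers in the attached body frame, bodies in ground,
    joints in the parent frame); orientations as body-fixed xyz Euler angles
    of the relative rotation, degrees.
    """
    _check_topology(model, reference)
    marker = model.marker_locals() - reference.marker_locals()
    body_pos = np.empty((N_BODIES, 3))
    body_ori = np.empty((N_BODIES, 3))
    for i in range(N_BODIES):
        s, r = model.segments[i], reference.segments[i]
        body_pos[i] = s.position - r.position
        body_ori[i] = relative_euler(euler_to_matrix(r.euler_xyz),
                                     euler_to_matrix(s.euler_xyz))
    joint_pos = np.empty((N_JOINTS, 3))
    joint_ori = np.empty((N_JOINTS, 3))
    for i in range(N_JOINTS):
        j, r = model.joints[i], reference.joints[i]
        joint_pos[i] = j.position - r.position
        joint_ori[i] = relative_euler(euler_to_matrix(r.euler_xyz),
                                      euler_to_matrix(j.euler_xyz))
    return ParameterVector.from_blocks(model.marker_names, marker, body_pos,
                                       body_ori, joint_pos, joint_ori)


def apply_perturbation(model: SpineModel, delta: ParameterVector) -> SpineModel:
    """Return a new model with the 294 parameter deltas imposed.

    Marker deltas displace marker locals in the attached body frame; body
    deltas move the alignment pose (landmark geometry only); joint deltas
    move the joint frame in the parent while the child-side offset is
    compensated so the static pose is preserved.
    """
    if delta.marker_names != model.marker_names:
        raise ModelStructureError("parameter vector layout does not match model")
    out = model.copy()
    md = delta.marker_deltas
    for i, m in enumerate(out.markers):
        m.position = m.position + md[i]
    bp, bo = delta.body_position_deltas, delta.body_orientation_deltas
    for i, s in enumerate(out.segments):
        s.position = s.position + bp[i]
        if bo[i].any():     # zero delta stays bit-exact
            s.euler_xyz = matrix_to_euler(
                euler_to_matrix(s.euler_xyz) @ euler_to_matrix(bo[i]))
    jp, jo = delta.joint_position_deltas, delta.joint_orientation_deltas
    for i, j in enumerate(out.joints):
        if not jp[i].any() and not jo[i].any():
            continue
        T_old = make_transform(j.position, j.euler_xyz)
        j.position = j.position + jp[i]
        if jo[i].any():
            j.euler_xyz = matrix_to_euler(
                euler_to_matrix(j.euler_xyz) @ euler_to_matrix(jo[i]))
        T_new = make_transform(j.position, j.euler_xyz)
        T_off = make_transform(j.child_offset_position, j.child_offset_euler)
        T_off = transform_inverse(T_new) @ T_old @ T_off
        j.child_offset_position = T_off[:3, 3].copy()
        j.child_offset_euler = matrix_to_euler(T_off[:3, :3])
    return out


def average_models(models) -> SpineModel:
    """Baseline model: arithmetic mean of positions, chordal mean of rotations.

    The inputs must be operator variants of one subject (identical topology
    and shared model-building chain pose, as produced by
    :func:`apply_perturbation`). Joint child-side offsets of the average are
    re-derived from the shared chain pose so the averaged joint frames stay
    kinematically consistent with it.
    """
    models = list(models)
    if len(models) < 2:
        raise ModelStructureError("need at least 2 models to average")
    ref = models[0]
    for m in models[1:]:
        _check_topology(ref, m)
    chain = chain_static_transforms(ref)
    for m in models[1:]:
        if not np.allclose(chain_static_transforms(m), chain, atol=1e-6):
            raise ModelStructureError(
                "models do not share a model-building chain pose; cannot "
                "average")

    out = ref.copy()
    for i, s in enumerate(out.segments):
        s.position = np.mean([m.segments[i].position for m in models], axis=0)
        s.euler_xyz = matrix_to_euler(mean_rotation(
            [euler_to_matrix(m.segments[i].euler_xyz) for m in models]))
        s.landmarks = {k: np.mean([m.segments[i].landmarks[k] for m in models],
                                  axis=0)
                       for k in s.landmarks}
    for i, mk in enumerate(out.markers):
        mk.position = np.mean([m.markers[i].position for m in models], axis=0)
    for i, j in enumerate(out.joints):
        j.position = np.mean([m.joints[i].position for m in models], axis=0)
        j.euler_xyz = matrix_to_euler(mean_rotation(
            [euler_to_matrix(m.joints[i].euler_xyz) for m in models]))
        # re-derive the fixed child offset from the shared chain pose
        T_joint = chain[i] @ make_transform(j.position, j.euler_xyz)
        T_off = transform_inverse(T_joint) @ chain[i + 1]
        j.child_offset_position = T_off[:3, 3].copy()
        j.child_offset_euler = matrix_to_euler(T_off[:3, :3])
    out.static_base_pose = np.mean([m.static_base_pose for m in models], axis=0)
    return out
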