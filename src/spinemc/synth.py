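"""Synthetic subjects, motions, operator variants and retest sessions.

The generator emulates the study conditions the analysis assumes: an
adult-spinal-deformity-like static geometry with prescribed lumbar lordosis
and thoracic kyphosis, a seated maximal forward trunk flexion recorded as
28 marker trajectories at 100 Hz, operator variants of a model whose
deviation magnitudes match the reported inter-operator variability, and
test-retest session pairs with execution jitter. Every generator takes an
explicit integer seed and is fully deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    BODY_NAMES,
    JOINT_NAMES,
    N_JOINTS,
    BodySegment,
    ParameterVector,
    SphericalJoint,
    SpineModel,
    VirtualMarker,
    apply_perturbation,
    forward_kinematics,
    make_transform,
)
from .pipeline import JointKinematicsSeries, MotionTrial
from .rotations import euler_to_matrix, transform_inverse

VERTEBRAE = BODY_NAMES[1:]          # L5..T1, caudal -> cranial
LUMBAR = VERTEBRAE[:5]
THORACIC = VERTEBRAE[5:]

#: vertebrae carrying an off-midline paraspinal marker (7, alternating sides)
PARASPINAL_LEVELS = ["T12", "T10", "T8", "T6", "T4", "T2", "T1"]


class GeometryError(ValueError):
    """Requested geometry is infeasible (e.g. negative spacing)."""


@dataclass
class GeometryParams:
    """Static spino-pelvic geometry of a synthetic subject.

    Angles in degrees, lengths in mm. ``deformity_severity`` scales the
    coronal offsets and axial/lateral rotations of the vertebrae (0 gives a
    perfectly sagittally symmetric spine).
    """

    lumbar_lordosis: float = 40.0
    thoracic_kyphosis: float = 30.0
    sacral_slope: float = 30.0
    lumbar_body_height: float = 28.0
    lumbar_disc_height: float = 10.0
    thoracic_body_height: float = 20.0
    thoracic_disc_height: float = 6.0
    hip_width: float = 170.0
    spinous_offset_lumbar: float = 50.0
    spinous_offset_thoracic: float = 42.0
    paraspinal_offset: float = 45.0
    deformity_severity: float = 0.3
    height_jitter: float = 0.03       # relative SD of per-level heights

    def validate(self):
        for name in ("lumbar_body_height", "lumbar_disc_height",
                     "thoracic_body_height", "thoracic_disc_height",
                     "hip_width"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.deformity_severity < 0:
            raise GeometryError("deformity_severity must be >= 0")


@dataclass
class OperatorVariabilitySpec:
    """Per component/parameter/direction spreads of zero-mean operator
    deviations (mm for positions, deg for orientations).

    Defaults are tuned so that, for three operators, the median absolute
    deviations of the variants from their average fall at the reported
    inter-operator magnitudes (markers ~0.11-0.12 mm, bodies ~0.55-0.74 mm
    and 0.96-1.68 deg, joints ~0.57-1.06 mm and 1.16-1.95 deg): for a
    zero-mean normal spread sigma, the deviation from a 3-model average has
    SD sigma*sqrt(2/3) and median |.| = 0.6745 of that.
    """

    marker_position_sd: tuple = (0.203, 0.218, 0.218)
    body_position_sd: tuple = (1.220, 1.002, 1.342)
    body_orientation_sd: tuple = (2.161, 3.051, 1.743)
    joint_position_sd: tuple = (1.420, 1.028, 1.921)
    joint_orientation_sd: tuple = (2.996, 3.541, 2.106)


@dataclass
class MotionSpec:
    """Seated maximal forward trunk flexion, sampled at ``rate`` Hz.

    The spinal flexion angle ramps smoothly (smoothstep) from the upright
    static pose to ``total_flexion`` degrees, distributed over the joints
    with lumbar-dominant level weights; the pelvis simultaneously tilts
    anteriorly by ``pelvis_tilt_rom``. Retest execution jitter rescales the
    amplitudes and level weights and offsets the start posture.
    """

    n_frames: int = 300
    rate: float = 100.0
    total_flexion: float = 45.0
    pelvis_tilt_rom: float = 50.0
    lumbar_weight: float = 1.0
    thoracic_weight: float = 0.3
    marker_noise_sd: float = 0.5
    jitter: bool = False
    amplitude_jitter: float = 0.10
    weight_jitter: float = 0.10
    start_offset_sd: float = 2.0

    def level_weights(self) -> np.ndarray:
        """Normalized flexion share per joint (chain order, 17 entries)."""
        w = np.array([self.lumbar_weight] * 6 + [self.thoracic_weight] * 11)
        return w / w.sum()


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


# ---------------------------------------------------------------------------
# model generation
# ---------------------------------------------------------------------------

def generate_spine_model(params: GeometryParams = None, seed: int = 0):
    """Build a synthetic subject-specific spino-pelvic model.

    Returns (model, record) where record holds the ground-truth geometry
    (inclination profile, centres, requested angles) for recovery tests.
    """
    params = params or GeometryParams()
    params.validate()
    rng = np.random.default_rng(seed)
    sev = params.deformity_severity

    heights = {}
    discs = {}
    for v in VERTEBRAE:
        lumbar = v in LUMBAR
        h = params.lumbar_body_height if lumbar else params.thoracic_body_height
        d = params.lumbar_disc_height if lumbar else params.thoracic_disc_height
        jit = 1.0 + params.height_jitter * rng.standard_normal()
        heights[v] = h * max(jit, 0.5)
        discs[v] = d * max(1.0 + params.height_jitter * rng.standard_normal(),
                           0.5)

    # sagittal inclination profile (deg, anterior positive)
    ss = params.sacral_slope
    theta = {}
    for k, v in enumerate(LUMBAR, start=1):          # L5..L1
        theta[v] = ss - params.lumbar_lordosis * k / 5.0
    t_l1 = theta["L1"]
    for k, v in enumerate(THORACIC):                 # T12..T1
        theta[v] = t_l1 + params.thoracic_kyphosis * k / 11.0

    # deformity: coronal offset + axial/lateral rotation, scaled by severity
    u = np.linspace(0.0, 1.0, len(VERTEBRAE) + 2)[1:-1]
    coronal = sev * 15.0 * np.sin(np.pi * u)
    axial = sev * 4.0 * np.sin(np.pi * u)
    lateral = sev * 3.0 * np.sin(2.0 * np.pi * u)

    # pelvis: ground-aligned frame with origin at the bicoxofemoral midpoint
    half_hip = params.hip_width / 2.0
    plate_c = np.array([0.0, 90.0, -30.0])
    n_plate = np.array([0.0, np.cos(np.radians(ss)), np.sin(np.radians(ss))])
    t_plate = np.array([0.0, -np.sin(np.radians(ss)), np.cos(np.radians(ss))])
    pelvis = BodySegment(
        "pelvis", np.zeros(3), np.zeros(3),
        landmarks={
            "body_center": np.array([0.0, 40.0, -20.0]),
            "sacral_plate_center": plate_c,
            "sacral_plate_normal_tip": plate_c + 10.0 * n_plate,
            "sacral_corner_ps": plate_c - 25.0 * t_plate,
            "hip_center_l": np.array([half_hip, 0.0, 0.0]),
            "hip_center_r": np.array([-half_hip, 0.0, 0.0]),
        })

    segments = [pelvis]
    centers = {}
    orientations = {}
    prev_top = plate_c
    prev_y = n_plate
    for i, v in enumerate(VERTEBRAE):
        eul = np.array([theta[v], axial[i], lateral[i]])
        R = euler_to_matrix(eul)
        y_axis = R[:, 1]
        half = heights[v] / 2.0
        gap = discs[v]
        y_mid = prev_y + y_axis
        y_mid = y_mid / np.linalg.norm(y_mid)
        c = prev_top + gap * y_mid + half * y_axis
        c = c + np.array([coronal[i], 0.0, 0.0])
        centers[v] = c
        orientations[v] = eul
        segments.append(BodySegment(
            v, c, eul,
            landmarks={
                "body_center": np.zeros(3),
                "sup_center": np.array([0.0, half, 0.0]),
                "sup_normal_tip": np.array([0.0, half + 10.0, 0.0]),
                "inf_center": np.array([0.0, -half, 0.0]),
                "inf_normal_tip": np.array([0.0, -half - 10.0, 0.0]),
            }))
        prev_top = c + half * y_axis
        prev_y = y_axis

    # joints at the disc midpoints, frame aligned with the caudal body
    joints = []
    for i, jname in enumerate(JOINT_NAMES):
        parent = segments[i]
        child = segments[i + 1]
        R_p = euler_to_matrix(parent.euler_xyz)
        R_c = euler_to_matrix(child.euler_xyz)
        if parent.name == "pelvis":
            p_sup = parent.landmarks["sacral_plate_center"]
        else:
            p_sup = parent.position + R_p @ parent.landmarks["sup_center"]
        c_inf = child.position + R_c @ child.landmarks["inf_center"]
        g = 0.5 * (p_sup + c_inf)
        pos_in_parent = R_p.T @ (g - parent.position)
        joints.append(SphericalJoint(jname, parent.name, child.name,
                                     pos_in_parent, np.zeros(3),
                                     np.zeros(3), np.zeros(3)))

    # markers: 4 pelvis + 17 spinous + 7 paraspinal = 28
    markers = [
        VirtualMarker("LASI", "pelvis", np.array([110.0, 20.0, 60.0])),
        VirtualMarker("RASI", "pelvis", np.array([-110.0, 20.0, 60.0])),
        VirtualMarker("LPSI", "pelvis", np.array([45.0, 60.0, -80.0])),
        VirtualMarker("RPSI", "pelvis", np.array([-45.0, 60.0, -80.0])),
    ]
    # spinous markers carry a small alternating lateral offset: with one
    # marker per level a purely midline column leaves alternating-sign
    # lateroflexion combinations of adjacent joints almost unobserved by
    # the IK; the off-axis component gives every level a lateral lever arm
    for i, v in enumerate(VERTEBRAE):
        depth = (params.spinous_offset_lumbar if v in LUMBAR
                 else params.spinous_offset_thoracic)
        depth += 2.0 * rng.standard_normal()
        side = 25.0 if i % 2 == 0 else -25.0
        markers.append(VirtualMarker(f"SP_{v}", v,
                                     np.array([side, 0.0, -abs(depth)])))
    for k, v in enumerate(PARASPINAL_LEVELS):
        side = 1.0 if k % 2 == 0 else -1.0
        markers.append(VirtualMarker(
            f"PS_{v}", v,
            np.array([side * params.paraspinal_offset, 0.0, -30.0])))

    mdl = SpineModel(segments, joints, markers, np.zeros(6))

    # solve the fixed child-side joint offsets from the static pose
    chain_target = np.empty((len(segments), 4, 4))
    for i, s in enumerate(segments):
        chain_target[i] = make_transform(s.position, s.euler_xyz)
    for i, j in enumerate(mdl.joints):
        T_joint = chain_target[i] @ make_transform(j.position, j.euler_xyz)
        T_off = transform_inverse(T_joint) @ chain_target[i + 1]
        j.child_offset_position = T_off[:3, 3].copy()
        from .rotations import matrix_to_euler
        j.child_offset_euler = matrix_to_euler(T_off[:3, :3])

    record = {
        "lumbar_lordosis": params.lumbar_lordosis,
        "thoracic_kyphosis": params.thoracic_kyphosis,
        "sacral_slope": params.sacral_slope,
        "deformity_severity": sev,
        "theta": {v: float(theta[v]) for v in VERTEBRAE},
        "centers": {v: centers[v].tolist() for v in VERTEBRAE},
        "seed": int(seed),
    }
    return mdl, record


# ---------------------------------------------------------------------------
# motion generation
# ---------------------------------------------------------------------------

def generate_flexion_trial(spine_model: SpineModel,
                           motion: MotionSpec = None, seed: int = 0):
    """Simulate a seated maximal forward trunk flexion for a model.

    Marker trajectories are the exact forward kinematics of a smooth
    ground-truth joint-angle ramp, plus i.i.d. Gaussian noise of the stated
    SD. Returns (trial, ground_truth_series).
    """
    motion = motion or MotionSpec()
    rng = np.random.default_rng(seed)
    n = motion.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")

    amp = motion.total_flexion
    pelvis_rom = motion.pelvis_tilt_rom
    weights = motion.level_weights()
    start_rx = 0.0
    if motion.jitter:
        amp *= 1.0 + motion.amplitude_jitter * rng.standard_normal()
        pelvis_rom *= 1.0 + motion.amplitude_jitter * rng.standard_normal()
        w = weights * (1.0 + motion.weight_jitter * rng.standard_normal(
            weights.size))
        weights = np.clip(w, 0.0, None)
        weights = weights / weights.sum()
        start_rx = motion.start_offset_sd * rng.standard_normal()

    s = _smoothstep(np.linspace(0.0, 1.0, n))
    angles = np.zeros((n, 3 * N_JOINTS))
    for j in range(N_JOINTS):
        angles[:, 3 * j] = weights[j] * amp * s   # FE channel
    base = np.zeros((n, 6))
    base[:, :3] = spine_model.static_base_pose[:3]
    base[:, 3] = spine_model.static_base_pose[3] + start_rx + pelvis_rom * s
    base[:, 4:] = spine_model.static_base_pose[4:]

    positions = np.empty((n, len(spine_model.markers), 3))
    for f in range(n):
        _, mk = forward_kinematics(spine_model, base[f], angles[f])
        positions[f] = mk
    if motion.marker_noise_sd > 0:
        positions = positions + motion.marker_noise_sd * \
            rng.standard_normal(positions.shape)

    trial = MotionTrial(spine_model.marker_names, positions, motion.rate)
    truth = JointKinematicsSeries(angles, base,
                                  np.arange(n) / motion.rate,
                                  np.zeros(n))
    return trial, truth


# ---------------------------------------------------------------------------
# operator emulation
# ---------------------------------------------------------------------------

def draw_operator_deviation(spine_model: SpineModel,
                            spec: OperatorVariabilitySpec,
                            rng) -> ParameterVector:
    """One zero-mean Gaussian 294-entry operator deviation draw."""
    def block(shape, sd):
        return rng.standard_normal(shape) * np.asarray(sd, dtype=float)

    from .model import N_BODIES, N_MARKERS
    return ParameterVector.from_blocks(
        spine_model.marker_names,
        block((N_MARKERS, 3), spec.marker_position_sd),
        block((N_BODIES, 3), spec.body_position_sd),
        block((N_BODIES, 3), spec.body_orientation_sd),
        block((N_JOINTS, 3), spec.joint_position_sd),
        block((N_JOINTS, 3), spec.joint_orientation_sd),
    )


def emulate_operators(spine_model: SpineModel,
                      spec: OperatorVariabilitySpec = None,
                      n_operators: int = 3, seed: int = 0):
    """Simulate independent operators re-creating the same subject's model."""
    if n_operators < 2:
        raise ValueError("need at least 2 operators")
    spec = spec or OperatorVariabilitySpec()
    rng = np.random.default_rng(seed)
    return [apply_perturbation(spine_model,
                               draw_operator_deviation(spine_model, spec, rng))
            for _ in range(n_operators)]
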