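"""Articulated humanoid description and forward kinematics.

The body is a 13-point articulated-particle model whose particles double as
the skeleton keypoints consumed downstream: head, left/right shoulder,
elbow, wrist, hip, knee and ankle.  The torso (head, shoulders, hips) is a
rigid cluster; each limb hangs off it through a ball joint at the shoulder
or hip followed by a hinge at the elbow or knee.  Bones are realized in the
dynamics as stiff distance constraints between the particles.

The reference (zero-joint) pose is a supine lie along the +x axis with the
pelvis midpoint at the local origin, the person's left side at +y and the
vertical at +z.  All offsets are meters for a roughly 1.7 m adult; particle
masses sum to ~60 kg with a plausible segment distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._quat import quat_apply, quat_from_axis_angle, quat_mul

KEYPOINT_NAMES: tuple[str, ...] = (
    "head",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_wrist",
    "r_wrist",
    "l_hip",
    "r_hip",
    "l_knee",
    "r_knee",
    "l_ankle",
    "r_ankle",
)
N_KEYPOINTS = len(KEYPOINT_NAMES)
KEYPOINT_INDEX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

#: distal upper-limb bodies excluded from the fall condition
HAND_KEYPOINTS: tuple[str, ...] = ("l_wrist", "r_wrist")
HAND_INDICES: tuple[int, ...] = tuple(KEYPOINT_INDEX[n] for n in HAND_KEYPOINTS)

# local offsets of each particle from the pelvis midpoint in the reference pose
_T = {
    "head": (0.70, 0.00, 0.0),
    "l_shoulder": (0.45, 0.18, 0.0),
    "r_shoulder": (0.45, -0.18, 0.0),
    "l_elbow": (0.15, 0.26, 0.0),
    "r_elbow": (0.15, -0.26, 0.0),
    "l_wrist": (-0.10, 0.29, 0.0),
    "r_wrist": (-0.10, -0.29, 0.0),
    "l_hip": (0.00, 0.12, 0.0),
    "r_hip": (0.00, -0.12, 0.0),
    "l_knee": (-0.45, 0.13, 0.0),
    "r_knee": (-0.45, -0.13, 0.0),
    "l_ankle": (-0.88, 0.14, 0.0),
    "r_ankle": (-0.88, -0.14, 0.0),
}
TEMPLATE_OFFSETS = np.array([_T[n] for n in KEYPOINT_NAMES])

_M = {
    "head": 5.0,
    "l_shoulder": 7.0,
    "r_shoulder": 7.0,
    "l_elbow": 2.0,
    "r_elbow": 2.0,
    "l_wrist": 1.5,
    "r_wrist": 1.5,
    "l_hip": 10.0,
    "r_hip": 10.0,
    "l_knee": 4.5,
    "r_knee": 4.5,
    "l_ankle": 2.5,
    "r_ankle": 2.5,
}
MASSES = np.array([_M[n] for n in KEYPOINT_NAMES])

# rigid torso cluster: all pairs among head/shoulders/hips
_TORSO = ("head", "l_shoulder", "r_shoulder", "l_hip", "r_hip")
_LIMB_BONES = (
    ("l_shoulder", "l_elbow"),
    ("l_elbow", "l_wrist"),
    ("r_shoulder", "r_elbow"),
    ("r_elbow", "r_wrist"),
    ("l_hip", "l_knee"),
    ("l_knee", "l_ankle"),
    ("r_hip", "r_knee"),
    ("r_knee", "r_ankle"),
)


def _bone_list() -> list[tuple[int, int, float]]:
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(_TORSO):
        for b in _TORSO[i + 1 :]:
            pairs.append((a, b))
    pairs.extend(_LIMB_BONES)
    out = []
    for a, b in pairs:
        ia, ib = KEYPOINT_INDEX[a], KEYPOINT_INDEX[b]
        rest = float(np.linalg.norm(TEMPLATE_OFFSETS[ia] - TEMPLATE_OFFSETS[ib]))
        out.append((ia, ib, rest))
    return out


BONES: tuple[tuple[int, int, float], ...] = tuple(_bone_list())

#: anatomical skeleton edge list (used by the graph regressor, not the physics)
SKELETON_EDGES: tuple[tuple[str, str], ...] = (
    ("head", "l_shoulder"),
    ("head", "r_shoulder"),
    ("l_shoulder", "r_shoulder"),
    ("l_shoulder", "l_elbow"),
    ("l_elbow", "l_wrist"),
    ("r_shoulder", "r_elbow"),
    ("r_elbow", "r_wrist"),
    ("l_shoulder", "l_hip"),
    ("r_shoulder", "r_hip"),
    ("l_hip", "r_hip"),
    ("l_hip", "l_knee"),
    ("l_knee", "l_ankle"),
    ("r_hip", "r_knee"),
    ("r_knee", "r_ankle"),
)


@dataclass(frozen=True)
class JointDescriptor:
    """One sampleable joint: ``kind`` is ``"hinge"`` or ``"ball"``.

    Hinges carry ``limits`` in radians (``None`` = unlimited, sampled from the
    sampler's default bounded range); balls are sampled as uniform random unit
    quaternions.
    """

    name: str
    kind: str
    limits: tuple[float, float] | None = None
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("hinge", "ball"):
            raise ValueError(f"unknown joint kind {self.kind!r}")


# elbows/knees flex about the local y axis within physiological-ish limits
JOINT_DESCRIPTORS: tuple[JointDescriptor, ...] = (
    JointDescriptor("l_shoulder", "ball"),
    JointDescriptor("r_shoulder", "ball"),
    JointDescriptor("l_elbow", "hinge", (0.0, 2.6)),
    JointDescriptor("r_elbow", "hinge", (0.0, 2.6)),
    JointDescriptor("l_hip", "ball"),
    JointDescriptor("r_hip", "ball"),
    JointDescriptor("l_knee", "hinge", (0.0, 2.6)),
    JointDescriptor("r_knee", "hinge", (0.0, 2.6)),
)
JOINT_INDEX = {d.name: i for i, d in enumerate(JOINT_DESCRIPTORS)}

# (parent particle, child particle, ball joint name, hinge joint name or None)
_CHAINS = (
    ("l_shoulder", "l_elbow", "l_shoulder", None),
    ("l_elbow", "l_wrist", "l_shoulder", "l_elbow"),
    ("r_shoulder", "r_elbow", "r_shoulder", None),
    ("r_elbow", "r_wrist", "r_shoulder", "r_elbow"),
    ("l_hip", "l_knee", "l_hip", None),
    ("l_knee", "l_ankle", "l_hip", "l_knee"),
    ("r_hip", "r_knee", "r_hip", None),
    ("r_knee", "r_ankle", "r_hip", "r_knee"),
)


@dataclass
class JointState:
    """Joint coordinates: hinge angles (radians) and ball quaternions.

    ``hinges`` maps hinge joint names to scalars; ``balls`` maps ball joint
    names to unit quaternions (w, x, y, z).
    """

    hinges: dict[str, float] = field(default_factory=dict)
    balls: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def neutral(cls) -> "JointState":
        hinges = {d.name: 0.0 for d in JOINT_DESCRIPTORS if d.kind == "hinge"}
        balls = {
            d.name: np.array([1.0, 0.0, 0.0, 0.0])
            for d in JOINT_DESCRIPTORS
            if d.kind == "ball"
        }
        return cls(hinges=hinges, balls=balls)


def forward_kinematics(
    root_pos: np.ndarray, root_quat: np.ndarray, joints: JointState
) -> np.ndarray:
    """Particle positions (13, 3) for a root pose plus joint coordinates.

    Torso particles are rigid with the root; the elbow/wrist (knee/ankle)
    follow the shoulder (hip) ball rotation, with the hinge applied in the
    post-ball local frame.  Batched inputs are supported: ``root_pos``
    (..., 3) and ``root_quat`` (..., 4) with joint values broadcasting.
    """
    root_pos = np.asarray(root_pos, float)
    root_quat = np.asarray(root_quat, float)
    batch = root_pos.shape[:-1]
    pos = np.zeros(batch + (N_KEYPOINTS, 3))
    for name in _TORSO:
        i = KEYPOINT_INDEX[name]
        pos[..., i, :] = root_pos + quat_apply(root_quat, TEMPLATE_OFFSETS[i])
    for parent, child, ball_name, hinge_name in _CHAINS:
        ip, ic = KEYPOINT_INDEX[parent], KEYPOINT_INDEX[child]
        seg = TEMPLATE_OFFSETS[ic] - TEMPLATE_OFFSETS[ip]
        q = joints.balls[ball_name]
        if hinge_name is not None:
            desc = JOINT_DESCRIPTORS[JOINT_INDEX[hinge_name]]
            angle = np.asarray(joints.hinges[hinge_name], float)
            q = quat_mul(q, quat_from_axis_angle(np.array(desc.axis), angle))
        local = quat_apply(q, seg)
        pos[..., ic, :] = pos[..., ip, :] + quat_apply(root_quat, local)
    return pos
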