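"""Initial-configuration sampling for in-bed episodes.

Two strategies generate the target configuration q = (planar position on
the bed, global root orientation, joint coordinates):

* ``pose_stratified`` — draw one of four coarse lying-posture modes
  (supine, prone, left-lateral, right-lateral) uniformly, take its preset
  root Euler triple, and perturb each axis with independent zero-mean
  Gaussian noise (sigma_deg, default 15 degrees).
* ``fully_random`` — draw root Euler angles independently and uniformly on
  [-180, 180] degrees per axis.  Note this is deliberately *not* uniform on
  SO(3); uniform Euler angles are the stated protocol.

Planar position is uniform on the bed footprint shrunk by an edge margin.
Hinge joints are uniform within their limits (or within a default bounded
range when unlimited); ball joints are uniform on the rotation group.
All Euler triples use the package-wide extrinsic xyz convention.

Preset convention: the reference pose lies along the bed long axis (+x
toward the head) with the person's left at +y.  Supine is the identity,
prone a 180-degree roll about x, and the laterals are -/+90-degree rolls
(left-lateral puts the person's left side down).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import humanoid
from ._quat import quat_from_euler_deg, quat_normalize, random_unit_quat
from .world import ConfigurationError

STRATEGY_POSE_STRATIFIED = "pose_stratified"
STRATEGY_FULLY_RANDOM = "fully_random"


class PostureMode(enum.Enum):
    """Coarse lying-posture mode with its preset root Euler triple (deg)."""

    SUPINE = "supine"
    PRONE = "prone"
    LEFT_LATERAL = "left_lateral"
    RIGHT_LATERAL = "right_lateral"

    @property
    def preset_euler_deg(self) -> np.ndarray:
        return np.array(_PRESETS[self], float)


_PRESETS = {
    PostureMode.SUPINE: (0.0, 0.0, 0.0),
    PostureMode.PRONE: (180.0, 0.0, 0.0),
    PostureMode.LEFT_LATERAL: (-90.0, 0.0, 0.0),
    PostureMode.RIGHT_LATERAL: (90.0, 0.0, 0.0),
}
MODES = tuple(PostureMode)


@dataclass(frozen=True)
class SamplerConfig:
    """Initial-state sampling settings.

    ``sigma_deg`` is the per-axis Gaussian perturbation of the posture
    presets; ``edge_margin`` (meters) shrinks the feasible planar rectangle
    away from the bed edges; ``joint_range_default`` (radians) bounds
    unlimited hinges symmetrically about zero.
    """

    strategy: str = STRATEGY_POSE_STRATIFIED
    sigma_deg: float = 15.0
    edge_margin: float = 0.1
    joint_range_default: float = np.pi / 4
    seed: int = 0

    def validate(self, bed_bounds: tuple[float, float, float, float] | None = None) -> None:
        if self.strategy not in (STRATEGY_POSE_STRATIFIED, STRATEGY_FULLY_RANDOM):
            raise ConfigurationError(f"unknown sampling strategy {self.strategy!r}")
        if self.sigma_deg < 0:
            raise ConfigurationError("sigma_deg must be non-negative")
        if self.edge_margin < 0:
            raise ConfigurationError("edge_margin must be non-negative")
        if bed_bounds is not None:
            x_min, x_max, y_min, y_max = bed_bounds
            if 2 * self.edge_margin >= min(x_max - x_min, y_max - y_min):
                raise ConfigurationError("edge_margin leaves an empty feasible region")


@dataclass
class InitialConfiguration:
    """A sampled target configuration q.

    ``planar_xy`` is in the bed frame (bed center = origin), ``root_quat``
    is a unit quaternion (w, x, y, z), ``joints`` holds hinge angles and
    ball quaternions, and ``mode`` tags the posture preset for stratified
    draws (``None`` for fully random).
    """

    planar_xy: np.ndarray
    root_quat: np.ndarray
    joints: humanoid.JointState
    mode: PostureMode | None = None


def sample_planar_position(
    rng: np.random.Generator,
    bed_bounds: tuple[float, float, float, float],
    edge_margin: float,
) -> np.ndarray:
    """Uniform planar point on the bed footprint shrunk by the edge margin."""
    x_min, x_max, y_min, y_max = bed_bounds
    if x_min + edge_margin >= x_max - edge_margin or y_min + edge_margin >= y_max - edge_margin:
        raise ConfigurationError("edge_margin leaves an empty feasible region")
    x = rng.uniform(x_min + edge_margin, x_max - edge_margin)
    y = rng.uniform(y_min + edge_margin, y_max - edge_margin)
    return np.array([x, y])


def sample_root_orientation(
    rng: np.random.Generator,
    config: SamplerConfig,
    mode: PostureMode | None = None,
) -> np.ndarray:
    """Unit root quaternion under the configured strategy.

    ``mode`` is required for pose-stratified sampling and must be omitted
    for fully random sampling.
    """
    if config.strategy == STRATEGY_POSE_STRATIFIED:
        if mode is None:
            raise ValueError("pose_stratified sampling requires a posture mode")
        euler = mode.preset_euler_deg + rng.normal(0.0, config.sigma_deg, size=3)
    else:
        if mode is not None:
            raise ValueError("fully_random sampling takes no posture mode")
        euler = rng.uniform(-180.0, 180.0, size=3)
    return quat_normalize(quat_from_euler_deg(euler))


def sample_joint_angles(
    rng: np.random.Generator,
    joint_descriptors: tuple[humanoid.JointDescriptor, ...],
    config: SamplerConfig,
) -> humanoid.JointState:
    """Joint coordinates: hinges uniform within limits, balls uniform on SO(3)."""
    state = humanoid.JointState()
    for desc in joint_descriptors:
        if desc.kind == "hinge":
            if desc.limits is not None:
                lo, hi = desc.limits
            else:
                lo, hi = -config.joint_range_default, config.joint_range_default
            state.hinges[desc.name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        else:
            state.balls[desc.name] = random_unit_quat(rng)
    return state


def sample_posture_mode(rng: np.random.Generator) -> PostureMode:
    """Uniform draw over the four coarse posture modes."""
    return MODES[int(rng.integers(len(MODES)))]


def draw_raw_configuration(
    rng: np.random.Generator,
    config: SamplerConfig,
    bed_bounds: tuple[float, float, float, float],
    joint_descriptors: tuple[humanoid.JointDescriptor, ...] = humanoid.JOINT_DESCRIPTORS,
    forced_mode: PostureMode | None = None,
) -> dict:
    """Draw the raw numbers of one configuration in a fixed stream order.

    This is the single source of randomness for both the per-episode API and
    the batched generator, so an episode is exactly replayable from its seed.
    Returns unconverted quantities: ``mode`` (PostureMode or None),
    ``planar`` (2,), ``euler_deg`` (3,), ``hinges`` (per hinge descriptor,
    in order) and ``ball_gauss`` (per ball descriptor, 4 Gaussians each,
    normalized later).  A ``forced_mode`` (pose-balanced test sets) replaces
    the uniform mode draw without consuming it.
    """
    config.validate(bed_bounds)
    mode: PostureMode | None = None
    if config.strategy == STRATEGY_POSE_STRATIFIED:
        mode = forced_mode if forced_mode is not None else sample_posture_mode(rng)
    elif forced_mode is not None:
        raise ValueError("fully_random sampling takes no posture mode")
    planar = sample_planar_position(rng, bed_bounds, config.edge_margin)
    if config.strategy == STRATEGY_POSE_STRATIFIED:
        euler = mode.preset_euler_deg + rng.normal(0.0, config.sigma_deg, size=3)
    else:
        euler = rng.uniform(-180.0, 180.0, size=3)
    hinges = []
    ball_gauss = []
    for desc in joint_descriptors:
        if desc.kind == "hinge":
            if desc.limits is not None:
                lo, hi = desc.limits
            else:
                lo, hi = -config.joint_range_default, config.joint_range_default
            hinges.append(float(rng.uniform(lo, hi)) if hi > lo else float(lo))
        else:
            ball_gauss.append(rng.standard_normal(4))
    return {
        "mode": mode,
        "planar": planar,
        "euler_deg": euler,
        "hinges": np.array(hinges),
        "ball_gauss": np.array(ball_gauss) if ball_gauss else np.zeros((0, 4)),
    }


def configuration_from_raw(
    raw: dict,
    joint_descriptors: tuple[humanoid.JointDescriptor, ...] = humanoid.JOINT_DESCRIPTORS,
) -> InitialConfiguration:
    """Convert a raw draw into an InitialConfiguration."""
    quat = quat_normalize(quat_from_euler_deg(raw["euler_deg"]))
    joints = humanoid.JointState()
    hi = bi = 0
    for desc in joint_descriptors:
        if desc.kind == "hinge":
            joints.hinges[desc.name] = float(raw["hinges"][hi])
            hi += 1
        else:
            joints.balls[desc.name] = quat_normalize(raw["ball_gauss"][bi])
            bi += 1
    return InitialConfiguration(
        planar_xy=np.asarray(raw["planar"], float),
        root_quat=quat,
        joints=joints,
        mode=raw["mode"],
    )


def sample_initial_configuration(
    rng: np.random.Generator,
    config: SamplerConfig,
    bed_bounds: tuple[float, float, float, float],
    joint_descriptors: tuple[humanoid.JointDescriptor, ...] = humanoid.JOINT_DESCRIPTORS,
) -> InitialConfiguration:
    """Compose the planar, orientation, and joint samplers into one draw."""
    raw = draw_raw_configuration(rng, config, bed_bounds, joint_descriptors)
    return configuration_from_raw(raw, joint_descriptors)
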