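"""Episode execution: pre-pose, drop-to-contact, rollout, fall adjudication.

One episode proceeds through four phases:

1. **pre-pose** — interpolate from the reset pose to the sampled target
   configuration at a fixed drop height above the bed, zeroing velocities at
   every substep so no momentum is injected;
2. **drop to contact** — advance under gravity until the first
   humanoid-bed contact, then freeze (velocities zeroed, clock reset to 0);
   this standardizes the episode start at a physically consistent contact
   configuration;
3. **rollout** — uncontrolled dynamics for a fixed window T (default 3 s);
4. **adjudication** — the episode is a fall iff any non-hand body segment
   contacts the floor within the window; hand-floor contacts alone are
   non-terminal.  Episodes that time out without touching the bed or that
   trigger integrator instability are rejected, never silently dropped.

:func:`run_episode` executes a single seeded episode through this contract;
:func:`generate_batch` runs many episodes vectorized through the same
engine arithmetic (the per-step numerics are identical, so a single episode
replayed from its logged seed reproduces its batched outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import humanoid, sampling
from ._quat import quat_from_euler_deg, quat_normalize, quat_slerp
from .labels import LabelConfig, fall_labels_from_steps
from .skeleton import BedBounds, flatten, normalize
from .world import (
    CONTACT_HUMANOID_BED,
    CONTACT_HUMANOID_FLOOR,
    ConfigurationError,
    SimState,
    World,
)

REJECT_TIMEOUT = "timeout"
REJECT_UNSTABLE = "unstable"

#: 30 fps frames captured from the episode start for sequence models
N_SEQUENCE_FRAMES = 5


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode phase settings (seconds / meters)."""

    drop_height: float = 2.0
    pre_pose_duration: float = 1.0
    contact_timeout: float = 2.0
    rollout_window: float = 3.0

    def validate(self, sim_timestep: float) -> None:
        for name in ("drop_height", "pre_pose_duration", "contact_timeout", "rollout_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        steps = self.rollout_window / sim_timestep
        if abs(steps - round(steps)) > 1e-9:
            raise ConfigurationError("rollout_window must be a whole number of timesteps")

    def n_rollout_steps(self, sim_timestep: float) -> int:
        return round(self.rollout_window / sim_timestep)


@dataclass
class EpisodeOutcome:
    """Adjudicated result of one rollout."""

    fell: bool
    fall_step: int | None
    unstable: bool
    settled_state: SimState | None = None
    contact_log: list | None = None


class EpisodeRejected(Exception):
    """Episode discarded (drop timeout or integrator instability)."""

    def __init__(self, reason: str):
        super().__init__(f"episode rejected: {reason}")
        self.reason = reason


@dataclass
class RejectionCounter:
    """Running tally of discarded episodes by reason."""

    counts: dict = field(default_factory=dict)

    def add(self, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def reset_configuration(world: World) -> sampling.InitialConfiguration:
    """The reset pose: neutral supine, centered over the bed."""
    return sampling.InitialConfiguration(
        planar_xy=np.zeros(2),
        root_quat=np.array([1.0, 0.0, 0.0, 0.0]),
        joints=humanoid.JointState.neutral(),
        mode=None,
    )


def _configuration_positions(
    world: World, config: sampling.InitialConfiguration, drop_height: float
) -> np.ndarray:
    """Particle positions of a configuration placed at the drop height."""
    root = np.array(
        [config.planar_xy[0], config.planar_xy[1], world.bed_top_height + drop_height]
    )
    return humanoid.forward_kinematics(root, config.root_quat, config.joints)


def pre_pose(
    world: World,
    target: sampling.InitialConfiguration,
    duration: float | None = None,
    drop_height: float = 2.0,
) -> SimState:
    """Kinematically interpolate from the reset pose to the target.

    Interpolation runs in configuration space — planar position and hinge
    angles linearly, root and ball quaternions by slerp — over
    ``duration / dt`` substeps with velocities zeroed at every substep.  The
    final state equals the target configuration exactly, with zero velocity
    and the root ``drop_height`` above the bed top.
    """
    if duration is None:
        duration = 1.0
    start = reset_configuration(world)
    n_sub = max(1, round(duration / world.sim_timestep))
    pos = None
    for k in range(1, n_sub + 1):
        a = k / n_sub
        if a >= 1.0:
            cfg = target
        else:
            joints = humanoid.JointState(
                hinges={
                    n: (1 - a) * start.joints.hinges[n] + a * target.joints.hinges[n]
                    for n in start.joints.hinges
                },
                balls={
                    n: quat_slerp(start.joints.balls[n], target.joints.balls[n], a)
                    for n in start.joints.balls
                },
            )
            cfg = sampling.InitialConfiguration(
                planar_xy=(1 - a) * start.planar_xy + a * target.planar_xy,
                root_quat=quat_slerp(start.root_quat, target.root_quat, a),
                joints=joints,
                mode=target.mode,
            )
        pos = _configuration_positions(world, cfg, drop_height)
    return SimState.from_positions(pos, t=0.0)


def drop_to_contact(world: World, state: SimState, timeout: float = 2.0) -> SimState:
    """Advance under gravity until the first humanoid-bed contact, then freeze.

    The drop phase is initialization only: it is excluded from the rollout
    window, and the returned state has zero velocities and t = 0.
    """
    max_steps = int(math.ceil(timeout / world.sim_timestep))
    for _ in range(max_steps):
        state, events = world.step(state)
        if state.unstable:
            raise EpisodeRejected(REJECT_UNSTABLE)
        if any(e.kind == CONTACT_HUMANOID_BED for e in events):
            return world.freeze(state)
    raise EpisodeRejected(REJECT_TIMEOUT)


def rollout_and_detect(world, start: SimState, config: EpisodeConfig) -> EpisodeOutcome:
    """Roll out uncontrolled dynamics and adjudicate the fall outcome.

    ``world`` needs only ``step`` and ``config.sim_timestep`` (a stub world
    with a scripted contact stream is sufficient for testing the
    hand-exclusion rule).  Stops at the first non-hand humanoid-floor
    contact or after the full window; keeps a per-step contact log.
    """
    if abs(start.t) > 1e-12:
        raise ValueError("rollout must start from a frozen state with t = 0")
    n_steps = config.n_rollout_steps(world.config.sim_timestep)
    state = start
    log: list = []
    for s in range(1, n_steps + 1):
        state, events = world.step(state)
        log.append(events)
        if state.unstable:
            return EpisodeOutcome(
                fell=False, fall_step=None, unstable=True, settled_state=start, contact_log=log
            )
        if any(e.kind == CONTACT_HUMANOID_FLOOR for e in events):
            return EpisodeOutcome(
                fell=True, fall_step=s, unstable=False, settled_state=start, contact_log=log
            )
    return EpisodeOutcome(
        fell=False, fall_step=None, unstable=False, settled_state=start, contact_log=log
    )


def run_episode(
    rng: np.random.Generator,
    world: World,
    sampler_config: sampling.SamplerConfig,
    episode_config: EpisodeConfig,
    counter: RejectionCounter | None = None,
    forced_mode: sampling.PostureMode | None = None,
) -> tuple[sampling.InitialConfiguration, SimState, EpisodeOutcome]:
    """Sample, initialize and roll out one episode.

    Raises :class:`EpisodeRejected` on drop timeout or instability (counted
    in ``counter`` when given); unstable rollouts are likewise rejected.
    """
    episode_config.validate(world.sim_timestep)
    raw = sampling.draw_raw_configuration(
        rng, sampler_config, world.bed_bounds, forced_mode=forced_mode
    )
    target = sampling.configuration_from_raw(raw)
    posed = pre_pose(
        world, target, episode_config.pre_pose_duration, episode_config.drop_height
    )
    try:
        start = drop_to_contact(world, posed, episode_config.contact_timeout)
        outcome = rollout_and_detect(world, start, episode_config)
        if outcome.unstable:
            raise EpisodeRejected(REJECT_UNSTABLE)
    except EpisodeRejected as exc:
        if counter is not None:
            counter.add(exc.reason)
        raise
    return target, start, outcome


# ---------------------------------------------------------------------------
# batched generation


@dataclass
class EpisodeBatch:
    """Struct-of-arrays record of a batch of episodes.

    ``accepted`` marks episodes that produced a labeled sample; rejected
    episodes carry a reason in ``reject_reason`` ("" when accepted).
    ``mode`` holds posture-mode names ("" for fully random).  ``frames`` are
    the first five 30 fps skeleton frames (fall-padded) for sequence models.
    """

    seeds: np.ndarray
    mode: np.ndarray
    accepted: np.ndarray
    reject_reason: np.ndarray
    fell: np.ndarray
    fall_step: np.ndarray
    u: np.ndarray
    validity: np.ndarray
    y: np.ndarray
    c: np.ndarray
    frames: np.ndarray

    def __len__(self) -> int:
        return len(self.seeds)


def _frame_step(k: int, fps: float, dt: float) -> int:
    """Simulator step of 30 fps frame k (ceil to the next completed step)."""
    return int(math.ceil(k / (fps * dt) - 1e-9))


def generate_batch(
    world: World,
    sampler_config: sampling.SamplerConfig,
    episode_config: EpisodeConfig,
    label_config: LabelConfig,
    seeds: np.ndarray,
    forced_modes: list | None = None,
) -> EpisodeBatch:
    """Run one episode per seed, vectorized across the batch.

    ``forced_modes`` (sequence of PostureMode, optional) pins each episode's
    posture mode, used for pose-balanced test sets.  Randomness is drawn per
    episode from ``default_rng(seed)`` in the same stream order as
    :func:`run_episode`, so any episode can be replayed alone.
    """
    episode_config.validate(world.sim_timestep)
    label_config.validate()
    seeds = np.asarray(seeds)
    n = len(seeds)
    bounds = BedBounds.from_world(world)

    planar = np.zeros((n, 2))
    euler = np.zeros((n, 3))
    hinge_names = [d.name for d in humanoid.JOINT_DESCRIPTORS if d.kind == "hinge"]
    ball_names = [d.name for d in humanoid.JOINT_DESCRIPTORS if d.kind == "ball"]
    hinges = np.zeros((n, len(hinge_names)))
    balls = np.zeros((n, len(ball_names), 4))
    modes = np.empty(n, dtype=object)
    for i in range(n):
        rng = np.random.default_rng(int(seeds[i]))
        forced = forced_modes[i] if forced_modes is not None else None
        raw = sampling.draw_raw_configuration(
            rng, sampler_config, world.bed_bounds, forced_mode=forced
        )
        planar[i] = raw["planar"]
        euler[i] = raw["euler_deg"]
        hinges[i] = raw["hinges"]
        balls[i] = raw["ball_gauss"]
        modes[i] = raw["mode"].value if raw["mode"] is not None else ""

    root_quat = quat_normalize(quat_from_euler_deg(euler))
    joint_state = humanoid.JointState(
        hinges={name: hinges[:, j] for j, name in enumerate(hinge_names)},
        balls={name: quat_normalize(balls[:, j]) for j, name in enumerate(ball_names)},
    )
    root_pos = np.column_stack(
        [planar, np.full(n, world.bed_top_height + episode_config.drop_height)]
    )
    pos = humanoid.forward_kinematics(root_pos, root_quat, joint_state)
    vel = np.zeros_like(pos)

    # drop phase: step everyone until their first bed contact (or timeout)
    max_drop = int(math.ceil(episode_config.contact_timeout / world.sim_timestep))
    pending = np.ones(n, bool)
    unstable = np.zeros(n, bool)
    bed_c = np.zeros((n, humanoid.N_KEYPOINTS), bool)
    floor_c = np.zeros_like(bed_c)
    unst = np.zeros(n, bool)
    frozen = pos.copy()
    for _ in range(max_drop):
        world.step_arrays_inplace(pos, vel, pending, bed_c, floor_c, unst)
        newly_unstable = pending & unst
        unstable |= newly_unstable
        contacted = pending & bed_c.any(axis=-1) & ~unst
        frozen[contacted] = pos[contacted]
        pending &= ~(contacted | newly_unstable)
        if not pending.any():
            break
    timed_out = pending & ~unstable

    # rollout from the frozen start (zero velocities, t = 0)
    n_steps = episode_config.n_rollout_steps(world.sim_timestep)
    hand = world.hand_mask
    pos = frozen.copy()
    vel = np.zeros_like(pos)
    fell = np.zeros(n, bool)
    fall_step = np.zeros(n, int)
    frame_steps = [
        _frame_step(k, label_config.fps, world.sim_timestep)
        for k in range(N_SEQUENCE_FRAMES)
    ]
    frames_xy = np.zeros((n, N_SEQUENCE_FRAMES, humanoid.N_KEYPOINTS, 2))
    frames_xy[:, 0] = pos[:, :, :2]
    done = unstable | timed_out
    for s in range(1, n_steps + 1):
        upd = ~done
        world.step_arrays_inplace(pos, vel, upd, bed_c, floor_c, unst)
        newly_unstable = upd & unst
        unstable |= newly_unstable
        newly_fell = upd & ~unst & (floor_c & ~hand).any(axis=-1)
        fall_step[newly_fell] = s
        fell |= newly_fell
        done |= newly_fell | newly_unstable
        for k, fs in enumerate(frame_steps):
            if fs == s:
                frames_xy[:, k] = pos[:, :, :2]
    # fall-padding: frames after the fall repeat the last frame at or before it
    for i in np.flatnonzero(fell):
        last = min(N_SEQUENCE_FRAMES - 1, int(fall_step[i]) // max(1, frame_steps[1]))
        for k in range(last + 1, N_SEQUENCE_FRAMES):
            frames_xy[i, k] = frames_xy[i, last]

    accepted = ~(unstable | timed_out)
    reasons = np.where(unstable, REJECT_UNSTABLE, np.where(timed_out, REJECT_TIMEOUT, ""))

    norm, validity = normalize(frames_xy[:, 0], bounds)
    u = flatten(norm)
    frames_norm, _ = normalize(frames_xy, bounds)
    frames_u = flatten(frames_norm)
    y = fall_labels_from_steps(fall_step, fell, label_config)
    y = np.where(accepted, y, 0.0)
    c = (fell & accepted).astype(int)

    return EpisodeBatch(
        seeds=seeds.copy(),
        mode=modes.astype(object),
        accepted=accepted,
        reject_reason=reasons.astype(object),
        fell=fell & accepted,
        fall_step=np.where(fell & accepted, fall_step, -1),
        u=u,
        validity=validity,
        y=y,
        c=c,
        frames=frames_u,
    )
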