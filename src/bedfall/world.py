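"""Rigid-body bed-human world: a floor plane, a box bed, and a humanoid.

The dynamics engine is a deterministic position-based-dynamics (PBD)
integrator over the 13-particle articulated humanoid of
:mod:`bedfall.humanoid`: semi-implicit gravity integration, Gauss-Seidel
projection of stiff bone distance constraints, unilateral contacts against
the bed top face and the floor plane, and strong Coulomb-style tangential
friction at contacts.  Everything downstream (episode rollout, fall
detection, skeleton extraction) talks to this module's contract and never
to integrator internals.

Conventions: world origin at the bed footprint center on the floor, z up,
bed long axis along x.  The floor is the plane z = 0; the bed top face is
the rectangle ``bed_bounds`` at height ``bed_top_height``.

The engine steps either one state (positions ``(13, 3)``) or a batch
``(B, 13, 3)`` with identical numerics, which keeps single-episode replay
and batched dataset generation bit-for-bit consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine, humanoid

ENGINE_NAME = "bedfall-pbd"
ENGINE_VERSION = "1.0"

CONTACT_HUMANOID_BED = "humanoid-bed"
CONTACT_HUMANOID_FLOOR = "humanoid-floor"
CONTACT_HAND_FLOOR = "hand-floor"
CONTACT_OTHER = "other"


class ConfigurationError(ValueError):
    """Invalid world or episode configuration."""


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and integrator settings of the bed-human world.

    ``bed_extents`` is the (length, width, height) of the box bed in meters;
    ``bed_top_height`` is the height of the sleeping surface above the floor
    (>= bed height, so the bed never sinks below the floor).  Friction is the
    per-contact tangential velocity retention exponent used by the PBD
    contact model: 0 = frictionless, 1 = fully sticking.
    """

    bed_extents: tuple[float, float, float] = (2.0, 0.9, 0.5)
    bed_top_height: float = 0.5
    sim_timestep: float = 1.0 / 60.0
    gravity: float = 9.81
    humanoid_model_id: str = "bedfall-humanoid-13"
    hand_keypoints: tuple[str, ...] = humanoid.HAND_KEYPOINTS
    friction: float = 0.85
    solver_iterations: int = 8
    particle_radius: float = 0.06
    velocity_damping: float = 1e-3

    def validate(self) -> None:
        if any(e <= 0 for e in self.bed_extents):
            raise ConfigurationError(f"bed_extents must be positive, got {self.bed_extents}")
        if self.sim_timestep <= 0:
            raise ConfigurationError("sim_timestep must be positive")
        if self.bed_top_height < self.bed_extents[2]:
            raise ConfigurationError("bed top must sit at or above the bed height")
        if not 0.0 <= self.friction <= 1.0:
            raise ConfigurationError("friction must lie in [0, 1]")


@dataclass
class SimState:
    """Maximal-coordinate simulator state.

    ``q`` holds the flattened particle positions (39 scalars, meter), ``v``
    the flattened velocities, ``t`` the simulated time in seconds.  States
    flagged ``unstable`` carry no physical meaning and must be discarded.
    """

    q: np.ndarray
    v: np.ndarray
    t: float = 0.0
    unstable: bool = False

    @classmethod
    def from_positions(cls, pos: np.ndarray, vel: np.ndarray | None = None, t: float = 0.0) -> "SimState":
        pos = np.asarray(pos, float)
        vel = np.zeros_like(pos) if vel is None else np.asarray(vel, float)
        return cls(q=pos.reshape(-1).copy(), v=vel.reshape(-1).copy(), t=float(t))

    @property
    def positions(self) -> np.ndarray:
        return self.q.reshape(humanoid.N_KEYPOINTS, 3)

    @property
    def velocities(self) -> np.ndarray:
        return self.v.reshape(humanoid.N_KEYPOINTS, 3)


@dataclass(frozen=True)
class ContactEvent:
    """One classified contact active after a step."""

    body_a: str
    body_b: str
    kind: str


class World:
    """Steppable world; construct through :func:`build_world`."""

    entity_groups = ("floor", "bed", "humanoid")

    def __init__(self, config: WorldConfig):
        config.validate()
        self.config = config
        length, width, _ = config.bed_extents
        self._x_half = length / 2.0
        self._y_half = width / 2.0
        self._bed_top = config.bed_top_height
        self._radius = config.particle_radius
        self._inv_mass = 1.0 / humanoid.MASSES
        self._bones_i = np.array([b[0] for b in humanoid.BONES])
        self._bones_j = np.array([b[1] for b in humanoid.BONES])
        self._bones_rest = np.array([b[2] for b in humanoid.BONES])
        self._hand_idx = np.array(
            [humanoid.KEYPOINT_INDEX[n] for n in config.hand_keypoints], dtype=int
        )
        self._hand_mask = np.zeros(humanoid.N_KEYPOINTS, bool)
        self._hand_mask[self._hand_idx] = True

    # -- geometry ----------------------------------------------------------

    @property
    def bed_bounds(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the bed top-face footprint."""
        return (-self._x_half, self._x_half, -self._y_half, self._y_half)

    @property
    def bed_top_height(self) -> float:
        return self._bed_top

    @property
    def sim_timestep(self) -> float:
        return self.config.sim_timestep

    @property
    def hand_mask(self) -> np.ndarray:
        """Boolean mask over keypoints marking the hand segments."""
        return self._hand_mask.copy()

    def support_height(self) -> float:
        """Resting height of a particle center on the bed surface."""
        return self._bed_top + self._radius

    # -- dynamics ----------------------------------------------------------

    def step_arrays(
        self, pos: np.ndarray, vel: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Advance positions/velocities by one timestep.

        ``pos``/``vel`` have shape (..., 13, 3).  Returns
        ``(pos, vel, bed_contact, floor_contact, unstable)`` where the
        contact arrays are boolean (..., 13) masks of particles in contact
        after the step and ``unstable`` is a boolean (...) flag.
        """
        pos = np.asarray(pos, float)
        single = pos.ndim == 2
        batch_pos = (pos[None] if single else pos).copy()
        batch_vel = (np.asarray(vel, float)[None] if single else np.asarray(vel, float)).copy()
        B = batch_pos.shape[0]
        active = np.ones(B, bool)
        bed_contact = np.zeros((B, humanoid.N_KEYPOINTS), bool)
        floor_contact = np.zeros_like(bed_contact)
        unstable = np.zeros(B, bool)
        self._kernel(batch_pos, batch_vel, active, bed_contact, floor_contact, unstable)
        if single:
            return batch_pos[0], batch_vel[0], bed_contact[0], floor_contact[0], unstable[0]
        return batch_pos, batch_vel, bed_contact, floor_contact, unstable

    def step_arrays_inplace(
        self,
        pos: np.ndarray,
        vel: np.ndarray,
        active: np.ndarray,
        bed_contact: np.ndarray,
        floor_contact: np.ndarray,
        unstable: np.ndarray,
    ) -> None:
        """In-place batched step; rows with ``active`` false are untouched."""
        self._kernel(pos, vel, active, bed_contact, floor_contact, unstable)

    def _kernel(self, pos, vel, active, bed_contact, floor_contact, unstable) -> None:
        cfg = self.config
        _engine.pbd_step(
            pos,
            vel,
            active,
            bed_contact,
            floor_contact,
            unstable,
            self._bones_i,
            self._bones_j,
            self._bones_rest,
            self._inv_mass,
            cfg.sim_timestep,
            cfg.gravity,
            cfg.velocity_damping,
            cfg.friction,
            self._x_half,
            self._y_half,
            self._bed_top + self._radius,
            self._radius,
            cfg.solver_iterations,
        )

    def step(self, state: SimState) -> tuple[SimState, list[ContactEvent]]:
        """Advance one state by exactly one timestep and classify contacts."""
        dt = self.config.sim_timestep
        p, v, bed_c, floor_c, unstable = self.step_arrays(state.positions, state.velocities)
        t_new = state.t + dt
        k = round(t_new / dt)
        if abs(k * dt - t_new) < 1e-12:  # keep the clock an exact step multiple
            t_new = k * dt
        new_state = SimState.from_positions(p, v, t=t_new)
        new_state.unstable = bool(unstable) or state.unstable
        return new_state, self.classify_contacts(bed_c, floor_c)

    def classify_contacts(
        self, bed_contact: np.ndarray, floor_contact: np.ndarray
    ) -> list[ContactEvent]:
        """Turn per-particle contact masks (13,) into classified events."""
        events: list[ContactEvent] = []
        for i, name in enumerate(humanoid.KEYPOINT_NAMES):
            if bed_contact[i]:
                events.append(ContactEvent(name, "bed", CONTACT_HUMANOID_BED))
            if floor_contact[i]:
                kind = CONTACT_HAND_FLOOR if self._hand_mask[i] else CONTACT_HUMANOID_FLOOR
                events.append(ContactEvent(name, "floor", kind))
        return events

    def freeze(self, state: SimState) -> SimState:
        """Zero all velocities (and controls) and reset the clock to t = 0.

        Positions are untouched; the kinematic pass is implicit because the
        state is already maximal-coordinate.
        """
        frozen = SimState(q=state.q.copy(), v=np.zeros_like(state.v), t=0.0)
        frozen.unstable = state.unstable
        return frozen

    # -- bookkeeping -------------------------------------------------------

    def manifest(self) -> dict:
        """Reproducibility record: geometry, integrator and contact settings."""
        cfg = self.config
        return {
            "engine": ENGINE_NAME,
            "engine_version": ENGINE_VERSION,
            "bed_extents_m": list(cfg.bed_extents),
            "bed_top_height_m": cfg.bed_top_height,
            "bed_bounds_m": list(self.bed_bounds),
            "sim_timestep_s": cfg.sim_timestep,
            "gravity_m_s2": cfg.gravity,
            "humanoid_model_id": cfg.humanoid_model_id,
            "hand_keypoints": list(cfg.hand_keypoints),
            "friction": cfg.friction,
            "solver_iterations": cfg.solver_iterations,
            "particle_radius_m": cfg.particle_radius,
            "velocity_damping": cfg.velocity_damping,
        }


def build_world(config: WorldConfig | None = None) -> World:
    """Build a steppable world: floor plane + box bed + one humanoid."""
    return World(config or WorldConfig())
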