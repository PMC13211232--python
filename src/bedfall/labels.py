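"""Discounted time-to-fall risk labels on a fixed 30 fps frame grid.

A fall first detected at simulator step ``s_f`` is mapped to the video-rate
frame index ``n_f = floor(F * s_f * dt_sim)`` and the episode observed at
step ``s`` receives the continuous label

    y = gamma ** (n_f - n(s))          if a fall occurs,
    y = 0                              otherwise,

with per-frame discount ``gamma`` in (0, 1).  Defining the discount on the
frame grid rather than on simulator steps makes the label independent of
the internal integrator frequency.  The label is a monotone exponential
transform of remaining time-to-fall: ``gamma**(n_f - n) = exp(-lambda * dt)``
with hazard rate ``lambda = -F * log(gamma)`` and ``dt = (n_f - n) / F``
seconds.  The main pipeline always observes the initial state (s = 0), so
fall labels lie in ``[gamma**(F*T), 1]`` for a window of T seconds.

Flooring is used for steps that do not land exactly on a frame boundary
(the frame index of the last completed frame); the alternative rounding
changes n by at most one frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .episodes import EpisodeOutcome


@dataclass(frozen=True)
class LabelConfig:
    """Risk-label settings: frame rate F, discount gamma, window T, dt_sim."""

    fps: float = 30.0
    gamma: float = 0.99
    sim_timestep: float = 1.0 / 60.0
    window: float = 3.0

    def validate(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie strictly inside (0, 1)")
        if self.fps <= 0 or self.window <= 0 or self.sim_timestep <= 0:
            raise ValueError("fps, window and sim_timestep must be positive")

    @property
    def max_frame(self) -> int:
        """Frame index of the window end, F*T on the frame grid."""
        return int(math.floor(self.fps * self.window + 1e-9))

    @property
    def min_fall_label(self) -> float:
        """Smallest possible fall label, gamma**(F*T)."""
        return self.gamma ** self.max_frame


def step_to_frame(s: int, config: LabelConfig) -> int:
    """Map simulator step index s to the 30 fps frame index floor(F*s*dt)."""
    if s < 0:
        raise ValueError("step index must be non-negative")
    # nudge by one ulp-scale epsilon so grid-aligned products do not floor down
    return int(math.floor(config.fps * s * config.sim_timestep + 1e-9))


def risk_label(outcome: "EpisodeOutcome", observe_step: int, config: LabelConfig) -> float:
    """Continuous risk label for an episode observed at ``observe_step``."""
    config.validate()
    if outcome.unstable:
        raise ValueError("unstable episodes carry no labels")
    if not outcome.fell:
        return 0.0
    if observe_step > outcome.fall_step:
        raise ValueError("observation after the fall is undefined")
    n_f = step_to_frame(outcome.fall_step, config)
    n_s = step_to_frame(observe_step, config)
    # float exponent keeps scalar and vectorized labeling bit-identical
    return config.gamma ** float(n_f - n_s)


def fall_labels_from_steps(fall_steps, fell, config: LabelConfig):
    """Vectorized initial-state labels (s = 0) from per-episode fall steps.

    ``fall_steps`` is an integer array (ignored where ``fell`` is false).
    """
    import numpy as np

    config.validate()
    fell = np.asarray(fell, bool)
    steps = np.asarray(fall_steps)
    n_f = np.floor(config.fps * steps * config.sim_timestep + 1e-9).astype(int)
    # scalar pow per unique frame keeps this bit-identical to risk_label
    # (numpy's vectorized power can differ from C pow in the last ulp)
    uniq, inv = np.unique(n_f, return_inverse=True)
    table = np.array([config.gamma ** float(e) for e in uniq])
    return np.where(fell, table[inv], 0.0)


def hazard_rate(config: LabelConfig) -> float:
    """Continuous-time hazard rate lambda = -F * ln(gamma), per second."""
    config.validate()
    return -config.fps * math.log(config.gamma)
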