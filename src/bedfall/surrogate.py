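"""Physics-free surrogate episode generator.

Emulates the statistical structure of simulated episodes so models, the
evaluator and dataset I/O are testable in seconds without the engine: each
record is a coherent 13-keypoint skeleton in bed-normalized coordinates
whose fall risk is a deterministic function of its proximity to the bed
edges.  A skeleton "falls" iff its minimum signed distance to the nearest
edge of the unit square drops below a cutoff; the fall frame grows with
that distance, so the discounted label decreases monotonically as the body
moves inward.  Labels go through the real risk labeler, hence they obey
every label invariant (non-falls exactly 0, falls in [gamma^(F*T), 1]).

The surrogate mirrors what a static in-bed skeleton is believed to encode
about fall risk — edge proximity of major body segments — while remaining
analytically controllable; it makes no claim of physical realism and does
not match the engine's pose distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import humanoid
from .datasets import SCHEMA_COLUMNS
from .episodes import EpisodeOutcome, N_SEQUENCE_FRAMES
from .labels import LabelConfig, risk_label
from .sampling import MODES
from .skeleton import FEATURE_COLUMNS, VALIDITY_COLUMNS


@dataclass(frozen=True)
class SurrogateConfig:
    """Surrogate generation settings.

    ``edge_cutoff`` is the normalized edge distance below which an episode
    falls; ``orientation_sd_deg`` controls planar rotation diversity around
    the two bed-aligned headings; ``noise_sd`` jitters keypoints in
    normalized units before the risk rule is applied (so the stored label
    is still an exact function of the stored features).
    """

    n_samples: int = 1000
    edge_cutoff: float = 0.15
    orientation_sd_deg: float = 25.0
    center_half_range: tuple[float, float] = (0.8, 0.4)  # normalized x, y
    bed_half_extents: tuple[float, float] = (1.0, 0.45)  # meters
    template_scale: float = 0.7  # body size relative to the simulator template
    noise_sd: float = 0.01
    balanced: bool = False
    label: LabelConfig = field(default_factory=LabelConfig)
    seed: int = 0


def _skeletons(rng: np.random.Generator, n: int, config: SurrogateConfig) -> np.ndarray:
    """Coherent skeletons (n, 13, 2) in normalized bed coordinates."""
    template = config.template_scale * humanoid.TEMPLATE_OFFSETS[:, :2]  # meters, body along +x
    theta = np.deg2rad(rng.normal(0.0, config.orientation_sd_deg, size=n))
    theta += np.pi * rng.integers(0, 2, size=n)  # random head direction
    cos, sin = np.cos(theta), np.sin(theta)
    rot = np.stack([np.stack([cos, -sin], -1), np.stack([sin, cos], -1)], -2)
    pts = np.einsum("nij,kj->nki", rot, template)
    hx, hy = config.bed_half_extents
    cx, cy = config.center_half_range
    center = np.column_stack(
        [rng.uniform(-cx * hx, cx * hx, n), rng.uniform(-cy * hy, cy * hy, n)]
    )
    pts = pts + center[:, None, :]
    norm = pts / np.array([hx, hy])  # bed footprint -> unit square
    norm += rng.normal(0.0, config.noise_sd, size=norm.shape)
    return norm


def _risk_rule(norm: np.ndarray, config: SurrogateConfig) -> tuple[np.ndarray, np.ndarray]:
    """(fell, fall_frame) from the minimum signed edge distance of each body."""
    d = np.minimum(1.0 - np.abs(norm[..., 0]), 1.0 - np.abs(norm[..., 1]))
    d_min = d.min(axis=-1)
    fell = d_min < config.edge_cutoff
    max_frame = config.label.max_frame
    frac = np.clip(d_min, 0.0, config.edge_cutoff) / config.edge_cutoff
    fall_frame = np.round(max_frame * frac).astype(int)
    return fell, fall_frame


def generate_surrogate(config: SurrogateConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a surrogate dataset (schema DataFrame, (n, 5, 26) frames).

    With ``balanced=True``, generation continues until exact class quotas
    (ceil(n/2) falls) are met, mirroring the simulate-until-quota protocol.
    Frames are static repeats of the single skeleton (the surrogate has no
    dynamics), which is the degenerate-but-valid sequence input.
    """
    rng = np.random.default_rng(config.seed)
    need = {1: math.ceil(config.n_samples / 2), 0: config.n_samples // 2}
    rows_u: list[np.ndarray] = []
    rows_meta: list[tuple] = []
    dt = config.label.sim_timestep
    steps_per_frame = max(1, int(round(1.0 / (config.label.fps * dt))))
    while True:
        n_left = need[0] + need[1] if config.balanced else config.n_samples - len(rows_meta)
        if n_left <= 0:
            break
        n_draw = max(256, 2 * n_left)
        norm = _skeletons(rng, n_draw, config)
        fell, fall_frame = _risk_rule(norm, config)
        for i in range(n_draw):
            label = int(fell[i])
            if config.balanced:
                if need[label] == 0:
                    continue
                need[label] -= 1
            outcome = EpisodeOutcome(
                fell=bool(fell[i]),
                fall_step=int(fall_frame[i]) * steps_per_frame if fell[i] else None,
                unstable=False,
            )
            y = risk_label(outcome, 0, config.label)
            inside = (np.abs(norm[i]) <= 1.0).all(axis=-1).astype(int)
            rows_u.append(norm[i].reshape(-1))
            rows_meta.append((MODES[int(rng.integers(4))].value, label, y, inside))
            if len(rows_meta) >= config.n_samples and not config.balanced:
                break
        if config.balanced and need[0] == 0 and need[1] == 0:
            break
    u = np.asarray(rows_u)
    data = {
        "mode": [m for m, _, _, _ in rows_meta],
        "c": [c for _, c, _, _ in rows_meta],
        "y": [y for _, _, y, _ in rows_meta],
    }
    for j, col in enumerate(FEATURE_COLUMNS):
        data[col] = u[:, j]
    validity = np.asarray([v for _, _, _, v in rows_meta])
    for j, col in enumerate(VALIDITY_COLUMNS):
        data[col] = validity[:, j]
    data["episode_seed"] = rng.integers(0, 2**31 - 1, size=len(rows_meta))
    df = pd.DataFrame(data, columns=SCHEMA_COLUMNS)
    frames = np.repeat(u[:, None, :], N_SEQUENCE_FRAMES, axis=1)
    return df, frames
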