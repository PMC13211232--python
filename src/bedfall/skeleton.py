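"""13-keypoint 2D skeleton extraction and bed-bounds normalization.

The simulator's particle anchors double as proxy anatomical keypoints.  A
raw skeleton is the planar (x, y) projection of the 13 anchors in the bed
frame, in the fixed order head, L/R shoulder, L/R elbow, L/R wrist,
L/R hip, L/R knee, L/R ankle.  Normalization maps the bed footprint
rectangle affinely onto [-1, 1]^2:

    x' = 2 * (x - x_min) / (x_max - x_min) - 1     (same for y)

Keypoints outside the footprint keep their affine image (values beyond
+-1) and are flagged invalid (v_k = 0).  The flattened feature vector u
interleaves coordinates as (x'_1, y'_1, ..., x'_13, y'_13), length 26; the
regressors consume u only, the flags are stored for quality control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import humanoid
from .world import SimState, World

N_FEATURES = 2 * humanoid.N_KEYPOINTS  # 26

FEATURE_COLUMNS = [f"u_{i:02d}" for i in range(N_FEATURES)]
VALIDITY_COLUMNS = [f"v_{i:02d}" for i in range(humanoid.N_KEYPOINTS)]


@dataclass(frozen=True)
class BedBounds:
    """Bed top-face footprint rectangle in meters."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def validate(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate bed bounds")

    @classmethod
    def from_world(cls, world: World) -> "BedBounds":
        return cls(*world.bed_bounds)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.x_max, self.y_min, self.y_max)


def extract_keypoints(world: World, state: SimState) -> np.ndarray:
    """Raw skeleton: planar projection of the anchors, shape (13, 2)."""
    if not np.isfinite(state.q).all():
        raise ValueError("cannot extract keypoints from a non-finite state")
    return state.positions[:, :2].copy()


def normalize(raw: np.ndarray, bounds: BedBounds) -> tuple[np.ndarray, np.ndarray]:
    """Normalize raw keypoints (..., 13, 2) to bed-centric [-1, 1] coordinates.

    Returns ``(normalized, validity)`` where validity is a {0, 1} integer
    array (..., 13); a keypoint is valid iff both raw coordinates lie inside
    the bed bounds.
    """
    bounds.validate()
    raw = np.asarray(raw, float)
    lo = np.array([bounds.x_min, bounds.y_min])
    hi = np.array([bounds.x_max, bounds.y_max])
    norm = 2.0 * (raw - lo) / (hi - lo) - 1.0
    inside = (raw >= lo) & (raw <= hi)
    validity = inside.all(axis=-1).astype(int)
    return norm, validity


def denormalize(norm: np.ndarray, bounds: BedBounds) -> np.ndarray:
    """Exact inverse of :func:`normalize` (the affine map is a bijection)."""
    bounds.validate()
    norm = np.asarray(norm, float)
    lo = np.array([bounds.x_min, bounds.y_min])
    hi = np.array([bounds.x_max, bounds.y_max])
    return (norm + 1.0) / 2.0 * (hi - lo) + lo


def flatten(skel: np.ndarray) -> np.ndarray:
    """Flatten (..., 13, 2) normalized keypoints to the 26-vector u."""
    skel = np.asarray(skel, float)
    if skel.shape[-2:] != (humanoid.N_KEYPOINTS, 2):
        raise ValueError(f"expected (..., 13, 2) skeleton, got {skel.shape}")
    return skel.reshape(skel.shape[:-2] + (N_FEATURES,))


def unflatten(u: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    u = np.asarray(u, float)
    if u.shape[-1] != N_FEATURES:
        raise ValueError(f"expected (..., {N_FEATURES}) feature vector, got {u.shape}")
    return u.reshape(u.shape[:-1] + (humanoid.N_KEYPOINTS, 2))


def features_from_state(world: World, state: SimState, bounds: BedBounds | None = None):
    """Convenience: state -> (u, validity) in one call."""
    bounds = bounds or BedBounds.from_world(world)
    norm, validity = normalize(extract_keypoints(world, state), bounds)
    return flatten(norm), validity
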