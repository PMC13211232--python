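"""Small batched quaternion helpers.

Quaternions are stored as ``(w, x, y, z)`` arrays; all functions broadcast
over leading axes. Euler conversions go through :mod:`scipy.spatial.transform`
using the package-wide extrinsic ``xyz`` convention (roll about the world
x axis, then pitch about y, then yaw about z).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "xyz"  # extrinsic roll-pitch-yaw; recorded in run manifests


def quat_from_euler_deg(euler_deg: np.ndarray) -> np.ndarray:
    """Convert Euler angles in degrees (..., 3) to unit quaternions (..., 4)."""
    r = Rotation.from_euler(EULER_CONVENTION, np.asarray(euler_deg, float), degrees=True)
    q = r.as_quat()  # scipy order (x, y, z, w)
    return np.roll(q, 1, axis=-1)


def euler_deg_from_quat(q: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quat_from_euler_deg`."""
    r = Rotation.from_quat(np.roll(np.asarray(q, float), -1, axis=-1))
    return r.as_euler(EULER_CONVENTION, degrees=True)


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product, broadcasting over leading axes."""
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_apply(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors v (..., 3) by quaternions q (..., 4)."""
    q = np.asarray(q, float)
    v = np.asarray(v, float)
    u = q[..., 1:]
    w = q[..., :1]
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def quat_slerp(a: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    """Spherical-linear interpolation between unit quaternions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    dot = np.sum(a * b, axis=-1, keepdims=True)
    b = np.where(dot < 0, -b, b)  # shortest arc
    dot = np.abs(np.clip(dot, -1.0, 1.0))
    theta = np.arccos(dot)
    sin_theta = np.sin(theta)
    small = sin_theta < 1e-9
    w_a = np.where(small, 1.0 - alpha, np.sin((1.0 - alpha) * theta) / np.where(small, 1.0, sin_theta))
    w_b = np.where(small, alpha, np.sin(alpha * theta) / np.where(small, 1.0, sin_theta))
    return quat_normalize(w_a * a + w_b * b)


def quat_from_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` radians about a unit axis."""
    angle = np.asarray(angle, float)
    axis = np.asarray(axis, float)
    half = angle / 2.0
    w = np.cos(half)[..., None]
    xyz = axis * np.sin(half)[..., None]
    return np.concatenate([w, xyz], axis=-1)


def random_unit_quat(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Quaternions uniform on SO(3) (normalized 4D Gaussians)."""
    shape = (4,) if n is None else (n, 4)
    g = rng.standard_normal(shape)
    return quat_normalize(g)
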