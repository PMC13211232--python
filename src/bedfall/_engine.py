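"""JIT-compiled PBD integration kernel.

One semi-implicit step of the articulated-particle system for a batch of
independent episodes: gravity integration, Gauss-Seidel projection of the
bone distance constraints, unilateral bed/floor contacts, tangential
friction.  Rows where ``active`` is false are skipped untouched, which lets
batched episode generation stop finished episodes without extra copies.
The scalar arithmetic is identical for every row, so a batch of one
reproduces a full batch row bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pbd_step(
    pos,  # (B, 13, 3) in/out
    vel,  # (B, 13, 3) in/out
    active,  # (B,) bool
    bed_contact,  # (B, 13) bool, out
    floor_contact,  # (B, 13) bool, out
    unstable,  # (B,) bool, out
    bones_i,
    bones_j,
    bones_rest,
    inv_mass,
    dt,
    gravity,
    damping,
    friction,
    x_half,
    y_half,
    surf,  # bed top + particle radius
    radius,
    n_iter,
):
    B, K, _ = pos.shape
    n_bones = bones_i.shape[0]
    for b in range(B):
        if not active[b]:
            continue
        # predict
        prev_above = np.empty(K, np.bool_)
        p = np.empty((K, 3))
        for k in range(K):
            prev_above[k] = pos[b, k, 2] >= surf - 1e-9
            vz = (vel[b, k, 2] - gravity * dt) * (1.0 - damping)
            vx = vel[b, k, 0] * (1.0 - damping)
            vy = vel[b, k, 1] * (1.0 - damping)
            p[k, 0] = pos[b, k, 0] + vx * dt
            p[k, 1] = pos[b, k, 1] + vy * dt
            p[k, 2] = pos[b, k, 2] + vz * dt
            bed_contact[b, k] = False
            floor_contact[b, k] = False
        # solve
        for _ in range(n_iter):
            for e in range(n_bones):
                i = bones_i[e]
                j = bones_j[e]
                dx = p[i, 0] - p[j, 0]
                dy = p[i, 1] - p[j, 1]
                dz = p[i, 2] - p[j, 2]
                dist = np.sqrt(dx * dx + dy * dy + dz * dz)
                denom = dist if dist > 1e-12 else 1e-12
                c = (dist - bones_rest[e]) / denom
                wi = inv_mass[i] / (inv_mass[i] + inv_mass[j])
                wj = 1.0 - wi
                p[i, 0] -= wi * c * dx
                p[i, 1] -= wi * c * dy
                p[i, 2] -= wi * c * dz
                p[j, 0] += wj * c * dx
                p[j, 1] += wj * c * dy
                p[j, 2] += wj * c * dz
            for k in range(K):
                if p[k, 2] < radius:
                    p[k, 2] = radius
                    floor_contact[b, k] = True
                if (
                    prev_above[k]
                    and p[k, 2] < surf
                    and -x_half <= p[k, 0] <= x_half
                    and -y_half <= p[k, 1] <= y_half
                ):
                    p[k, 2] = surf
                    bed_contact[b, k] = True
        # velocity update + friction
        ok = True
        for k in range(K):
            nvx = (p[k, 0] - pos[b, k, 0]) / dt
            nvy = (p[k, 1] - pos[b, k, 1]) / dt
            nvz = (p[k, 2] - pos[b, k, 2]) / dt
            if bed_contact[b, k] or floor_contact[b, k]:
                nvx *= 1.0 - friction
                nvy *= 1.0 - friction
                if nvz < 0.0:
                    nvz = 0.0
            pos[b, k, 0] = p[k, 0]
            pos[b, k, 1] = p[k, 1]
            pos[b, k, 2] = p[k, 2]
            vel[b, k, 0] = nvx
            vel[b, k, 1] = nvy
            vel[b, k, 2] = nvz
            for a in range(3):
                if not (np.isfinite(pos[b, k, a]) and np.isfinite(vel[b, k, a])):
                    ok = False
                if np.abs(pos[b, k, a]) >= 50.0:
                    ok = False
        unstable[b] = not ok
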