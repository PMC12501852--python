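"""Independent brute-force ray caster used as a rendering oracle.

Per-pixel scalar math, no shared code with the package renderer: for
each pixel the closest sphere hit decides visibility, and each sphere's
solo hit test gives its amodal mask.  Deliberately slow and simple.
"""

import math

import numpy as np


def _basis(position, target):
    fx = target[0] - position[0]
    fy = target[1] - position[1]
    fz = target[2] - position[2]
    n = math.sqrt(fx * fx + fy * fy + fz * fz)
    f = (fx / n, fy / n, fz / n)
    up = (0.0, 0.0, 1.0)
    if abs(f[0] * up[0] + f[1] * up[1] + f[2] * up[2]) > 0.999:
        up = (1.0, 0.0, 0.0)
    rx = f[1] * up[2] - f[2] * up[1]
    ry = f[2] * up[0] - f[0] * up[2]
    rz = f[0] * up[1] - f[1] * up[0]
    n = math.sqrt(rx * rx + ry * ry + rz * rz)
    r = (rx / n, ry / n, rz / n)
    d = (f[1] * r[2] - f[2] * r[1],
         f[2] * r[0] - f[0] * r[2],
         f[0] * r[1] - f[1] * r[0])
    return f, r, d


def _sphere_hit(origin, direction, center, radius):
    """Smallest positive ray parameter, or None."""
    ox = origin[0] - center[0]
    oy = origin[1] - center[1]
    oz = origin[2] - center[2]
    b = direction[0] * ox + direction[1] * oy + direction[2] * oz
    c = ox * ox + oy * oy + oz * oz - radius * radius
    disc = b * b - c
    if disc <= 0:
        return None
    sq = math.sqrt(disc)
    t = -b - sq
    if t <= 1e-6:
        t = -b + sq
    return t if t > 1e-6 else None


def brute_force_masks(camera, spheres):
    """Visible id buffer and per-sphere amodal masks via per-pixel loops.

    ``camera``: object with position/target/focal/cx/cy/width/height;
    ``spheres``: list of (center, radius).  Returns (idbuf, amodal list)
    with ids 1-based, 0 = background.
    """
    f, r, d = _basis(camera.position, camera.target)
    H, W = camera.height, camera.width
    idbuf = np.zeros((H, W), dtype=np.int32)
    amodal = [np.zeros((H, W), dtype=bool) for _ in spheres]
    for row in range(H):
        v = (row + 0.5 - camera.cy) / camera.focal
        for col in range(W):
            u = (col + 0.5 - camera.cx) / camera.focal
            dx = f[0] + u * r[0] + v * d[0]
            dy = f[1] + u * r[1] + v * d[1]
            dz = f[2] + u * r[2] + v * d[2]
            n = math.sqrt(dx * dx + dy * dy + dz * dz)
            direction = (dx / n, dy / n, dz / n)
            best_t, best_k = math.inf, 0
            for k, (center, radius) in enumerate(spheres):
                t = _sphere_hit(camera.position, direction, center, radius)
                if t is None:
                    continue
                amodal[k][row, col] = True
                if t < best_t:
                    best_t, best_k = t, k + 1
            idbuf[row, col] = best_k
    return idbuf, amodal
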