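"""Optional numba-compiled inner loops.

The pure-numpy paths in :mod:`cgcph.energetics` are the reference
implementation; when numba is importable these kernels replace the
Lennard-Jones pair loop (the dominant cost for solvated systems) with
identical arithmetic.  Import of this module never fails: ``HAS_NUMBA``
tells the caller which path is live.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAS_NUMBA = True
except ImportError:  # pragma: no cover - environment without numba
    HAS_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def lj_switch_pairs(pos, ii, jj, sig, eps, box, r_s, r_c, forces):
    """Switched LJ over an explicit pair list; accumulates forces in
    place and returns (energy, min_r2_seen)."""
    energy = 0.0
    min_r2 = 1e30
    rc2 = r_c * r_c
    inv_span = 1.0 / (r_c - r_s)
    for m in range(len(ii)):
        i = ii[m]
        j = jj[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < min_r2:
            min_r2 = r2
        r = np.sqrt(r2)
        s6 = (sig[m] * sig[m] / r2) ** 3
        u = 4.0 * eps[m] * (s6 * s6 - s6)
        du = 24.0 * eps[m] * (s6 - 2.0 * s6 * s6) / r
        if r <= r_s:
            sw = 1.0
            dsw = 0.0
        else:
            x = (r - r_s) * inv_span
            sw = 1.0 - x * x * (3.0 - 2.0 * x)
            dsw = -6.0 * x * (1.0 - x) * inv_span
        energy += u * sw
        fmag = -(du * sw + u * dsw) / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, min_r2
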