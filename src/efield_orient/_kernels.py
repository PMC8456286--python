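"""Compiled inner loop of the Langevin rotor integrator.

The kernel advances a batch of replicas by a block of steps; the Python
driver in :mod:`efield_orient.rotor` supplies the pre-evaluated field
strengths at the step boundaries and the pre-drawn Gaussian noise for the
block (so all randomness flows through one seeded numpy Generator), and
records observables between blocks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["advance_block"]


@njit(cache=True, fastmath=False)
def _rotate(w, x, y, z, vx, vy, vz):
    # rotate v by unit quaternion (w, x, y, z): body -> lab
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    rx = vx + w * tx + (y * tz - z * ty)
    ry = vy + w * ty + (z * tx - x * tz)
    rz = vz + w * tz + (x * ty - y * tx)
    return rx, ry, rz


@njit(cache=True, fastmath=False)
def _free_rotate(q, l, I, r, h):
    # axis-splitting free-rotor propagator: halves about axes 2,1, full
    # about 0, halves about 1,2.  Conserves lab angular momentum exactly.
    for sub in range(5):
        if sub == 0 or sub == 4:
            k = 2
            hh = 0.5 * h
        elif sub == 1 or sub == 3:
            k = 1
            hh = 0.5 * h
        else:
            k = 0
            hh = h
        a = (k + 1) % 3
        b = (k + 2) % 3
        phi = l[r, k] / I[k] * hh
        c = np.cos(phi)
        s = np.sin(phi)
        la = l[r, a] * c + l[r, b] * s
        lb = -l[r, a] * s + l[r, b] * c
        l[r, a] = la
        l[r, b] = lb
        ch = np.cos(0.5 * phi)
        sh = np.sin(0.5 * phi)
        w = q[r, 0]
        x = q[r, 1]
        y = q[r, 2]
        z = q[r, 3]
        if k == 0:
            q[r, 0] = w * ch - x * sh
            q[r, 1] = w * sh + x * ch
            q[r, 2] = y * ch + z * sh
            q[r, 3] = z * ch - y * sh
        elif k == 1:
            q[r, 0] = w * ch - y * sh
            q[r, 1] = x * ch - z * sh
            q[r, 2] = w * sh + y * ch
            q[r, 3] = z * ch + x * sh
        else:
            q[r, 0] = w * ch - z * sh
            q[r, 1] = x * ch + y * sh
            q[r, 2] = y * ch - x * sh
            q[r, 3] = w * sh + z * ch


@njit(cache=True, fastmath=False)
def _kick(q, l, r, mu_conv, f_dir, e, half_dt):
    # half torque kick: l += R^T (R mu x E) * dt/2, with CONV folded into mu
    mx, my, mz = _rotate(
        q[r, 0], q[r, 1], q[r, 2], q[r, 3], mu_conv[0], mu_conv[1], mu_conv[2]
    )
    ex = e * f_dir[0]
    ey = e * f_dir[1]
    ez = e * f_dir[2]
    tx = my * ez - mz * ey
    ty = mz * ex - mx * ez
    tz = mx * ey - my * ex
    # lab -> body with the conjugate quaternion
    bx, by, bz = _rotate(q[r, 0], -q[r, 1], -q[r, 2], -q[r, 3], tx, ty, tz)
    l[r, 0] += bx * half_dt
    l[r, 1] += by * half_dt
    l[r, 2] += bz * half_dt


@njit(cache=True, fastmath=False)
def advance_block(
    q, l, I, mu_conv, f_dir, e_vals, dt, c1, noise_sd, noise,
    use_field, use_ou, use_noise,
):
    """Advance all replicas by ``len(e_vals) - 1`` steps in place.

    q : (n, 4) unit quaternions, scalar first.  l : (n, 3) body-frame
    angular momenta.  e_vals : field strength at the step boundaries.
    noise : (steps, n, 3) standard normals (ignored when use_ou is False
    or noise_sd is all zero).
    """
    n = q.shape[0]
    n_steps = e_vals.shape[0] - 1
    half_dt = 0.5 * dt
    for i in range(n_steps):
        for r in range(n):
            if use_field:
                _kick(q, l, r, mu_conv, f_dir, e_vals[i], half_dt)
            _free_rotate(q, l, I, r, half_dt)
            if use_ou:
                for a in range(3):
                    l[r, a] = c1 * l[r, a]
                    if use_noise:
                        l[r, a] += noise_sd[a] * noise[i, r, a]
            _free_rotate(q, l, I, r, half_dt)
            norm = np.sqrt(
                q[r, 0] ** 2 + q[r, 1] ** 2 + q[r, 2] ** 2 + q[r, 3] ** 2
            )
            q[r, 0] /= norm
            q[r, 1] /= norm
            q[r, 2] /= norm
            q[r, 3] /= norm
            if use_field:
                _kick(q, l, r, mu_conv, f_dir, e_vals[i + 1], half_dt)
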