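"""Numba inner loops for the delayed-oscillator integrators.

Both kernels implement the stochastic Heun scheme on networks with
heterogeneous, integer-step coupling delays.  Delayed states are read from a
circular history buffer whose length is one more than the largest delay, so a
slot can be overwritten exactly when it falls out of the delay horizon.  For
the phase model the buffer stores sin/cos of the phases rather than the phases
themselves, which turns the pairwise coupling term

    sin(phi_n(t - tau_jn) - phi_j(t))
        = cos(phi_j) * sin(phi_n_delayed) - sin(phi_j) * cos(phi_n_delayed)

into two multiply-adds per connection instead of a trigonometric call.

The additive noise increment for step m is supplied pre-drawn as ``noise[m]``
(already scaled by sqrt(dt) or dt, per the caller's convention) so that all
randomness is owned by numpy Generators outside the jitted code.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def integrate_phase(two_pi_f, w, dsteps, cn, dt, n_steps, n_transient,
                    noise, phi0):
    """Delayed Kuramoto network; returns sin(phi) after the transient.

    Parameters are raw arrays: ``two_pi_f`` (N,), ``w`` (N, N) with zero
    diagonal, ``dsteps`` (N, N) integer delay steps, ``cn`` the coupling C/N,
    ``noise`` (n_steps, N) pre-scaled increments, ``phi0`` (N,) initial phases.
    """
    N = two_pi_f.shape[0]
    max_d = 0
    for j in range(N):
        for n in range(N):
            if dsteps[j, n] > max_d:
                max_d = dsteps[j, n]
    H = max_d + 1
    sb = np.empty((H, N))
    cb = np.empty((H, N))
    for j in range(N):
        s = np.sin(phi0[j])
        c = np.cos(phi0[j])
        for h in range(H):
            sb[h, j] = s
            cb[h, j] = c
    phi = phi0.copy()
    sin_cur = np.sin(phi0)
    cos_cur = np.cos(phi0)
    k1 = np.empty(N)
    pred = np.empty(N)
    sp = np.empty(N)
    cp = np.empty(N)
    out = np.empty((n_steps - n_transient, N))
    for m in range(n_steps):
        base = m % H
        for j in range(N):
            acc_s = 0.0
            acc_c = 0.0
            for n in range(N):
                wjn = w[j, n]
                if wjn != 0.0:
                    slot = base - dsteps[j, n]
                    if slot < 0:
                        slot += H
                    acc_s += wjn * sb[slot, n]
                    acc_c += wjn * cb[slot, n]
            k1[j] = two_pi_f[j] + cn * (cos_cur[j] * acc_s - sin_cur[j] * acc_c)
        for j in range(N):
            pred[j] = phi[j] + dt * k1[j]
            sp[j] = np.sin(pred[j])
            cp[j] = np.cos(pred[j])
        base1 = base + 1
        if base1 == H:
            base1 = 0
        for j in range(N):
            acc_s = 0.0
            acc_c = 0.0
            for n in range(N):
                wjn = w[j, n]
                if wjn != 0.0:
                    d = dsteps[j, n]
                    if d == 0:
                        acc_s += wjn * sp[n]
                        acc_c += wjn * cp[n]
                    else:
                        slot = base1 - d
                        if slot < 0:
                            slot += H
                        acc_s += wjn * sb[slot, n]
                        acc_c += wjn * cb[slot, n]
            k2 = two_pi_f[j] + cn * (cp[j] * acc_s - sp[j] * acc_c)
            phi[j] = phi[j] + 0.5 * dt * (k1[j] + k2) + noise[m, j]
        for j in range(N):
            s = np.sin(phi[j])
            c = np.cos(phi[j])
            sin_cur[j] = s
            cos_cur[j] = c
            sb[base1, j] = s
            cb[base1, j] = c
        if m >= n_transient:
            for j in range(N):
                out[m - n_transient, j] = sin_cur[j]
    return out


@njit(cache=True, fastmath=True)
def integrate_hopf(a, two_pi_f, w, dsteps, cn, dt, n_steps, n_transient,
                   noise_x, noise_y, x0, y0):
    """Delayed Hopf normal-form (limit-cycle) network.

    Returns ``(out, status)`` where ``out`` holds Re(z) after the transient and
    ``status`` is -1 on success or the step index at which the state became
    non-finite or left a large bounding radius.
    """
    N = a.shape[0]
    max_d = 0
    for j in range(N):
        for n in range(N):
            if dsteps[j, n] > max_d:
                max_d = dsteps[j, n]
    H = max_d + 1
    xb = np.empty((H, N))
    yb = np.empty((H, N))
    for j in range(N):
        for h in range(H):
            xb[h, j] = x0[j]
            yb[h, j] = y0[j]
    x = x0.copy()
    y = y0.copy()
    wsum = np.empty(N)
    for j in range(N):
        s = 0.0
        for n in range(N):
            s += w[j, n]
        wsum[j] = s
    k1x = np.empty(N)
    k1y = np.empty(N)
    px = np.empty(N)
    py = np.empty(N)
    out = np.empty((n_steps - n_transient, N))
    for m in range(n_steps):
        base = m % H
        for j in range(N):
            accx = 0.0
            accy = 0.0
            for n in range(N):
                wjn = w[j, n]
                if wjn != 0.0:
                    slot = base - dsteps[j, n]
                    if slot < 0:
                        slot += H
                    accx += wjn * xb[slot, n]
                    accy += wjn * yb[slot, n]
            r2 = x[j] * x[j] + y[j] * y[j]
            lin = a[j] - r2
            k1x[j] = lin * x[j] - two_pi_f[j] * y[j] + cn * (accx - wsum[j] * x[j])
            k1y[j] = lin * y[j] + two_pi_f[j] * x[j] + cn * (accy - wsum[j] * y[j])
        for j in range(N):
            px[j] = x[j] + dt * k1x[j]
            py[j] = y[j] + dt * k1y[j]
        base1 = base + 1
        if base1 == H:
            base1 = 0
        for j in range(N):
            accx = 0.0
            accy = 0.0
            for n in range(N):
                wjn = w[j, n]
                if wjn != 0.0:
                    d = dsteps[j, n]
                    if d == 0:
                        accx += wjn * px[n]
                        accy += wjn * py[n]
                    else:
                        slot = base1 - d
                        if slot < 0:
                            slot += H
                        accx += wjn * xb[slot, n]
                        accy += wjn * yb[slot, n]
            r2 = px[j] * px[j] + py[j] * py[j]
            lin = a[j] - r2
            k2x = lin * px[j] - two_pi_f[j] * py[j] + cn * (accx - wsum[j] * px[j])
            k2y = lin * py[j] + two_pi_f[j] * px[j] + cn * (accy - wsum[j] * py[j])
            x[j] = x[j] + 0.5 * dt * (k1x[j] + k2x) + noise_x[m, j]
            y[j] = y[j] + 0.5 * dt * (k1y[j] + k2y) + noise_y[m, j]
        bad = False
        for j in range(N):
            r2 = x[j] * x[j] + y[j] * y[j]
            if not np.isfinite(r2) or r2 > 1e12:
                bad = True
            xb[base1, j] = x[j]
            yb[base1, j] = y[j]
        if bad:
            return out, m
        if m >= n_transient:
            for j in range(N):
                out[m - n_transient, j] = x[j]
    return out, -1
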