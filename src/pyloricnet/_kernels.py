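"""Numba-compiled integration kernels.

All hot loops live here: plain fixed-step integration of the fast neural
subsystem, and co-integration of the fast states with the slow regulated
biases.  Everything operates on raw float64 arrays; the object-level API
wraps these in :mod:`pyloricnet.ctrnn` and :mod:`pyloricnet.adhp`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rk4_record", "adhp_record", "adhp_batch_final"]


@njit(cache=True, inline="always", fastmath=True, error_model="numpy")
def _deriv(y, inv_tau, theta, w, out, o):
    n = y.size
    for i in range(n):
        o[i] = 1.0 / (1.0 + np.exp(-(y[i] + theta[i])))
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += w[i, j] * o[j]
        out[i] = inv_tau[i] * (s - y[i])


@njit(cache=True, inline="always", fastmath=True, error_model="numpy")
def _step(y, inv_tau, theta, w, dt, euler, k1, k2, k3, k4, yt, o):
    n = y.size
    _deriv(y, inv_tau, theta, w, k1, o)
    if euler:
        for i in range(n):
            y[i] += dt * k1[i]
        return
    for i in range(n):
        yt[i] = y[i] + 0.5 * dt * k1[i]
    _deriv(yt, inv_tau, theta, w, k2, o)
    for i in range(n):
        yt[i] = y[i] + 0.5 * dt * k2[i]
    _deriv(yt, inv_tau, theta, w, k3, o)
    for i in range(n):
        yt[i] = y[i] + dt * k3[i]
    _deriv(yt, inv_tau, theta, w, k4, o)
    for i in range(n):
        y[i] += (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True, fastmath=True, error_model="numpy")
def rk4_record(y0, tau, theta, w, dt, n_transient, n_record, euler):
    """Integrate the frozen-parameter network, recording post-transient states.

    Sample ``k`` of the returned array is the state at ``t = (n_transient+k)*dt``
    (the first recorded sample falls exactly at the end of the transient).
    """
    n = y0.size
    y = y0.copy()
    inv_tau = 1.0 / tau
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    osc = np.empty(n)
    states = np.empty((n_record, n))
    total = n_transient + n_record
    for k in range(total):
        if k >= n_transient:
            for i in range(n):
                states[k - n_transient, i] = y[i]
        if k < total - 1 or n_record == 0:
            _step(y, inv_tau, theta, w, dt, euler, k1, k2, k3, k4, yt, osc)
    return states


@njit(cache=True, fastmath=True, error_model="numpy")
def adhp_record(
    y0,
    tau,
    theta0,
    w,
    dt,
    n_steps,
    reg,
    lb,
    ub,
    inv_tau_theta,
    win_n,
    theta_lo,
    theta_hi,
    record_every,
    settle_window_rec,
    settle_tol,
    check_every_rec,
):
    """Co-integrate fast states and slow regulated biases.

    Fast states advance by RK4 with biases frozen within the step; regulated
    biases then move by one forward-Euler step of rho(<o>_s)/tau_theta and are
    hard-clipped to [theta_lo, theta_hi].  The sliding average uses a ring
    buffer of ``win_n`` samples per regulated neuron; while the buffer warms
    up the average is taken over the samples available so far (win_n <= 1
    means instantaneous output).

    Biases and outputs are recorded every ``record_every`` steps.  If
    ``settle_tol > 0``, the run stops early once every regulated bias has
    stayed within ``settle_tol`` over the trailing ``settle_window_rec``
    recorded samples (checked every ``check_every_rec`` records).

    Returns (t_rec, theta_rec, o_rec, n_rec, y, theta, settled_at) where
    ``settled_at`` is the early-exit time in seconds or -1.0.
    """
    n = y0.size
    nr = reg.size
    y = y0.copy()
    theta = theta0.copy()
    inv_tau = 1.0 / tau
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    osc = np.empty(n)

    maxw = 1
    for j in range(nr):
        if win_n[j] > maxw:
            maxw = win_n[j]
    buf = np.zeros((nr, maxw))
    bsum = np.zeros(nr)
    bcnt = np.zeros(nr, np.int64)
    bpos = np.zeros(nr, np.int64)

    n_rec_max = n_steps // record_every + 1
    t_rec = np.empty(n_rec_max)
    theta_rec = np.empty((n_rec_max, nr))
    o_rec = np.empty((n_rec_max, n))
    rec_i = 0
    settled_at = -1.0

    for k in range(n_steps):
        if k % record_every == 0:
            t_rec[rec_i] = k * dt
            for j in range(nr):
                theta_rec[rec_i, j] = theta[reg[j]]
            for i in range(n):
                o_rec[rec_i, i] = 1.0 / (1.0 + np.exp(-(y[i] + theta[i])))
            rec_i += 1
            if (
                settle_tol > 0.0
                and rec_i >= settle_window_rec
                and rec_i % check_every_rec == 0
            ):
                quiet = True
                for j in range(nr):
                    lo = theta_rec[rec_i - settle_window_rec, j]
                    hi = lo
                    for m in range(rec_i - settle_window_rec + 1, rec_i):
                        v = theta_rec[m, j]
                        if v < lo:
                            lo = v
                        if v > hi:
                            hi = v
                    if hi - lo >= settle_tol:
                        quiet = False
                        break
                if quiet:
                    settled_at = k * dt
                    break

        _step(y, inv_tau, theta, w, dt, False, k1, k2, k3, k4, yt, osc)

        for j in range(nr):
            i = reg[j]
            o_i = 1.0 / (1.0 + np.exp(-(y[i] + theta[i])))
            if win_n[j] <= 1:
                avg = o_i
            else:
                if bcnt[j] < win_n[j]:
                    bsum[j] += o_i
                    buf[j, bpos[j]] = o_i
                    bcnt[j] += 1
                else:
                    bsum[j] += o_i - buf[j, bpos[j]]
                    buf[j, bpos[j]] = o_i
                bpos[j] = (bpos[j] + 1) % win_n[j]
                avg = bsum[j] / bcnt[j]
            if avg < lb[j]:
                drive = lb[j] - avg
            elif avg > ub[j]:
                drive = ub[j] - avg
            else:
                drive = 0.0
            t_new = theta[i] + dt * drive * inv_tau_theta[j]
            if t_new < theta_lo:
                t_new = theta_lo
            elif t_new > theta_hi:
                t_new = theta_hi
            theta[i] = t_new

    if settled_at < 0.0 and rec_i < n_rec_max:
        # record the terminal sample when the loop ran to completion
        t_rec[rec_i] = n_steps * dt
        for j in range(nr):
            theta_rec[rec_i, j] = theta[reg[j]]
        for i in range(n):
            o_rec[rec_i, i] = 1.0 / (1.0 + np.exp(-(y[i] + theta[i])))
        rec_i += 1

    return t_rec, theta_rec, o_rec, rec_i, y, theta, settled_at


@njit(cache=True, fastmath=True, error_model="numpy")
def adhp_batch_final(
    y0,
    tau,
    theta0,
    w,
    dt,
    n_equil,
    n_steps,
    reg,
    lb,
    ub,
    inv_tau_theta,
    theta_lo,
    theta_hi,
    check_every,
    settle_window_checks,
    settle_tol,
):
    """Batched regulation with instantaneous activity detection (no window).

    Integrates B independent copies of the network (rows of ``y0`` /
    ``theta0``) through ``n_equil`` frozen steps followed by ``n_steps``
    regulated steps.  No trajectories are recorded; members whose regulated
    biases stay within ``settle_tol`` over the trailing
    ``settle_window_checks`` snapshots (taken every ``check_every`` steps)
    are frozen early.  Returns (theta_final, y_final, settled_at).
    """
    B, n = y0.shape
    nr = reg.size
    y = y0.copy()
    theta = theta0.copy()
    inv_tau = 1.0 / tau
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    osc = np.empty(n)
    active = np.ones(B, np.bool_)
    settled_at = np.full(B, -1.0)
    snaps = np.empty((B, settle_window_checks, nr))
    n_snap = np.zeros(B, np.int64)

    for k in range(n_equil + n_steps):
        regulate = k >= n_equil
        for b in range(B):
            if not active[b]:
                continue
            yb = y[b]
            tb = theta[b]
            _step(yb, inv_tau, tb, w, dt, False, k1, k2, k3, k4, yt, osc)
            if regulate:
                for j in range(nr):
                    i = reg[j]
                    o_i = 1.0 / (1.0 + np.exp(-(yb[i] + tb[i])))
                    if o_i < lb[j]:
                        drive = lb[j] - o_i
                    elif o_i > ub[j]:
                        drive = ub[j] - o_i
                    else:
                        drive = 0.0
                    t_new = tb[i] + dt * drive * inv_tau_theta[j]
                    if t_new < theta_lo:
                        t_new = theta_lo
                    elif t_new > theta_hi:
                        t_new = theta_hi
                    tb[i] = t_new
        if regulate and settle_tol > 0.0 and (k - n_equil) % check_every == 0:
            slot = int(((k - n_equil) // check_every) % settle_window_checks)
            any_active = False
            for b in range(B):
                if not active[b]:
                    continue
                for j in range(nr):
                    snaps[b, slot, j] = theta[b, reg[j]]
                n_snap[b] += 1
                if n_snap[b] >= settle_window_checks:
                    quiet = True
                    for j in range(nr):
                        lo_v = snaps[b, 0, j]
                        hi_v = lo_v
                        for m in range(1, settle_window_checks):
                            v = snaps[b, m, j]
                            if v < lo_v:
                                lo_v = v
                            if v > hi_v:
                                hi_v = v
                        if hi_v - lo_v >= settle_tol:
                            quiet = False
                            break
                    if quiet:
                        active[b] = False
                        settled_at[b] = (k - n_equil) * dt
                if active[b]:
                    any_active = True
            if not any_active:
                break
    return theta, y, settled_at
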