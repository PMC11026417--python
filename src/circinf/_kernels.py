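"""Numba kernels for the hot paths: OFF-period integration and run simulation.

The OFF dynamics are a 1-D autonomous ODE in the belief log-odds L.  The
raw drift grows like e^{|L|}, which makes explicit stepping stiff at large
|L|, so integration is carried out in the compressed coordinate
u = tanh(L / 2), where the same dynamics read

    du/dt = r_on (1 - u) - r_off (1 + u) + a (1 - u^2) atanh(u)

and every term is bounded.  For b = 0.5 and a = 0 this reduces exactly to
du/dt = -r u, the closed-form decay law of the leaky integrator.  The OFF
dynamics are autonomous, so one integration of a grid of start values
yields a flow map L_in -> L_out per delay level; run simulation then only
interpolates that map per trial.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True, inline="always")
def _udrift(u, r_on, r_off, a):
    return r_on * (1.0 - u) - r_off * (1.0 + u) + a * (1.0 - u * u) * np.arctanh(u)


@nb.njit(cache=True, inline="always")
def _rk4_step_u(u, h, r_on, r_off, a, u_cap):
    k1 = _udrift(u, r_on, r_off, a)
    v = u + 0.5 * h * k1
    if v > u_cap:
        v = u_cap
    elif v < -u_cap:
        v = -u_cap
    k2 = _udrift(v, r_on, r_off, a)
    v = u + 0.5 * h * k2
    if v > u_cap:
        v = u_cap
    elif v < -u_cap:
        v = -u_cap
    k3 = _udrift(v, r_on, r_off, a)
    v = u + h * k3
    if v > u_cap:
        v = u_cap
    elif v < -u_cap:
        v = -u_cap
    k4 = _udrift(v, r_on, r_off, a)
    out = u + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if out > u_cap:
        out = u_cap
    elif out < -u_cap:
        out = -u_cap
    return out


@nb.njit(cache=True)
def rk4_evolve(L0, duration, dt, r_on, r_off, a, l_cap):
    """Integrate the OFF dynamics from each entry of L0 over `duration`.

    Fixed-step classical Runge-Kutta in u = tanh(L/2) with a shortened
    final step so the stop time is hit exactly.  Returns a new array of
    log-odds, capped at +/- l_cap.
    """
    n = L0.shape[0]
    u_cap = np.tanh(0.5 * l_cap)
    u = np.empty(n)
    for i in range(n):
        v = np.tanh(0.5 * L0[i])
        if v > u_cap:
            v = u_cap
        elif v < -u_cap:
            v = -u_cap
        u[i] = v
    t = 0.0
    while t < duration - 1e-12:
        h = dt if duration - t > dt else duration - t
        for i in range(n):
            u[i] = _rk4_step_u(u[i], h, r_on, r_off, a, u_cap)
        t += h
    out = np.empty(n)
    for i in range(n):
        out[i] = 2.0 * np.arctanh(u[i])
    return out


@nb.njit(cache=True)
def rk4_flow_snapshots(grid, times, dt, r_on, r_off, a, l_cap):
    """Flow maps of the OFF dynamics at several horizons in one pass.

    `times` must be ascending.  Row k of the result holds the log-odds at
    ``times[k]`` of the trajectory started at each grid node.
    """
    n_t = times.shape[0]
    n_g = grid.shape[0]
    u_cap = np.tanh(0.5 * l_cap)
    out = np.empty((n_t, n_g))
    u = np.empty(n_g)
    for i in range(n_g):
        v = np.tanh(0.5 * grid[i])
        if v > u_cap:
            v = u_cap
        elif v < -u_cap:
            v = -u_cap
        u[i] = v
    t = 0.0
    for k in range(n_t):
        target = times[k]
        while t < target - 1e-12:
            h = dt if target - t > dt else target - t
            for i in range(n_g):
                u[i] = _rk4_step_u(u[i], h, r_on, r_off, a, u_cap)
            t += h
        for i in range(n_g):
            out[k, i] = 2.0 * np.arctanh(u[i])
    return out


@nb.njit(cache=True)
def simulate_responses(
    flow,
    grid_min,
    inv_dgrid,
    level_idx,
    is_block_first,
    w,
    penalty,
    relative_penalty,
    noise,
    coins,
    block_start_l,
    l_cap,
):
    """Simulate percept reports for several runs sharing one OFF sequence.

    Per trial: evolve the belief through the preceding OFF period (linear
    interpolation of the per-level flow map), add the sensory impulse
    w * noise, report the sign (a fair coin from `coins` breaks exact ties),
    then apply the penalty shift.  Returns int8 responses (+1 SFA, -1 SFB)
    of shape (n_runs, n_trials).
    """
    n_runs, n_trials = noise.shape
    n_g = flow.shape[1]
    resp = np.empty((n_runs, n_trials), dtype=np.int8)
    for rix in range(n_runs):
        L = block_start_l
        for t in range(n_trials):
            if is_block_first[t]:
                L = block_start_l
            row = level_idx[t]
            pos = (L - grid_min) * inv_dgrid
            if pos <= 0.0:
                L = flow[row, 0]
            elif pos >= n_g - 1:
                L = flow[row, n_g - 1]
            else:
                i = int(pos)
                fr = pos - i
                L = flow[row, i] * (1.0 - fr) + flow[row, i + 1] * fr
            L = L + w * noise[rix, t]
            if L > 0.0:
                r = 1
            elif L < 0.0:
                r = -1
            else:
                r = 1 if coins[rix, t] < 0.5 else -1
            resp[rix, t] = r
            if relative_penalty:
                # signed shift along the just-reported percept's direction:
                # negative P destabilizes it, positive P entrenches it
                L = L + r * penalty
            else:
                L = L + penalty
            if L > l_cap:
                L = l_cap
            elif L < -l_cap:
                L = -l_cap
    return resp


@nb.njit(cache=True)
def pair_counts(resp, level_idx, same_block, n_levels):
    """Ordered-pair counts by delay level, pooled over runs.

    Pair codes: 0 SFA->SFA, 1 SFA->SFB, 2 SFB->SFA, 3 SFB->SFB; the delay
    attributed to a pair is the OFF duration of its second trial.
    """
    n_runs, n_trials = resp.shape
    counts = np.zeros((4, n_levels), dtype=np.int64)
    for rix in range(n_runs):
        for t in range(n_trials - 1):
            if same_block[t]:
                code = 0
                if resp[rix, t] < 0:
                    code += 2
                if resp[rix, t + 1] < 0:
                    code += 1
                counts[code, level_idx[t + 1]] += 1
    return counts
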