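"""Numba kernel for the Metropolis bead-fluctuation simulation.

The tether stretching energy is pre-tabulated on a uniform grid of bead-bead
distances (values + derivatives, i.e. energy and tension) and evaluated by
cubic Hermite interpolation, so one Monte-Carlo step costs a handful of
floating-point operations.  Distances beyond the table (tether stretched past
its usable force range) return a huge energy, so such proposals are rejected
rather than raising.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_HUGE = 1e30


@njit(cache=True, inline="always")
def _tether_energy(r, r0, dr, E, F):
    n = E.shape[0]
    t = (r - r0) / dr
    if t <= 0.0:
        return E[0]
    if t >= n - 1:
        # beyond the tabulated force range: continue with the end-point
        # tension plus a stiff quadratic wall, so out-of-domain states keep
        # a restoring gradient (a flat cap would let the walker diffuse
        # freely whenever an imposed hairpin flip strands it out there)
        over = r - (r0 + (n - 1) * dr)
        return E[n - 1] + F[n - 1] * over + 500.0 * over * over
    i = int(t)
    s = t - i
    h = dr
    e0, e1 = E[i], E[i + 1]
    f0, f1 = F[i], F[i + 1]
    s2 = s * s
    s3 = s2 * s
    return (
        (2.0 * s3 - 3.0 * s2 + 1.0) * e0
        + (s3 - 2.0 * s2 + s) * h * f0
        + (-2.0 * s3 + 3.0 * s2) * e1
        + (s3 - s2) * h * f1
    )


@njit(cache=True, inline="always")
def _total_energy(u1, u2, d, k1, k2, state, r0, dr, Ef, Ff, Eu, Fu, dG_u):
    e = 0.0
    for j in range(3):
        e += 0.5 * k1[j] * u1[j] * u1[j] + 0.5 * k2[j] * u2[j] * u2[j]
    rx = d + u2[0] - u1[0]
    ry = u2[1] - u1[1]
    rz = u2[2] - u1[2]
    r = np.sqrt(rx * rx + ry * ry + rz * rz)
    if state == 0:
        e += _tether_energy(r, r0, dr, Ef, Ff)
    else:
        e += _tether_energy(r, r0, dr, Eu, Fu) + dG_u
    return e


@njit(cache=True)
def run_mc(
    seed,
    n_steps,
    sample_every,
    k1,
    k2,
    d0,
    dx_accept,
    d_stop,
    step,
    kT,
    r0,
    dr,
    Ef,
    Ff,
    Eu,
    Fu,
    dG_u,
    states,
    p_flip,
    init_state,
    u1,
    u2,
):
    """Run the Metropolis chain; returns block-averaged observables.

    Parameters (arrays are float64 unless noted):
      seed          RNG seed (int)
      n_steps       maximum number of MC iterations
      sample_every  block size for output averaging (mc_rate / output_rate)
      k1, k2        (3,) trap stiffnesses; index 0 = pulling axis
      d0            initial trap separation (nm)
      dx_accept     trap-separation increment applied after each accepted move
      d_stop        stop when separation exceeds this (ignored if <= d0)
      step          proposal half-width n (nm), uniform in [-n, n] per coord
      kT            thermal energy (pN nm)
      r0, dr, E*, F* tether energy tables (folded / unfolded)
      dG_u          energy offset of the unfolded hairpin state
      states        int8[n_steps] imposed hidden states, or length-0 array
      p_flip        per-step probability of proposing a hairpin flip (<=0 off)
      init_state    starting hidden state
      u1, u2        (3,) initial bead displacements from trap centers (mutated)

    Returns (trap_sep, defl1, defl2, force, ext, state_frac, n_out, n_accept,
    sum_dE, E_first, E_last, final_state).
    """
    np.random.seed(seed)
    n_blocks = n_steps // sample_every
    o_sep = np.zeros(n_blocks)
    o_d1 = np.zeros(n_blocks)
    o_d2 = np.zeros(n_blocks)
    o_f = np.zeros(n_blocks)
    o_x = np.zeros(n_blocks)
    o_s = np.zeros(n_blocks)
    o_y1 = np.zeros(n_blocks)  # bead-1 transverse and beam-axis coordinates,
    o_z1 = np.zeros(n_blocks)  # for per-axis fluctuation diagnostics

    d = d0
    state = init_state
    imposed = states.shape[0] > 0
    E_cur = _total_energy(u1, u2, d, k1, k2, state, r0, dr, Ef, Ff, Eu, Fu, dG_u)
    E_first = E_cur
    sum_dE = 0.0
    n_accept = 0
    v1 = np.empty(3)
    v2 = np.empty(3)

    i = 0
    while i < n_steps:
        if imposed:
            s_new = states[i]
            if s_new != state:
                state = s_new
                E_cur = _total_energy(
                    u1, u2, d, k1, k2, state, r0, dr, Ef, Ff, Eu, Fu, dG_u
                )
        # simultaneous perturbation of all six bead coordinates
        for j in range(3):
            v1[j] = u1[j] + np.random.uniform(-step, step)
            v2[j] = u2[j] + np.random.uniform(-step, step)
        E_new = _total_energy(v1, v2, d, k1, k2, state, r0, dr, Ef, Ff, Eu, Fu, dG_u)
        dE = E_new - E_cur
        if dE <= 0.0 or np.random.random() < np.exp(-dE / kT):
            for j in range(3):
                u1[j] = v1[j]
                u2[j] = v2[j]
            n_accept += 1
            sum_dE += dE
            E_cur = E_new
            if dx_accept != 0.0:
                d += dx_accept
                E_cur = _total_energy(
                    u1, u2, d, k1, k2, state, r0, dr, Ef, Ff, Eu, Fu, dG_u
                )
        # optional Metropolis hairpin flip (equilibrium hopping mode)
        if p_flip > 0.0 and np.random.random() < p_flip:
            s_try = 1 - state
            E_try = _total_energy(
                u1, u2, d, k1, k2, s_try, r0, dr, Ef, Ff, Eu, Fu, dG_u
            )
            dEs = E_try - E_cur
            if dEs <= 0.0 or np.random.random() < np.exp(-dEs / kT):
                state = s_try
                sum_dE += dEs
                E_cur = E_try

        blk = i // sample_every
        o_sep[blk] += d
        o_d1[blk] += u1[0]
        o_d2[blk] += -u2[0]
        o_f[blk] += 0.5 * (k1[0] * u1[0] - k2[0] * u2[0])
        o_x[blk] += d + u2[0] - u1[0]
        o_s[blk] += state
        o_y1[blk] += u1[1]
        o_z1[blk] += u1[2]
        i += 1
        if d_stop > d0 and d >= d_stop and (i % sample_every) == 0:
            break

    n_out = i // sample_every
    inv = 1.0 / sample_every
    for b in range(n_out):
        o_sep[b] *= inv
        o_d1[b] *= inv
        o_d2[b] *= inv
        o_f[b] *= inv
        o_x[b] *= inv
        o_s[b] *= inv
        o_y1[b] *= inv
        o_z1[b] *= inv
    return (
        o_sep[:n_out],
        o_d1[:n_out],
        o_d2[:n_out],
        o_f[:n_out],
        o_x[:n_out],
        o_s[:n_out],
        o_y1[:n_out],
        o_z1[:n_out],
        n_out,
        n_accept,
        sum_dE,
        E_first,
        E_cur,
        state,
    )
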