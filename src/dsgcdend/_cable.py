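"""Numba kernel for the tree cable equation.

Backward-Euler integration of a branched passive/active cable with
conductance-based biexponential synapses.  The linear system at each step
is solved exactly in O(N) with Hines' ordered elimination: compartments
are numbered so every parent precedes its children, so eliminating from
the leaves upward never creates fill-in.

Units: mV, ms, nF, µS, nA (so C/dt [nF/ms] and g [µS] are commensurable).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_cable_sim"]


@njit(cache=True)
def _hines_solve(parent, ga, d, rhs, v_out):
    n = d.shape[0]
    # eliminate children into parents (parent[i] < i always)
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = ga[i] / d[i]
        d[p] -= ga[i] * f
        rhs[p] += rhs[i] * f
    v_out[0] = rhs[0] / d[0]
    for i in range(1, n):
        v_out[i] = (rhs[i] + ga[i] * v_out[parent[i]]) / d[i]


@njit(cache=True)
def run_cable_sim(
    parent,            # int64[n]  parent compartment (-1 for root=0)
    ga,                # f8[n]     axial conductance to parent, µS (ga[0]=0)
    C,                 # f8[n]     capacitance, nF
    gL,                # f8[n]     leak conductance, µS
    eL,                # f8        leak reversal, mV
    dt,                # f8        ms
    n_steps,           # int
    rec_stride,        # int       record every rec_stride-th step
    syn_comp,          # int64[m]  compartment of each synapse (may be empty)
    syn_onset,         # f8[m]     onset time, ms (inf = never)
    syn_gmax,          # f8[m]     peak conductance, µS
    syn_erev,          # f8[m]     reversal, mV
    syn_dec_r,         # f8[m]     exp(-dt/tau_rise)
    syn_dec_d,         # f8[m]     exp(-dt/tau_decay)
    syn_norm,          # f8[m]     peak normalization of (B - A)
    i_inj,             # f8[n]     constant injected current, nA
    active_enabled,    # bool
    g_na, g_k, g_km,   # f8[n]     max conductances, µS
    e_na, e_k,         # f8
    q_phi,             # f8        gating rate multiplier (temperature)
    theta,             # f8        1.0 = backward Euler, 0.5 = Crank-Nicolson
):
    n = parent.shape[0]
    m = syn_comp.shape[0]
    n_rec = (n_steps + rec_stride - 1) // rec_stride
    v_rec = np.empty((n, n_rec), dtype=np.float32)

    v = np.full(n, eL)
    a_state = np.zeros(m)
    b_state = np.zeros(m)
    fired = np.zeros(m, dtype=np.bool_)
    g_old = np.zeros(n)      # total ionic conductance at the previous time
    drive_old = np.zeros(n)  # total ionic conductance-weighted reversal
    for i in range(n):
        g_old[i] = gL[i]
        drive_old[i] = gL[i] * eL

    # HH gates (shifted-voltage convention, rest near -60 mV)
    mg = np.zeros(n)
    hg = np.ones(n)
    ng = np.zeros(n)
    pg = np.zeros(n)
    if active_enabled:
        for i in range(n):
            vs = v[i] + 60.0
            am = 0.1 * (25.0 - vs) / (np.exp((25.0 - vs) / 10.0) - 1.0)
            bm = 4.0 * np.exp(-vs / 18.0)
            ah = 0.07 * np.exp(-vs / 20.0)
            bh = 1.0 / (np.exp((30.0 - vs) / 10.0) + 1.0)
            an = 0.01 * (10.0 - vs) / (np.exp((10.0 - vs) / 10.0) - 1.0)
            bn = 0.125 * np.exp(-vs / 80.0)
            mg[i] = am / (am + bm)
            hg[i] = ah / (ah + bh)
            ng[i] = an / (an + bn)
            pg[i] = 1.0 / (1.0 + np.exp(-(v[i] + 35.0) / 10.0))

    d = np.empty(n)
    rhs = np.empty(n)
    v_new = np.empty(n)
    g_new = np.empty(n)
    drive_new = np.empty(n)
    ga_th = ga * theta
    k_rec = 0
    for step in range(n_steps):
        t = step * dt
        # record at the *start* of the step so sample times are exactly
        # step*dt regardless of dt (keeps dt-refinement comparisons aligned)
        if step % rec_stride == 0:
            for i in range(n):
                v_rec[i, k_rec] = v[i]
            k_rec += 1
        # synapse state update (analytic decay + onset increments)
        for s in range(m):
            a_state[s] *= syn_dec_r[s]
            b_state[s] *= syn_dec_d[s]
            if (not fired[s]) and t + dt >= syn_onset[s]:
                a_state[s] += 1.0
                b_state[s] += 1.0
                fired[s] = True

        # total ionic conductance / drive at the new time level
        for i in range(n):
            g_new[i] = gL[i]
            drive_new[i] = gL[i] * eL
        for s in range(m):
            g = syn_gmax[s] * syn_norm[s] * (b_state[s] - a_state[s])
            if g > 0.0:
                c = syn_comp[s]
                g_new[c] += g
                drive_new[c] += g * syn_erev[s]
        if active_enabled:
            for i in range(n):
                gna_i = g_na[i] * mg[i] * mg[i] * mg[i] * hg[i]
                gk_i = g_k[i] * ng[i] * ng[i] * ng[i] * ng[i]
                gkm_i = g_km[i] * pg[i]
                g_new[i] += gna_i + gk_i + gkm_i
                drive_new[i] += gna_i * e_na + (gk_i + gkm_i) * e_k

        # theta-method: (C/dt + θ(G₁+L))V₁ = (C/dt − (1−θ)(G₀+L))V₀
        #               + θ·drive₁ + (1−θ)·drive₀ + I
        one_m = 1.0 - theta
        for i in range(n):
            d[i] = C[i] / dt + theta * g_new[i]
            rhs[i] = (C[i] / dt - one_m * g_old[i]) * v[i] \
                + theta * drive_new[i] + one_m * drive_old[i] + i_inj[i]
        for i in range(1, n):
            p = parent[i]
            d[i] += theta * ga[i]
            d[p] += theta * ga[i]
            if one_m > 0.0:
                ax = ga[i] * (v[i] - v[p])
                rhs[i] -= one_m * ax
                rhs[p] += one_m * ax

        _hines_solve(parent, ga_th, d, rhs, v_new)
        for i in range(n):
            v[i] = v_new[i]
            g_old[i] = g_new[i]
            drive_old[i] = drive_new[i]

        if active_enabled:
            for i in range(n):
                vs = v[i] + 60.0
                if abs(25.0 - vs) < 1e-9:
                    am = 1.0
                else:
                    am = 0.1 * (25.0 - vs) / (np.exp((25.0 - vs) / 10.0) - 1.0)
                bm = 4.0 * np.exp(-vs / 18.0)
                ah = 0.07 * np.exp(-vs / 20.0)
                bh = 1.0 / (np.exp((30.0 - vs) / 10.0) + 1.0)
                if abs(10.0 - vs) < 1e-9:
                    an = 0.1
                else:
                    an = 0.01 * (10.0 - vs) / (np.exp((10.0 - vs) / 10.0) - 1.0)
                bn = 0.125 * np.exp(-vs / 80.0)
                # exponential Euler with temperature factor
                tm = 1.0 / (q_phi * (am + bm))
                th = 1.0 / (q_phi * (ah + bh))
                tn = 1.0 / (q_phi * (an + bn))
                mg[i] += (am / (am + bm) - mg[i]) * (1.0 - np.exp(-dt / tm))
                hg[i] += (ah / (ah + bh) - hg[i]) * (1.0 - np.exp(-dt / th))
                ng[i] += (an / (an + bn) - ng[i]) * (1.0 - np.exp(-dt / tn))
                p_inf = 1.0 / (1.0 + np.exp(-(v[i] + 35.0) / 10.0))
                pg[i] += (p_inf - pg[i]) * (1.0 - np.exp(-dt / 50.0))

    return v_rec
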