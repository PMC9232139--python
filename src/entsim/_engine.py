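"""Compiled integration kernel.

One backward-Euler step of the multi-segment membrane equation per dt, with
exponential-Euler gate updates from precomputed voltage tables and exact /
exponential updates of the synaptic states.  All channel and synaptic
currents are linear in v once the gating states are frozen for the step, so
the voltage update is a single tridiagonal solve (Thomas algorithm) over the
soma segments.

Units inside the kernel: mV, ms, uS, nA, uF.  C(uF) * dv/dt(mV/ms) is in uA,
hence the factor 1000 against nA currents.
"""

import numpy as np
from numba import njit

#: |v| beyond which the integration is declared divergent (mV).
V_DIVERGE = 200.0


@njit(cache=True)
def run(
    dt,
    n_steps,
    v0,
    c_seg,          # uF per segment
    g_ax,           # uS between adjacent segments
    g_leak_seg,     # uS per segment (scalar)
    e_leak,
    # gate tables: (n_gates, n_v) steady state and exp(-dt/tau)
    minf_tab,
    efac_tab,
    vmin,
    dv_inv,
    gate_state,     # (n_gates, n_seg), modified in place
    # channels
    chan_g,         # (n_chan,) uS per segment
    chan_e,
    chan_gate_ptr,  # (n_chan+1,) into chan_gate_idx/exp
    chan_gate_idx,
    chan_gate_exp,
    # biexponential synapses (two-state exact decay + event increments)
    syn_e1,         # exp(-dt/tau_rise)
    syn_e2,         # exp(-dt/tau_decay)
    syn_erev,
    syn_inc,        # weight/peak_factor, uS added per event
    syn_seg,
    syn_ev_step,    # flattened, per-synapse sorted event step indices
    syn_ev_ptr,     # (n_syn+1,)
    # slow-EPSP synapses
    slow_gsk,
    slow_erev,
    slow_seg,
    slow_agonist,   # (n_slow, n_steps) agonist level during each step
    slow_rates,     # (n_slow, 6): a1 b1 a2 b2 a3 b3 (1/s)
    slow_state,     # (n_slow, 3): D, C, P, modified in place
    dt_s,           # cascade step in seconds
    # step-current injections
    inj_seg,
    inj_amp,
    inj_on,         # step index
    inj_off,
    # outputs
    v_out,          # (n_steps+1, n_seg)
    p_out,          # (n_slow, n_steps+1)
):
    n_seg = v0.shape[0]
    n_gates = gate_state.shape[0]
    n_chan = chan_g.shape[0]
    n_syn = syn_e1.shape[0]
    n_slow = slow_gsk.shape[0]
    n_v = minf_tab.shape[1]

    v = v0.copy()
    v_out[0, :] = v
    for j in range(n_slow):
        p_out[j, 0] = slow_state[j, 2]

    syn_a = np.zeros(n_syn)      # rise state (decays with tau_rise)
    syn_b = np.zeros(n_syn)      # decay state
    syn_next = np.empty(n_syn, dtype=np.int64)
    for j in range(n_syn):
        syn_next[j] = syn_ev_ptr[j]

    cfac = 1000.0 * c_seg / dt

    G = np.empty(n_seg)
    B = np.empty(n_seg)
    # Thomas algorithm scratch
    cp = np.empty(n_seg)
    dp = np.empty(n_seg)

    for step in range(1, n_steps + 1):
        # --- gates: exponential update via table lookup at current v -------
        for s in range(n_seg):
            x = (v[s] - vmin) * dv_inv
            if x < 0.0:
                x = 0.0
            elif x > n_v - 1.001:
                x = n_v - 1.001
            i0 = int(x)
            f = x - i0
            for g in range(n_gates):
                minf = minf_tab[g, i0] + (minf_tab[g, i0 + 1] - minf_tab[g, i0]) * f
                efac = efac_tab[g, i0] + (efac_tab[g, i0 + 1] - efac_tab[g, i0]) * f
                m = minf + (gate_state[g, s] - minf) * efac
                if m < 0.0:
                    m = 0.0
                elif m > 1.0:
                    m = 1.0
                gate_state[g, s] = m

        # --- biexponential synapses: decay, then apply this step's events --
        for j in range(n_syn):
            syn_a[j] *= syn_e1[j]
            syn_b[j] *= syn_e2[j]
            while syn_next[j] < syn_ev_ptr[j + 1] and syn_ev_step[syn_next[j]] <= step:
                syn_a[j] += syn_inc[j]
                syn_b[j] += syn_inc[j]
                syn_next[j] += 1

        # --- slow-EPSP cascade: exact/exponential sub-updates --------------
        for j in range(n_slow):
            a1 = slow_rates[j, 0]
            b1 = slow_rates[j, 1]
            a2 = slow_rates[j, 2]
            b2 = slow_rates[j, 3]
            a3 = slow_rates[j, 4]
            b3 = slow_rates[j, 5]
            D = slow_state[j, 0]
            C = slow_state[j, 1]
            P = slow_state[j, 2]
            I = slow_agonist[j, step - 1]
            d_inf = a1 * I / b1
            D = d_inf + (D - d_inf) * np.exp(-b1 * dt_s)
            c_inf = a2 * D * D / b2
            C = c_inf + (C - c_inf) * np.exp(-b2 * dt_s)
            rate = a3 * C + b3
            p_inf = b3 / rate
            P = p_inf + (P - p_inf) * np.exp(-rate * dt_s)
            if P > 1.0:
                P = 1.0
            elif P < 0.0:
                P = 0.0
            slow_state[j, 0] = D
            slow_state[j, 1] = C
            slow_state[j, 2] = P
            p_out[j, step] = P

        # --- assemble per-segment conductance / source -------------------
        for s in range(n_seg):
            G[s] = g_leak_seg
            B[s] = g_leak_seg * e_leak
        for c in range(n_chan):
            for s in range(n_seg):
                of = 1.0
                for k in range(chan_gate_ptr[c], chan_gate_ptr[c + 1]):
                    m = gate_state[chan_gate_idx[k], s]
                    for _ in range(chan_gate_exp[k]):
                        of *= m
                gc = chan_g[c] * of
                G[s] += gc
                B[s] += gc * chan_e[c]
        for j in range(n_syn):
            gs = syn_b[j] - syn_a[j]
            if gs < 0.0:
                gs = 0.0
            G[syn_seg[j]] += gs
            B[syn_seg[j]] += gs * syn_erev[j]
        for j in range(n_slow):
            gs = slow_gsk[j] * slow_state[j, 2]
            G[slow_seg[j]] += gs
            B[slow_seg[j]] += gs * slow_erev[j]
        for j in range(inj_seg.shape[0]):
            if inj_on[j] <= step <= inj_off[j]:
                B[inj_seg[j]] += inj_amp[j]

        # --- backward-Euler voltage update: tridiagonal solve -------------
        # (cfac + G_s + axial) v'_s - g_ax (v'_{s-1} + v'_{s+1}) = cfac v_s + B_s
        if n_seg == 1:
            v[0] = (cfac * v[0] + B[0]) / (cfac + G[0])
        else:
            b0 = cfac + G[0] + g_ax
            cp[0] = -g_ax / b0
            dp[0] = (cfac * v[0] + B[0]) / b0
            for s in range(1, n_seg):
                ax = g_ax if s == n_seg - 1 else 2.0 * g_ax
                bs = cfac + G[s] + ax
                denom = bs + g_ax * cp[s - 1]
                cp[s] = -g_ax / denom
                dp[s] = (cfac * v[s] + B[s] + g_ax * dp[s - 1]) / denom
            v[n_seg - 1] = dp[n_seg - 1]
            for s in range(n_seg - 2, -1, -1):
                v[s] = dp[s] - cp[s] * v[s + 1]

        for s in range(n_seg):
            if not np.isfinite(v[s]) or abs(v[s]) > V_DIVERGE:
                return step
        v_out[step, :] = v

    return -1
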