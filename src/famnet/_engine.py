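"""Compiled time-stepping kernel for the reservoir simulation.

One step: (1) decay all per-neuron traces; (2) deliver spikes emitted on
the previous step (one-step uniform transmission delay) plus external
input/forced spikes; (3) exponential-Euler membrane update with optional
Gaussian noise current; (4) threshold, reset and refractory handling, BPAP
restart; (5) plasticity update (NMDAR calcium rule over all plastic
synapses, or pair-based STDP on spike events).

Synaptic plasticity state per synapse is only (weight, calcium): the EPSP,
NMDA-open and BPAP traces are per-neuron double exponentials restarted on
spikes, shared by all synapses of that neuron.  Driving force, Omega and
eta are table lookups.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_OFF = 0
MODE_NMDAR = 1
MODE_STDP = 2


@njit(cache=True, fastmath=True)
def run_kernel(
    n_steps, dt, seed,
    # neuron state
    v, refrac_left, refrac_steps, disabled,
    psc, epsp_f, epsp_s, nmda_f, nmda_s, bpap_f, bpap_s,
    # membrane constants
    decay_m, v_rest, r_m, i_inject, noise_std, v_thresh,
    v_reset_lo, v_reset_hi,
    # trace decay factors and restart amplitudes
    d_psc, d_ef, d_es, d_nf, d_ns, d_bf, d_bs,
    ef0, es0, nf0, ns0, bf0, bs0,
    # reservoir synapses (flat + CSR by pre for delivery, CSR by post for STDP)
    recurrent_efficacy,
    syn_pre, syn_post, syn_w, syn_plastic, syn_ca, syn_ca_eff,
    out_indptr, out_syn,
    in_indptr, in_syn,
    # input projection (CSR by channel) and spikes
    inp_indptr, inp_post, inp_w,
    inp_spike_step, inp_spike_chan,
    forced_step, forced_neuron, pending,
    # plasticity
    mode, trace_restart, epsp_gain, v_rest_nmda, nmda_gain, dt_ms, tau_ca_ms,
    ca_max, tau_eff_ms,
    h_table, v_tab_min, v_tab_step,
    omega_table, eta_table, ca_tab_step, kappa, w_min, w_max,
    bpap_on,
    a_plus, a_minus, tau_plus_ms, tau_minus_ms,
    last_pre_ms, last_post_ms,
    # recording
    rec_n, rec_t, t_offset,
    trace_syn, trace_every, trace_ca, trace_w,
    trace_neu, trace_v,
):
    np.random.seed(seed)
    n = v.shape[0]
    n_syn = syn_pre.shape[0]
    max_rec = rec_n.shape[0]
    n_rec = 0
    overflow = 0

    cap = 2 * n + 16
    prev_spikes = np.empty(cap, np.int64)
    n_prev = pending.shape[0]
    for k in range(n_prev):
        prev_spikes[k] = pending[k]
    cur_spikes = np.empty(cap, np.int64)

    ip = 0  # pointer into input spikes
    fp = 0  # pointer into forced spikes
    n_inp = inp_spike_step.shape[0]
    n_forced = forced_step.shape[0]
    h_len = h_table.shape[0]
    ca_len = omega_table.shape[0]
    dt_s = dt

    for step in range(n_steps):
        t_ms = (t_offset + step) * dt * 1000.0
        # 1. decay traces
        for i in range(n):
            psc[i] *= d_psc
            epsp_f[i] *= d_ef
            epsp_s[i] *= d_es
            nmda_f[i] *= d_nf
            nmda_s[i] *= d_ns
            bpap_f[i] *= d_bf
            bpap_s[i] *= d_bs

        # 2a. deliver reservoir spikes from previous step
        for k in range(n_prev):
            pre = prev_spikes[k]
            # glutamate release: pre-side traces sum (or restart) on spikes
            if trace_restart == 1:
                epsp_f[pre] = ef0
                epsp_s[pre] = es0
                nmda_f[pre] = nf0
                nmda_s[pre] = ns0
            else:
                epsp_f[pre] += ef0
                epsp_s[pre] += es0
                nmda_f[pre] += nf0
                nmda_s[pre] += ns0
            last_pre_ms[pre] = t_ms
            for j in range(out_indptr[pre], out_indptr[pre + 1]):
                s = out_syn[j]
                # weight (A) -> nA; recurrent transmission is scaled by the
                # steady-state short-term-depression efficacy
                psc[syn_post[s]] += syn_w[s] * recurrent_efficacy * 1e9
                if mode == MODE_STDP and syn_plastic[s]:
                    # pre arrival after a post spike: depression
                    dtp = t_ms - last_post_ms[syn_post[s]]
                    if dtp >= 0.0 and dtp < 10.0 * tau_minus_ms:
                        w2 = syn_w[s] - a_minus * np.exp(-dtp / tau_minus_ms)
                        if w2 < w_min:
                            w2 = w_min
                        syn_w[s] = w2

        # 2b. external input spikes scheduled for this step
        while ip < n_inp and inp_spike_step[ip] <= step:
            c = inp_spike_chan[ip]
            for j in range(inp_indptr[c], inp_indptr[c + 1]):
                psc[inp_post[j]] += inp_w[j] * 1e9
            ip += 1

        # 3. membrane update (exponential Euler toward V_inf)
        for i in range(n):
            if refrac_left[i] > 0:
                refrac_left[i] -= 1
                continue
            cur = psc[i] + i_inject
            if noise_std > 0.0:
                cur += noise_std * np.random.normal()
            v_inf = v_rest + r_m * cur
            v[i] = v_inf + (v[i] - v_inf) * decay_m

        # 4. threshold crossing and forced spikes
        n_cur = 0
        for i in range(n):
            if disabled[i] == 0 and refrac_left[i] == 0 and v[i] >= v_thresh:
                v[i] = v_reset_lo + (v_reset_hi - v_reset_lo) * np.random.random()
                refrac_left[i] = refrac_steps[i]
                cur_spikes[n_cur] = i
                n_cur += 1
        while fp < n_forced and forced_step[fp] <= step:
            i = forced_neuron[fp]
            v[i] = v_reset_lo + (v_reset_hi - v_reset_lo) * np.random.random()
            refrac_left[i] = refrac_steps[i]
            if n_cur < cap:
                cur_spikes[n_cur] = i
                n_cur += 1
            fp += 1
        for k in range(n_cur):
            i = cur_spikes[k]
            if bpap_on == 1:
                bpap_f[i] = bf0
                bpap_s[i] = bs0
            last_post_ms[i] = t_ms
            if n_rec < max_rec:
                rec_n[n_rec] = i
                rec_t[n_rec] = step * dt
                n_rec += 1
            else:
                overflow = 1
            if mode == MODE_STDP:
                # post spike after pre arrivals: potentiation
                for j in range(in_indptr[i], in_indptr[i + 1]):
                    s = in_syn[j]
                    if syn_plastic[s]:
                        dtp = t_ms - last_pre_ms[syn_pre[s]]
                        if dtp >= 0.0 and dtp < 10.0 * tau_plus_ms:
                            w2 = syn_w[s] + a_plus * np.exp(-dtp / tau_plus_ms)
                            if w2 > w_max:
                                w2 = w_max
                            syn_w[s] = w2

        # 5. NMDAR calcium plasticity over all plastic synapses
        if mode == MODE_NMDAR:
            for s in range(n_syn):
                if not syn_plastic[s]:
                    continue
                pre = syn_pre[s]
                ntr = nmda_f[pre] + nmda_s[pre]
                ca = syn_ca[s]
                if ntr < 1e-4 and ca < 1e-4 and syn_ca_eff[s] < 1e-4:
                    continue
                vloc = (v_rest_nmda
                        + epsp_gain * syn_w[s] * (epsp_f[pre] + epsp_s[pre])
                        + bpap_f[syn_post[s]] + bpap_s[syn_post[s]])
                fi = (vloc - v_tab_min) / v_tab_step
                if fi < 0.0:
                    fi = 0.0
                elif fi > h_len - 1.001:
                    fi = h_len - 1.001
                i0 = int(fi)
                frac = fi - i0
                h = h_table[i0] * (1.0 - frac) + h_table[i0 + 1] * frac
                flux = nmda_gain * ntr * h
                if ca_max > 0.0:
                    inact = 1.0 - ca / ca_max
                    if inact < 0.0:
                        inact = 0.0
                    flux *= inact
                ca = ca + dt_ms * (flux - ca / tau_ca_ms)
                if ca < 0.0:
                    ca = 0.0
                syn_ca[s] = ca
                # slow effector pool (kinase/phosphatase integration) gates
                # the weight rule; tau_eff <= 0 couples instantaneously
                if tau_eff_ms > 0.0:
                    ce = syn_ca_eff[s] + dt_ms * (ca - syn_ca_eff[s]) / tau_eff_ms
                    syn_ca_eff[s] = ce
                else:
                    ce = ca
                ci = ce / ca_tab_step
                if ci > ca_len - 1.001:
                    ci = ca_len - 1.001
                c0 = int(ci)
                cf = ci - c0
                om = omega_table[c0] * (1.0 - cf) + omega_table[c0 + 1] * cf
                et = eta_table[c0] * (1.0 - cf) + eta_table[c0 + 1] * cf
                w2 = syn_w[s] + dt_s * et * (kappa * om - syn_w[s])
                if w2 < w_min:
                    w2 = w_min
                elif w2 > w_max:
                    w2 = w_max
                syn_w[s] = w2
        elif mode == MODE_OFF:
            # calcium still decays so a later learning phase starts cleanly
            pass

        # recording of traces
        if trace_every > 0 and step % trace_every == 0:
            row = step // trace_every
            for k in range(trace_syn.shape[0]):
                trace_ca[row, k] = syn_ca[trace_syn[k]]
                trace_w[row, k] = syn_w[trace_syn[k]]
            for k in range(trace_neu.shape[0]):
                trace_v[row, k] = v[trace_neu[k]]

        # swap spike buffers
        tmp = prev_spikes
        prev_spikes = cur_spikes
        cur_spikes = tmp
        n_prev = n_cur

    # return residual spikes to deliver on the next call
    resid = np.empty(n_prev, np.int64)
    for k in range(n_prev):
        resid[k] = prev_spikes[k]
    return n_rec, overflow, resid
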