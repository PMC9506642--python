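"""Inner time-stepping loop of the cable integrator.

Written as a single flat-array function so it can be JIT-compiled with numba
(set DENDROSIM_NO_NUMBA=1 to run the pure-Python version, e.g. when
debugging tiny models).  The voltage is solved implicitly on the tree with a
Hines-ordered elimination (parents precede children); gates, synaptic states
and the calcium pool advance by exact/exponential updates per step.

Sign conventions: ionic currents are written g·(V − E) (outward positive),
so inward Ca²⁺ current is negative and charges the pool.
"""

from __future__ import annotations

import math
import os

import numpy as np


def _step_loop(
    # topology / passive
    parent, ga, cm,  # (n,) int64 / μS / nF
    theta,  # implicit weight: 1.0 backward Euler, 0.5 Crank-Nicolson
    # mechanisms: m rows
    mech_gbar, mech_erev, mech_is_ca,  # (m,n) μS, (m,), (m,) bool
    # gates: G rows, owner mech per gate
    gate_mech, gate_exp,  # (G,) int64
    inf_tab, tau_tab, tab_vmin, tab_dv,  # (G,NV), (G,NV), float, float
    dv_inf, dv_tau, tau_scale,  # (G,n)
    state,  # (G,n) in/out
    # calcium
    has_ca, ca, gamma, ca_rest, ca_tau, eca_coef, ca_out, eca,  # flags/arrays
    # stimuli
    pulse_comp, pulse_on, pulse_off, pulse_amp,  # (P,)
    alpha_comp, alpha_on, alpha_tau, alpha_g, alpha_e,  # (A,) μS
    esyn_comp, esyn_decay, esyn_g, esyn_e, esyn_s,  # (E,) μS
    nsyn_comp, nsyn_g, nsyn_e, nsyn_s, nsyn_x,
    nsyn_xdecay, nsyn_taux, nsyn_taus, nsyn_alpha, nsyn_mg,  # (N,)
    ev_time, ev_kind, ev_idx,  # (K,) sorted events: kind 0 exp, 1 nmda
    # gating replay (clamp one gate at one compartment to a trace)
    replay_gate, replay_comp, replay_t, replay_y,
    # run control
    v, t0, dt, nsteps,
    # probes
    probe_kind, probe_a, probe_b,  # (Q,): kind 0 v, 1 gate, 2 ca, 3 eca
    out,  # (nsteps+1, Q)
):
    n = v.shape[0]
    n_mech = mech_gbar.shape[0]
    n_gate = gate_mech.shape[0]
    nv = inf_tab.shape[1] if n_gate > 0 else 0
    n_probe = probe_kind.shape[0]

    gtot = np.empty(n)
    b = np.empty(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    gprod = np.empty(n)
    gmech = np.empty((n_mech, n))

    def record(row):
        for q in range(n_probe):
            k = probe_kind[q]
            if k == 0:
                out[row, q] = v[probe_b[q]]
            elif k == 1:
                out[row, q] = state[probe_a[q], probe_b[q]]
            elif k == 2:
                out[row, q] = ca[probe_b[q]]
            else:
                out[row, q] = eca[probe_b[q]]

    record(0)
    ev = 0
    n_ev = ev_time.shape[0]
    rp = 0  # replay trace cursor
    n_rp = replay_t.shape[0]

    for step in range(nsteps):
        t = t0 + step * dt
        tn = t + dt

        # --- synaptic state updates (exact decay, then events in (t, tn]) ---
        for j in range(esyn_s.shape[0]):
            esyn_s[j] *= esyn_decay[j]
        for j in range(nsyn_s.shape[0]):
            x_old = nsyn_x[j]
            x_new = x_old * nsyn_xdecay[j]
            x_bar = (x_old - x_new) * nsyn_taux[j] / dt
            rate = 1.0 / nsyn_taus[j] + nsyn_alpha[j] * x_bar
            s_inf = nsyn_alpha[j] * x_bar / rate
            s = s_inf + (nsyn_s[j] - s_inf) * math.exp(-rate * dt)
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
            nsyn_s[j] = s
            nsyn_x[j] = x_new
        while ev < n_ev and ev_time[ev] <= tn + 1e-12:
            if ev_time[ev] > t + 1e-12:
                if ev_kind[ev] == 0:
                    esyn_s[ev_idx[ev]] += 1.0
                else:
                    nsyn_x[ev_idx[ev]] += 1.0
            ev += 1

        # --- gate updates at the old voltage (exponential toward inf) -------
        for g in range(n_gate):
            for i in range(n):
                vi = v[i] - dv_inf[g, i]
                u = (vi - tab_vmin) / tab_dv
                if u < 0.0:
                    u = 0.0
                elif u > nv - 1.001:
                    u = nv - 1.001
                i0 = int(u)
                w = u - i0
                inf = inf_tab[g, i0] * (1.0 - w) + inf_tab[g, i0 + 1] * w
                vt = v[i] - dv_tau[g, i]
                u = (vt - tab_vmin) / tab_dv
                if u < 0.0:
                    u = 0.0
                elif u > nv - 1.001:
                    u = nv - 1.001
                i0 = int(u)
                w = u - i0
                tau = (tau_tab[g, i0] * (1.0 - w) + tau_tab[g, i0 + 1] * w)
                tau *= tau_scale[g, i]
                state[g, i] = inf + (state[g, i] - inf) * math.exp(-dt / tau)

        # --- replay clamp (linear interpolation of the recorded trace) ------
        if replay_gate >= 0 and n_rp > 0:
            while rp < n_rp - 1 and replay_t[rp + 1] < tn:
                rp += 1
            if rp < n_rp - 1 and replay_t[rp + 1] > replay_t[rp]:
                w = (tn - replay_t[rp]) / (replay_t[rp + 1] - replay_t[rp])
                if w < 0.0:
                    w = 0.0
                elif w > 1.0:
                    w = 1.0
                yv = replay_y[rp] * (1.0 - w) + replay_y[rp + 1] * w
            else:
                yv = replay_y[n_rp - 1]
            state[replay_gate, replay_comp] = yv

        # --- assemble membrane conductances and drive -----------------------
        for i in range(n):
            gtot[i] = 0.0
            b[i] = 0.0
        for m in range(n_mech):
            for i in range(n):
                gprod[i] = mech_gbar[m, i]
            for g in range(n_gate):
                if gate_mech[g] == m:
                    e = gate_exp[g]
                    for i in range(n):
                        s = state[g, i]
                        p = s
                        for _ in range(e - 1):
                            p *= s
                        gprod[i] *= p
            if mech_is_ca[m]:
                for i in range(n):
                    gmech[m, i] = gprod[i]
                    gtot[i] += gprod[i]
                    b[i] += gprod[i] * eca[i]
            else:
                erev = mech_erev[m]
                for i in range(n):
                    gmech[m, i] = gprod[i]
                    gtot[i] += gprod[i]
                    b[i] += gprod[i] * erev

        # stimuli evaluated at the end of the step
        for j in range(pulse_comp.shape[0]):
            if tn >= pulse_on[j] and tn < pulse_off[j]:
                b[pulse_comp[j]] += pulse_amp[j]
        for j in range(alpha_comp.shape[0]):
            xx = (tn - alpha_on[j]) / alpha_tau[j]
            if xx > 0.0:
                gs = alpha_g[j] * xx * math.exp(1.0 - xx)
                i = alpha_comp[j]
                gtot[i] += gs
                b[i] += gs * alpha_e[j]
        for j in range(esyn_comp.shape[0]):
            gs = esyn_g[j] * esyn_s[j]
            if gs != 0.0:
                i = esyn_comp[j]
                gtot[i] += gs
                b[i] += gs * esyn_e[j]
        for j in range(nsyn_comp.shape[0]):
            i = nsyn_comp[j]
            blockf = 1.0 / (1.0 + nsyn_mg[j] * math.exp(-0.062 * v[i]) / 3.57)
            gs = nsyn_g[j] * nsyn_s[j] * blockf
            if gs != 0.0:
                gtot[i] += gs
                b[i] += gs * nsyn_e[j]

        # --- implicit tree solve -------------------------------------------
        # (C/dt + θ(Gtot + L)) v_new = C/dt v − (1−θ)(Gtot + L) v + b
        if theta < 1.0:
            for i in range(n):
                av = gtot[i] * v[i]
                if parent[i] >= 0:
                    av += ga[i] * (v[i] - v[parent[i]])
                rhs[i] = cm[i] / dt * v[i] - (1.0 - theta) * av + b[i]
            for i in range(1, n):
                p = parent[i]
                rhs[p] -= (1.0 - theta) * ga[i] * (v[p] - v[i])
        else:
            for i in range(n):
                rhs[i] = cm[i] / dt * v[i] + b[i]
        for i in range(n):
            diag[i] = cm[i] / dt + theta * gtot[i]
        for i in range(1, n):
            tga = theta * ga[i]
            diag[i] += tga
            diag[parent[i]] += tga
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = theta * ga[i] / diag[i]
            diag[p] -= f * theta * ga[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + theta * ga[i] * v[parent[i]]) / diag[i]
        for i in range(n):
            if not math.isfinite(v[i]):
                return step

        # --- calcium pool (exact exponential toward the per-step fixed point)
        if has_ca:
            for i in range(n):
                i_ca = 0.0
                for m in range(n_mech):
                    if mech_is_ca[m]:
                        i_ca += gmech[m, i] * (v[i] - eca[i])
                ca_ss = ca_rest - gamma[i] * i_ca * ca_tau
                c = ca_ss + (ca[i] - ca_ss) * math.exp(-dt / ca_tau)
                if c < 1e-7:
                    c = 1e-7
                ca[i] = c
                eca[i] = eca_coef * math.log(ca_out / c)

        record(step + 1)

    return -1


if os.environ.get("DENDROSIM_NO_NUMBA", "0") == "1":
    step_loop = _step_loop
else:  # pragma: no cover - exercised indirectly by every simulation test
    try:
        from numba import njit

        step_loop = njit(cache=True, fastmath=False)(_step_loop)
    except ImportError:
        step_loop = _step_loop
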