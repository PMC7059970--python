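"""Numba-compiled inner loop of the network integrator.

The full coupled system (all cell compartments, all gating variables, one
GABA_A gate per presynaptic cell) is packed into a single flat state
vector and advanced with classical fixed-step RK4.  Noise inputs (FSI
Poisson shot noise, SPN Gaussian noise) are redrawn once per step and held
constant across the four RK4 stages.

State layout for nf FSIs and ns = nd1 + nd2 SPNs::

    [0,    nf)   FSI soma V          [5nf, 6nf)   FSI dend V
    [nf,  2nf)   soma h              [6nf, 7nf)   dend h
    [2nf, 3nf)   soma n              [7nf, 8nf)   dend n
    [3nf, 4nf)   soma a              [8nf, 9nf)   dend a
    [4nf, 5nf)   soma b              [9nf, 10nf)  dend b
    [10nf,       10nf+ns)    SPN V
    [10nf+ns,    10nf+5ns)   SPN m, h, n, w
    [10nf+5ns,   11nf+5ns)   FSI-sourced GABA gates S_f
    [11nf+5ns,   11nf+6ns)   SPN-sourced GABA gates S_s

Because a GABA_A gate depends only on its presynaptic voltage, one gate
per source cell serves every postsynaptic target.
"""

import numpy as np
from numba import njit

from .cells import (
    fsi_m_inf, fsi_h_inf, fsi_tau_h, fsi_n_inf, fsi_tau_n,
    fsi_a_inf, fsi_b_inf,
    spn_alpha_m, spn_beta_m, spn_alpha_h, spn_beta_h,
    spn_alpha_n, spn_beta_n, spn_alpha_w, spn_beta_w,
)

# indices into the scalar-parameter vector P
CM_F, ENA_F, EK_F, EL_F, TAU_A, TAU_B, DSCALE, GC = range(8)
CM_S, GNA_S, GK_S, GL_S, GM_S, ENA_S, EK_S, EL_S, QS = range(8, 17)
G_FF, G_FS, G_SS, E_I, TAU_I, TAU_R, G_GJ = range(17, 24)
N_PARAMS = 24

GATE_CLAMP_TOL = 1e-6  # silently clamp gate overshoots below this

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_GATE_OVERSHOOT = 2
STATUS_SPIKE_OVERFLOW = 3


def state_size(nf: int, ns: int) -> int:
    return 11 * nf + 6 * ns


def gate_mask(nf: int, ns: int) -> np.ndarray:
    """Boolean mask of state entries that must stay within [0, 1]."""
    mask = np.ones(state_size(nf, ns), dtype=np.bool_)
    mask[0:nf] = False                       # soma V
    mask[5 * nf:6 * nf] = False              # dend V
    mask[10 * nf:10 * nf + ns] = False       # SPN V
    return mask


@njit(cache=True)
def rhs(y, dy, nf, nd1, nd2, W_ff, W_fs, W_ss, G_adj, gj_deg,
        gna_f, gk_f, gl_f, gd_f, P, I_ext_f, I_in_spn):
    """Time derivative of the packed network state."""
    ns = nd1 + nd2
    Vs = y[0:nf]
    Hs = y[nf:2 * nf]
    Ns = y[2 * nf:3 * nf]
    As = y[3 * nf:4 * nf]
    Bs = y[4 * nf:5 * nf]
    Vd = y[5 * nf:6 * nf]
    Hd = y[6 * nf:7 * nf]
    Nd = y[7 * nf:8 * nf]
    Ad = y[8 * nf:9 * nf]
    Bd = y[9 * nf:10 * nf]
    o = 10 * nf
    Vp = y[o:o + ns]
    Mp = y[o + ns:o + 2 * ns]
    Hp = y[o + 2 * ns:o + 3 * ns]
    Np = y[o + 3 * ns:o + 4 * ns]
    Wp = y[o + 4 * ns:o + 5 * ns]
    Sf = y[o + 5 * ns:o + 5 * ns + nf]
    Ss = y[o + 5 * ns + nf:o + 5 * ns + nf + ns]

    cm_f = P[CM_F]
    ena_f, ek_f, el_f = P[ENA_F], P[EK_F], P[EL_F]
    tau_a, tau_b = P[TAU_A], P[TAU_B]
    dscale, gc = P[DSCALE], P[GC]
    e_i, tau_i, tau_r = P[E_I], P[TAU_I], P[TAU_R]

    if nf > 0:
        s_on_f = np.dot(Sf, W_ff)
        gj_in = np.dot(G_adj, Vd)
    else:
        s_on_f = np.zeros(0)
        gj_in = np.zeros(0)

    for i in range(nf):
        v = Vs[i]
        m = fsi_m_inf(v)
        i_mem = (gna_f[i] * m * m * m * Hs[i] * (v - ena_f)
                 + gk_f[i] * Ns[i] * Ns[i] * (v - ek_f)
                 + gd_f[i] * As[i] ** 3 * Bs[i] * (v - ek_f)
                 + gl_f[i] * (v - el_f))
        i_gaba = P[G_FF] * s_on_f[i] * (v - e_i)
        i_ds = gc * (Vd[i] - v)
        dy[i] = (-i_mem - i_gaba + i_ds) / cm_f
        dy[nf + i] = (fsi_h_inf(v) - Hs[i]) / fsi_tau_h(v)
        dy[2 * nf + i] = (fsi_n_inf(v) - Ns[i]) / fsi_tau_n(v)
        dy[3 * nf + i] = (fsi_a_inf(v) - As[i]) / tau_a
        dy[4 * nf + i] = (fsi_b_inf(v) - Bs[i]) / tau_b

        vd = Vd[i]
        md = fsi_m_inf(vd)
        i_mem_d = dscale * (gna_f[i] * md * md * md * Hd[i] * (vd - ena_f)
                            + gk_f[i] * Nd[i] * Nd[i] * (vd - ek_f)
                            + gd_f[i] * Ad[i] ** 3 * Bd[i] * (vd - ek_f)
                            + gl_f[i] * (vd - el_f))
        i_elec = P[G_GJ] * (gj_in[i] - gj_deg[i] * vd)
        i_sd = gc * (v - vd)
        dy[5 * nf + i] = (-i_mem_d + I_ext_f[i] + i_elec + i_sd) / cm_f
        dy[6 * nf + i] = (fsi_h_inf(vd) - Hd[i]) / fsi_tau_h(vd)
        dy[7 * nf + i] = (fsi_n_inf(vd) - Nd[i]) / fsi_tau_n(vd)
        dy[8 * nf + i] = (fsi_a_inf(vd) - Ad[i]) / tau_a
        dy[9 * nf + i] = (fsi_b_inf(vd) - Bd[i]) / tau_b

        # FSI-sourced GABA gate, driven by the somatic voltage
        dy[o + 5 * ns + i] = ((1.0 + np.tanh(v / 10.0)) / tau_r
                              * (1.0 - Sf[i]) - Sf[i] / tau_i)

    if ns > 0:
        if nf > 0:
            s_fs = np.dot(Sf, W_fs)
        else:
            s_fs = np.zeros(ns)
        s_ss = np.dot(Ss, W_ss)
        cm_s = P[CM_S]
        gna_s, gk_s, gl_s, gm_s = P[GNA_S], P[GK_S], P[GL_S], P[GM_S]
        ena_s, ek_s, el_s, qs = P[ENA_S], P[EK_S], P[EL_S], P[QS]
        for j in range(ns):
            v = Vp[j]
            i_mem = (gna_s * Mp[j] ** 3 * Hp[j] * (v - ena_s)
                     + gk_s * Np[j] ** 4 * (v - ek_s)
                     + gm_s * Wp[j] * (v - ek_s)
                     + gl_s * (v - el_s))
            i_syn = (P[G_FS] * s_fs[j] + P[G_SS] * s_ss[j]) * (v - e_i)
            dy[o + j] = (-i_mem - i_syn + I_in_spn[j]) / cm_s
            dy[o + ns + j] = (spn_alpha_m(v) * (1.0 - Mp[j])
                              - spn_beta_m(v) * Mp[j])
            dy[o + 2 * ns + j] = (spn_alpha_h(v) * (1.0 - Hp[j])
                                  - spn_beta_h(v) * Hp[j])
            dy[o + 3 * ns + j] = (spn_alpha_n(v) * (1.0 - Np[j])
                                  - spn_beta_n(v) * Np[j])
            dy[o + 4 * ns + j] = (spn_alpha_w(v, qs) * (1.0 - Wp[j])
                                  - spn_beta_w(v, qs) * Wp[j])
            # SPN-sourced GABA gate
            dy[o + 5 * ns + nf + j] = (2.0 * (1.0 + np.tanh(v / 4.0))
                                       * (1.0 - Ss[j]) - Ss[j] / tau_i)


@njit(cache=True)
def run_network(y0, nf, nd1, nd2, W_ff, W_fs, W_ss, G_adj, gj_deg,
                gna_f, gk_f, gl_f, gd_f, P,
                I_app_f, I_app_spn,
                dt, n_steps, record_stride,
                noise_rate_f, noise_amp_f, noise_kernel, noise_decay,
                spn_noise_amp, spn_noise_sqrt_dt,
                pulse_t0, pulse_t1, pulse_amp, pulse_lo, pulse_hi,
                spike_thresh, refractory, max_spikes,
                is_gate, seed):
    """Integrate the network; returns recorded traces and spike tables.

    Noise is held piecewise-constant over each RK4 step.  ``noise_kernel``
    0 injects each Poisson event as a single-step rectangular pulse of
    ``noise_amp_f``; 1 feeds events into a one-sided exponential kernel
    with per-step decay factor ``noise_decay``.  SPN noise is additive
    Gaussian with per-step amplitude ``spn_noise_amp * dt`` (literal) or
    ``spn_noise_amp * sqrt(dt)`` when ``spn_noise_sqrt_dt`` is set.
    """
    np.random.seed(seed)
    ns = nd1 + nd2
    n_state = y0.shape[0]
    o = 10 * nf

    y = y0.copy()
    k1 = np.zeros(n_state)
    k2 = np.zeros(n_state)
    k3 = np.zeros(n_state)
    k4 = np.zeros(n_state)
    yt = np.zeros(n_state)

    n_rec = n_steps // record_stride + 1
    rec_t = np.zeros(n_rec)
    rec_vs = np.zeros((nf, n_rec))
    rec_vd = np.zeros((nf, n_rec))
    rec_vspn = np.zeros((ns, n_rec))
    rec_isyn_f = np.zeros((nf, n_rec))
    rec_isyn_s_fsi = np.zeros((ns, n_rec))   # FSI-sourced GABA onto SPNs
    rec_isyn_s_spn = np.zeros((ns, n_rec))   # SPN-sourced GABA onto SPNs

    spk_t_f = np.zeros((nf, max_spikes))
    spk_n_f = np.zeros(nf, dtype=np.int64)
    spk_t_s = np.zeros((ns, max_spikes))
    spk_n_s = np.zeros(ns, dtype=np.int64)
    last_f = np.full(nf, -1e9)
    last_s = np.full(ns, -1e9)
    prev_vf = y[0:nf].copy()
    prev_vs = y[o:o + ns].copy()

    I_ext_f = np.zeros(nf)
    I_in_spn = np.zeros(ns)
    shot = np.zeros(nf)
    lam = noise_rate_f * dt * 1e-3  # events per step
    if spn_noise_sqrt_dt:
        g_amp = spn_noise_amp * np.sqrt(dt)
    else:
        g_amp = spn_noise_amp * dt

    status = STATUS_OK
    bad_index = -1
    bad_step = -1

    # record initial state
    _record(0, 0.0, y, nf, nd1, nd2, W_ff, W_fs, W_ss, P,
            rec_t, rec_vs, rec_vd, rec_vspn, rec_isyn_f,
            rec_isyn_s_fsi, rec_isyn_s_spn)
    rec_i = 1

    for step in range(n_steps):
        t = step * dt

        # refresh noise (held constant over the step)
        for i in range(nf):
            k = np.random.poisson(lam) if lam > 0.0 else 0
            if noise_kernel == 0:
                shot[i] = k * noise_amp_f
            else:
                shot[i] = shot[i] * noise_decay + k * noise_amp_f
            I_ext_f[i] = I_app_f[i] + shot[i]
        for j in range(ns):
            if g_amp > 0.0:
                I_in_spn[j] = I_app_spn[j] + g_amp * np.random.normal(0.0, 1.0)
            else:
                I_in_spn[j] = I_app_spn[j]
        for p in range(pulse_t0.shape[0]):
            if pulse_t0[p] <= t < pulse_t1[p]:
                for j in range(pulse_lo[p], pulse_hi[p]):
                    I_in_spn[j] += pulse_amp[p]

        # classical RK4
        rhs(y, k1, nf, nd1, nd2, W_ff, W_fs, W_ss, G_adj, gj_deg,
            gna_f, gk_f, gl_f, gd_f, P, I_ext_f, I_in_spn)
        for i in range(n_state):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        rhs(yt, k2, nf, nd1, nd2, W_ff, W_fs, W_ss, G_adj, gj_deg,
            gna_f, gk_f, gl_f, gd_f, P, I_ext_f, I_in_spn)
        for i in range(n_state):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        rhs(yt, k3, nf, nd1, nd2, W_ff, W_fs, W_ss, G_adj, gj_deg,
            gna_f, gk_f, gl_f, gd_f, P, I_ext_f, I_in_spn)
        for i in range(n_state):
            yt[i] = y[i] + dt * k3[i]
        rhs(yt, k4, nf, nd1, nd2, W_ff, W_fs, W_ss, G_adj, gj_deg,
            gna_f, gk_f, gl_f, gd_f, P, I_ext_f, I_in_spn)
        for i in range(n_state):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        # gate bounds: clamp rounding-level overshoot, flag instability
        for i in range(n_state):
            if is_gate[i]:
                g = y[i]
                if g < 0.0:
                    if g > -GATE_CLAMP_TOL:
                        y[i] = 0.0
                    else:
                        status = STATUS_GATE_OVERSHOOT
                        bad_index = i
                        bad_step = step
                elif g > 1.0:
                    if g < 1.0 + GATE_CLAMP_TOL:
                        y[i] = 1.0
                    else:
                        status = STATUS_GATE_OVERSHOOT
                        bad_index = i
                        bad_step = step
        if status != STATUS_OK:
            break

        t_next = (step + 1) * dt

        # online spike detection at full resolution (upward crossing)
        for i in range(nf):
            v = y[i]
            if prev_vf[i] < spike_thresh <= v and t_next - last_f[i] >= refractory:
                if spk_n_f[i] < max_spikes:
                    spk_t_f[i, spk_n_f[i]] = t_next
                    spk_n_f[i] += 1
                else:
                    status = STATUS_SPIKE_OVERFLOW
                    bad_index = i
                last_f[i] = t_next
            prev_vf[i] = v
        for j in range(ns):
            v = y[o + j]
            if prev_vs[j] < spike_thresh <= v and t_next - last_s[j] >= refractory:
                if spk_n_s[j] < max_spikes:
                    spk_t_s[j, spk_n_s[j]] = t_next
                    spk_n_s[j] += 1
                else:
                    status = STATUS_SPIKE_OVERFLOW
                    bad_index = j
                last_s[j] = t_next
            prev_vs[j] = v
        if status != STATUS_OK:
            break

        if (step + 1) % record_stride == 0:
            # blow-up check piggybacked on recording
            for i in range(n_state):
                if not np.isfinite(y[i]):
                    status = STATUS_NONFINITE
                    bad_index = i
                    bad_step = step
                    break
            if status != STATUS_OK:
                break
            _record(rec_i, t_next, y, nf, nd1, nd2, W_ff, W_fs, W_ss, P,
                    rec_t, rec_vs, rec_vd, rec_vspn, rec_isyn_f,
                    rec_isyn_s_fsi, rec_isyn_s_spn)
            rec_i += 1

    return (status, bad_index, bad_step, rec_t, rec_vs, rec_vd, rec_vspn,
            rec_isyn_f, rec_isyn_s_fsi, rec_isyn_s_spn,
            spk_t_f, spk_n_f, spk_t_s, spk_n_s, y)


@njit(cache=True)
def _record(idx, t, y, nf, nd1, nd2, W_ff, W_fs, W_ss, P,
            rec_t, rec_vs, rec_vd, rec_vspn, rec_isyn_f,
            rec_isyn_s_fsi, rec_isyn_s_spn):
    ns = nd1 + nd2
    o = 10 * nf
    rec_t[idx] = t
    Sf = y[o + 5 * ns:o + 5 * ns + nf]
    Ss = y[o + 5 * ns + nf:o + 5 * ns + nf + ns]
    if nf > 0:
        s_on_f = np.dot(Sf, W_ff)
        for i in range(nf):
            rec_vs[i, idx] = y[i]
            rec_vd[i, idx] = y[5 * nf + i]
            rec_isyn_f[i, idx] = P[G_FF] * s_on_f[i] * (y[i] - P[E_I])
    if ns > 0:
        if nf > 0:
            s_fs = np.dot(Sf, W_fs)
        else:
            s_fs = np.zeros(ns)
        s_ss = np.dot(Ss, W_ss)
        for j in range(ns):
            v = y[o + j]
            rec_vspn[j, idx] = v
            rec_isyn_s_fsi[j, idx] = P[G_FS] * s_fs[j] * (v - P[E_I])
            rec_isyn_s_spn[j, idx] = P[G_SS] * s_ss[j] * (v - P[E_I])
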