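"""Compiled integrator for the CRU-lattice myocyte model.

Single forward-Euler / Rush-Larsen time loop over a 1-D chain of Ca2+
release units coupled to a shared cytosolic compartment chain, network SR
and a Hodgkin-Huxley-style sarcolemma.  All bookkeeping is done in
amounts per litre of cytosol, with antisymmetric flux exchanges, so total
cell Ca2+ is conserved exactly (to rounding) when sarcolemmal fluxes are
disabled.

Stochastics: each CRU owns a named counter-based RNG stream (SplitMix64)
derived from the master seed, so trajectories are bit-reproducible and
individual CRU streams are independent of the number of steps other CRUs
consume.

The module is deliberately free of Python objects in the hot path: the
caller packs parameters with :func:`crusparks.params.pack_params` and
passes flat state arrays (see :mod:`crusparks.model.cell` for the
friendly wrapper).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..params import P_IDX

# parameter indices resolved at import time (compile-time constants)
_IP = {k: int(v) for k, v in P_IDX.items()}

I_K_SENS = _IP["k_sens"]; I_K_REFR = _IP["k_refr"]; I_LAMBDA0 = _IP["lambda0"]
I_K_HALF = _IP["K_half"]; I_HILL_H = _IP["hill_h"]; I_TAU_REFILL = _IP["tau_refill"]
I_GAMMA = _IP["gamma_rec"]; I_JRELMAX = _IP["J_rel_max"]; I_TAU_RR = _IP["tau_refr_R"]
I_R_RESET = _IP["R_reset"]; I_TAU_OPEN = _IP["tau_open"]; I_CJSR_REF = _IP["c_jsr_ref"]
I_N_CRU = _IP["n_cru"]; I_DX = _IP["dx"]; I_V_SS = _IP["v_ss"]; I_V_JSR = _IP["v_jsr"]
I_V_NSR = _IP["v_nsr"]; I_BETA_SR = _IP["beta_sr"]; I_B_TOT = _IP["b_tot"]
I_B_KD = _IP["b_kd"]; I_D_CA = _IP["d_ca"]; I_TAU_SS = _IP["tau_ss"]
I_V_UP = _IP["v_up"]; I_K_UP = _IP["k_up"]; I_G_LEAK = _IP["g_leak"]
I_J_BG = _IP["j_bg"]; I_CAL_SS = _IP["cal_ss_frac"]; I_C_REST = _IP["c_rest"]
I_G_NA = _IP["g_na"]; I_G_CAL = _IP["g_cal"]; I_E_CAL = _IP["e_cal"]
I_K_FCA = _IP["k_fca"]; I_G_KR = _IP["g_kr"]; I_G_KS = _IP["g_ks"]
I_G_TO = _IP["g_to"]; I_G_K1 = _IP["g_k1"]; I_G_NAK = _IP["g_nak"]
I_G_NCX = _IP["g_ncx"]; I_NCX_SUB = _IP["ncx_sub_frac"]
I_E_NA = _IP["e_na"]; I_E_K = _IP["e_k"]
I_NA_I = _IP["na_i"]; I_NA_O = _IP["na_o"]; I_CA_O = _IP["ca_o"]
I_KM_NA = _IP["km_na"]; I_KM_CA = _IP["km_ca"]; I_ETA = _IP["eta"]
I_K_SAT = _IP["k_sat"]; I_CM = _IP["cm"]; I_C2F = _IP["current_to_flux"]
I_STIM_AMP = _IP["stim_amp"]; I_STIM_DUR = _IP["stim_dur"]
I_DT = _IP["dt"]; I_CRU_SUB = _IP["cru_substep"]; I_SARCO = _IP["sarco_on"]

# global-state vector layout
S_T = 0; S_VM = 1; S_CNSR = 2; S_M = 3; S_H = 4; S_J = 5; S_D = 6; S_F = 7
S_XR = 8; S_XS = 9; S_ATO = 10; S_ITO = 11
N_GSTATE = 12

# recorded current order
CURRENT_NAMES = ("I_Na", "I_CaL", "I_NCX", "I_Kr", "I_Ks", "I_to", "I_K1",
                 "I_NaK", "I_stim")

RT_F = 26.712  # mV at 37 C


# ---------------------------------------------------------------------------
# per-CRU SplitMix64 streams
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def _splitmix64(state):
    z = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    out = z
    out = ((out ^ (out >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    out = ((out ^ (out >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    out = out ^ (out >> np.uint64(31))
    return z, out


@njit(cache=False, inline="always")
def _uniform(states, i):
    s, out = _splitmix64(states[i])
    states[i] = s
    return (out >> np.uint64(11)) * (1.0 / 9007199254740992.0)


def seed_streams(master_seed: int, n: int) -> np.ndarray:
    """Derive n named CRU streams from a master seed (one state per CRU)."""
    states = np.empty(n, dtype=np.uint64)
    s = np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF) ^ np.uint64(0xD1B54A32D192ED03)
    for i in range(n):
        s = np.uint64((int(s) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
        z = int(s)
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        states[i] = np.uint64(z ^ (z >> 31))
    return states


# ---------------------------------------------------------------------------
# scalar pieces
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def trigger_rate(c_ss, R, lambda0, k_half_eff, h, gamma):
    """Cluster spark trigger rate lambda0 * Hill(c_ss) * R^gamma (1/ms)."""
    if c_ss <= 0.0:
        return 0.0
    ch = c_ss ** h
    return lambda0 * ch / (ch + k_half_eff ** h) * R ** gamma


@njit(cache=False, inline="always")
def free_from_total(a, b_tot, b_kd):
    """Free [Ca2+] from total (free + rapid-buffer bound): quadratic inversion."""
    b = b_tot + b_kd - a
    c = 0.5 * (-b + math.sqrt(b * b + 4.0 * b_kd * a))
    return c if c > 1e-12 else 1e-12


@njit(cache=False, inline="always")
def total_from_free(c, b_tot, b_kd):
    return c + b_tot * c / (c + b_kd)


@njit(cache=False, inline="always")
def ncx_current(v, c_sub, g_ncx, na_i, na_o, ca_o, km_na, km_ca, eta, k_sat):
    """Electrogenic 3:1 Na/Ca exchange density (pA/pF); inward negative."""
    vf = v / RT_F
    e1 = math.exp(eta * vf)
    e2 = math.exp((eta - 1.0) * vf)
    num = e1 * na_i ** 3 * ca_o - e2 * na_o ** 3 * c_sub
    den = (km_na ** 3 + na_o ** 3) * (km_ca + ca_o) * (1.0 + k_sat * e2)
    return g_ncx * num / den


@njit(cache=False)
def gate_rates(v, out):
    """inf/tau pairs for m,h,j,d,f,xr,xs,ato,ito -> out[18]."""
    # I_Na activation / inactivation (Luo-Rudy style)
    am = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13))) \
        if abs(v + 47.13) > 1e-6 else 3.2
    bm = 0.08 * math.exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp((v + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * math.exp((80.0 + v) / -6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23)))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    out[0] = am / (am + bm); out[1] = 1.0 / (am + bm)
    out[2] = ah / (ah + bh); out[3] = 1.0 / (ah + bh)
    out[4] = aj / (aj + bj); out[5] = 1.0 / (aj + bj)

    # I_CaL d (activation) and f (voltage inactivation with pedestal)
    dinf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 6.24))
    taud = 1.0 / (0.25 + abs(v + 10.0) / 30.0) + 1.2
    finf = 1.0 / (1.0 + math.exp((v + 32.0) / 8.0)) \
        + 0.10 / (1.0 + math.exp((50.0 - v) / 20.0))
    tauf = 20.0 + 60.0 * math.exp(-((v + 25.0) / 25.0) ** 2)
    out[6] = dinf; out[7] = taud
    out[8] = finf; out[9] = tauf

    # I_Kr activation
    xrinf = 1.0 / (1.0 + math.exp(-(v + 21.5) / 7.5))
    a_xr = 0.00138 * (v + 14.2) / (1.0 - math.exp(-0.123 * (v + 14.2))) \
        if abs(v + 14.2) > 1e-6 else 0.00138 / 0.123
    b_xr = 0.00061 * (v + 38.9) / (math.exp(0.145 * (v + 38.9)) - 1.0) \
        if abs(v + 38.9) > 1e-6 else 0.00061 / 0.145
    out[10] = xrinf; out[11] = 1.0 / (a_xr + b_xr)

    # I_Ks activation
    xsinf = 1.0 / (1.0 + math.exp(-(v - 1.5) / 16.7))
    a_xs = 7.19e-5 * (v + 30.0) / (1.0 - math.exp(-0.148 * (v + 30.0))) \
        if abs(v + 30.0) > 1e-6 else 7.19e-5 / 0.148
    b_xs = 1.31e-4 * (v + 30.0) / (math.exp(0.0687 * (v + 30.0)) - 1.0) \
        if abs(v + 30.0) > 1e-6 else 1.31e-4 / 0.0687
    out[12] = xsinf; out[13] = 1.0 / (a_xs + b_xs)

    # I_to activation / inactivation
    out[14] = 1.0 / (1.0 + math.exp(-(v - 5.0) / 14.0)); out[15] = 2.5
    out[16] = 1.0 / (1.0 + math.exp((v + 42.0) / 5.0))
    out[17] = 25.0 + 40.0 / (1.0 + math.exp((v + 20.0) / 8.0))
    return out


@njit(cache=False)
def membrane_currents(v, g, c_ss_mean, c_sub_ncx, P, out):
    """All current densities (pA/pF) into out[9]; returns their sum.

    g = gate vector slice [m,h,j,d,f,xr,xs,ato,ito]; c_ss_mean drives
    Ca-dependent inactivation of I_CaL; c_sub_ncx drives NCX.
    """
    e_k = P[I_E_K]
    i_na = P[I_G_NA] * g[0] ** 3 * g[1] * g[2] * (v - P[I_E_NA])
    # Ca-dependent inactivation driven by dyadic subspace Ca, with a
    # pedestal (inactivation is partial even at high local Ca)
    fca = 0.3 + 0.7 / (1.0 + (c_ss_mean / P[I_K_FCA]) ** 2)
    i_cal = P[I_G_CAL] * g[3] * g[4] * fca * (v - P[I_E_CAL])
    i_ncx = ncx_current(v, c_sub_ncx, P[I_G_NCX], P[I_NA_I], P[I_NA_O],
                        P[I_CA_O], P[I_KM_NA], P[I_KM_CA], P[I_ETA], P[I_K_SAT])
    rkr = 1.0 / (1.0 + math.exp((v + 9.0) / 22.4))
    i_kr = P[I_G_KR] * g[5] * rkr * (v - e_k)
    i_ks = P[I_G_KS] * g[6] * g[6] * (v - e_k)
    # transient outward with a sustained (non-inactivating) component,
    # the rodent/rabbit steady-state K+ current folded into I_to
    i_to = P[I_G_TO] * g[7] * (g[8] + 0.30) * (v - e_k)
    # inward rectifier
    dv = v - e_k
    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (dv - 59.215)))
    bk1 = (0.49124 * math.exp(0.08032 * (dv + 5.476))
           + math.exp(0.06175 * (dv - 594.31))) \
        / (1.0 + math.exp(-0.5143 * (dv + 4.753)))
    i_k1 = P[I_G_K1] * ak1 / (ak1 + bk1) * dv
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RT_F)
                   + 0.0365 * math.exp(-v / RT_F))
    i_nak = P[I_G_NAK] * f_nak
    out[0] = i_na; out[1] = i_cal; out[2] = i_ncx; out[3] = i_kr
    out[4] = i_ks; out[5] = i_to; out[6] = i_k1; out[7] = i_nak; out[8] = 0.0
    return i_na + i_cal + i_ncx + i_kr + i_ks + i_to + i_k1 + i_nak


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@njit(cache=False)
def integrate(P, gstate, a_i, c_ss, c_jsr, open_state, t_open, R, rng_states,
              refr_fac,
              n_steps, stim_times, clamp_mode, command, ica_replay,
              block_t0, block_t1, rec_every,
              rec_t, rec_vm, rec_cmean, rec_cnsr, rec_cssmean, rec_cur,
              rec_iclamp, rec_ci,
              ev_t, ev_x, ev_dur, ev_cjsr, ev_open_idx, ev_count_in):
    """Advance the full cell model n_steps; fills recording/event arrays.

    Returns (status, n_recorded, n_events): status 0 = ok, 1 = numerical
    failure (NaN or negative concentration).
    """
    dt = P[I_DT]
    n_cru = int(P[I_N_CRU])
    sub = int(P[I_CRU_SUB])
    dt_cru = dt * sub
    sarco = P[I_SARCO] > 0.5
    w = 1.0 / n_cru                      # cytosol volume fraction per compartment
    v_ss_i = P[I_V_SS] / n_cru
    v_jsr_i = P[I_V_JSR] / n_cru
    beta_sr = P[I_BETA_SR]
    b_tot = P[I_B_TOT]; b_kd = P[I_B_KD]
    difco = P[I_D_CA] / (P[I_DX] * P[I_DX])
    k_half_eff = P[I_K_HALF] / P[I_K_SENS]
    h_hill = P[I_HILL_H]
    gamma = P[I_GAMMA]
    lam0 = P[I_LAMBDA0]
    tau_refill_eff = P[I_TAU_REFILL] * P[I_K_REFR]
    tau_rr_eff = P[I_TAU_RR] * P[I_K_REFR]
    tau_open = P[I_TAU_OPEN]
    jrelmax = P[I_JRELMAX]
    cjsr_ref = P[I_CJSR_REF]
    c2f = P[I_C2F]

    curbuf = np.empty(9)
    rates = np.empty(18)
    c_i = np.empty(n_cru)
    ncx_i = np.empty(n_cru)
    cal_i = np.empty(n_cru)
    gates = np.empty(9)

    t = gstate[S_T]
    vm = gstate[S_VM]
    c_nsr = gstate[S_CNSR]
    for k in range(9):
        gates[k] = gstate[S_M + k]

    n_rec = 0
    n_ev = int(ev_count_in)
    stim_ptr = 0
    n_stim = stim_times.shape[0]
    replay = ica_replay.shape[0] > 0

    for step in range(n_steps):
        # free cytosolic Ca per compartment
        for i in range(n_cru):
            c_i[i] = free_from_total(a_i[i], b_tot, b_kd)

        # stimulus current
        i_stim = 0.0
        if clamp_mode == 0:
            while stim_ptr < n_stim and t >= stim_times[stim_ptr] + P[I_STIM_DUR]:
                stim_ptr += 1
            if stim_ptr < n_stim and stim_times[stim_ptr] <= t:
                i_stim = P[I_STIM_AMP]

        # mean subspace Ca (drives CDI); NCX handled per CRU below
        css_mean = 0.0
        for i in range(n_cru):
            css_mean += c_ss[i]
        css_mean *= w

        # per-CRU NCX (driven by the submembrane cytosolic Ca at each
        # release site — local sparks produce inward current) and per-CRU
        # L-type current (Ca-dependent inactivation driven by each dyad's
        # own subspace Ca: dyads engaged in release inactivate their LCCs
        # while LCCs over quiescent dyads keep conducting)
        i_ncx_tot = 0.0
        i_cal_tot = 0.0
        df_gate = gates[3] * gates[4] * P[I_G_CAL] * (vm - P[I_E_CAL])
        phi = P[I_NCX_SUB]
        for i in range(n_cru):
            # submembrane Ca: local cytosolic plus a small dyadic admixture
            c_sub = c_i[i] + phi * (c_ss[i] - c_i[i])
            ncx_i[i] = ncx_current(vm, c_sub, P[I_G_NCX], P[I_NA_I],
                                   P[I_NA_O], P[I_CA_O], P[I_KM_NA],
                                   P[I_KM_CA], P[I_ETA], P[I_K_SAT])
            i_ncx_tot += ncx_i[i]
            fca_i = 0.3 + 0.7 / (1.0 + (c_ss[i] / P[I_K_FCA]) ** 2)
            cal_i[i] = df_gate * fca_i
            i_cal_tot += cal_i[i]
        i_ncx_tot *= w
        i_cal_tot *= w

        s_ion = membrane_currents(vm, gates, css_mean, css_mean, P, curbuf)
        s_ion += i_ncx_tot - curbuf[2]
        curbuf[2] = i_ncx_tot
        s_ion += i_cal_tot - curbuf[1]
        curbuf[1] = i_cal_tot
        if replay:
            s_ion += ica_replay[step] - curbuf[1]
            curbuf[1] = ica_replay[step]
            # replayed current is distributed uniformly across dyads
            for i in range(n_cru):
                cal_i[i] = ica_replay[step]
        curbuf[8] = i_stim

        # ------- Ca fluxes (amounts in uM of cytosol) -------

        for i in range(n_cru):
            # release
            j_rel = jrelmax * (c_jsr[i] / cjsr_ref) if open_state[i] == 1 else 0.0
            # subspace <-> cytosol transfer
            j_x = (c_ss[i] - c_i[i]) * v_ss_i / P[I_TAU_SS]
            dss = (j_rel - j_x) / v_ss_i
            if sarco:
                # only the junctional share of this dyad's I_CaL flux
                dss += P[I_CAL_SS] * (-cal_i[i] * w * c2f) / v_ss_i
            c_ss[i] += dt * dss
            if c_ss[i] < 1e-9:
                c_ss[i] = 1e-9
            a_i[i] += dt * j_x / w
            if sarco:
                # NCX: one Ca per unit charge; inward (negative) = extrusion
                # from the submembrane cytosolic compartment; plus the
                # non-junctional share of this site's I_CaL influx
                a_i[i] += dt * (ncx_i[i] * 2.0 * c2f
                                - (1.0 - P[I_CAL_SS]) * cal_i[i] * c2f)
            # JSR depletion and refill (same flux value on both sides)
            j_refill = (c_nsr - c_jsr[i]) / tau_refill_eff   # free-conc rate
            c_jsr[i] += dt * (j_refill - j_rel / (v_jsr_i * beta_sr))
            if c_jsr[i] < 0.0:
                c_jsr[i] = 0.0
            c_nsr -= dt * j_refill * v_jsr_i / P[I_V_NSR]
            # SERCA and leak
            j_up = P[I_V_UP] * c_i[i] * c_i[i] / (c_i[i] * c_i[i]
                                                  + P[I_K_UP] * P[I_K_UP])
            j_leak = P[I_G_LEAK] * (c_nsr - c_i[i])
            a_i[i] += dt * (j_leak - j_up)
            c_nsr += dt * (j_up - j_leak) * w / (P[I_V_NSR] * beta_sr)
            if sarco:
                a_i[i] += dt * P[I_J_BG]
            # R recovery while closed (per-site heterogeneous time constant)
            if open_state[i] == 0:
                R[i] += dt * (1.0 - R[i]) / (tau_rr_eff * refr_fac[i])
                if R[i] > 1.0:
                    R[i] = 1.0

        # diffusion of free Ca along the chain (reflecting ends)
        for i in range(n_cru):
            left = c_i[i - 1] if i > 0 else c_i[i]
            right = c_i[i + 1] if i < n_cru - 1 else c_i[i]
            a_i[i] += dt * difco * (left - 2.0 * c_i[i] + right)

        # ------- CRU gating substep -------
        if step % sub == 0:
            in_block = block_t0 <= t < block_t1
            for i in range(n_cru):
                if open_state[i] == 1:
                    t_open[i] += dt_cru
                    p_close = 1.0 - math.exp(-dt_cru / tau_open)
                    if _uniform(rng_states, i) < p_close:
                        open_state[i] = 0
                        R[i] = P[I_R_RESET]
                        if 0 <= ev_open_idx[i] < ev_t.shape[0]:
                            ev_dur[ev_open_idx[i]] = t_open[i]
                        ev_open_idx[i] = -1
                else:
                    if not in_block:
                        rate = trigger_rate(c_ss[i], R[i], lam0, k_half_eff,
                                            h_hill, gamma)
                        p_open = 1.0 - math.exp(-rate * dt_cru)
                        if _uniform(rng_states, i) < p_open:
                            open_state[i] = 1
                            t_open[i] = 0.0
                            if n_ev < ev_t.shape[0]:
                                ev_t[n_ev] = t
                                ev_x[n_ev] = i
                                ev_cjsr[n_ev] = c_jsr[i]
                                ev_dur[n_ev] = -1.0
                                ev_open_idx[i] = n_ev
                                n_ev += 1

        # ------- membrane update -------
        gate_rates(vm, rates)
        for k in range(9):
            inf = rates[2 * k]
            tau = rates[2 * k + 1]
            gates[k] = inf + (gates[k] - inf) * math.exp(-dt / tau)

        if clamp_mode == 0:
            vm += -dt * (s_ion + i_stim) / P[I_CM]
            i_clamp = 0.0
        else:
            # clamp current the amplifier injects to impose the command:
            # I_clamp = Cm dV/dt + sum(I_ionic)
            cmd = command[step] if command.shape[0] > 1 else command[0]
            if command.shape[0] > 1 and step + 1 < command.shape[0]:
                dcmd = (command[step + 1] - command[step]) / dt
            else:
                dcmd = 0.0
            i_clamp = s_ion + P[I_CM] * dcmd
            vm = cmd

        t += dt

        # ------- recording -------
        if step % rec_every == 0:
            if n_rec < rec_t.shape[0]:
                rec_t[n_rec] = t
                rec_vm[n_rec] = vm
                cm = 0.0
                for i in range(n_cru):
                    cm += c_i[i]
                rec_cmean[n_rec] = cm * w
                rec_cnsr[n_rec] = c_nsr
                rec_cssmean[n_rec] = css_mean
                for k in range(9):
                    rec_cur[k, n_rec] = curbuf[k]
                rec_iclamp[n_rec] = i_clamp
                for i in range(n_cru):
                    rec_ci[i, n_rec] = c_i[i]
                n_rec += 1

        # sanity check every 10k steps
        if step % 10000 == 0:
            if not (math.isfinite(vm) and math.isfinite(c_nsr)
                    and c_nsr >= 0.0):
                gstate[S_T] = t; gstate[S_VM] = vm; gstate[S_CNSR] = c_nsr
                return 1, n_rec, n_ev

    gstate[S_T] = t
    gstate[S_VM] = vm
    gstate[S_CNSR] = c_nsr
    for k in range(9):
        gstate[S_M + k] = gates[k]
    return 0, n_rec, n_ev


@njit(cache=False)
def total_calcium(P, a_i, c_ss, c_jsr, c_nsr):
    """Total cell Ca2+ in uM per litre of cytosol (free + buffered, all stores)."""
    n_cru = int(P[I_N_CRU])
    w = 1.0 / n_cru
    v_ss_i = P[I_V_SS] / n_cru
    v_jsr_i = P[I_V_JSR] / n_cru
    tot = 0.0
    for i in range(n_cru):
        tot += w * a_i[i]
        tot += v_ss_i * c_ss[i]
        tot += v_jsr_i * c_jsr[i] * P[I_BETA_SR]
    tot += P[I_V_NSR] * c_nsr * P[I_BETA_SR]
    return tot
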