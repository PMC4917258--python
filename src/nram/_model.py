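"""Compiled core of the NRAM ionic model.

Everything numerical lives here as scalar numba functions plus two driver
kernels (single cell and tissue).  The public modules (:mod:`nram.kinetics`,
:mod:`nram.currents`, :mod:`nram.cell`, :mod:`nram.tissue`) wrap these same
functions, so the integrator and the inspection API cannot drift apart.

Sign conventions: outward membrane current is positive (pA/pF); a positive
stimulus is depolarizing, dV/dt = (-I_ion + I_stim)/Cm.  SR fluxes J_up,
J_leak, J_rel are expressed in cytosolic-volume mM/ms; J_tr in JSR-volume
mM/ms.
"""

import math

import numpy as np
from numba import njit

from .constants import (
    FARADAY, GAS_R, NVAR, NOUT, MODE_SINGLE_CELL,
    S_V, S_M, S_H, S_J, S_D, S_F, S_FCA, S_B, S_G, S_R, S_S, S_S_SLOW,
    S_UA, S_UI, S_XR, S_XS1, S_XS2, S_Y,
    S_CA_I, S_CA_NSR, S_CA_JSR, S_RYR_R, S_RYR_O, S_RYR_I,
    S_B_TRPN, S_B_CMDN, S_B_CSQN,
    P_G_NA, P_G_CAL, P_G_CAT, P_G_TO, P_G_KUR, P_G_KR, P_G_KS, P_K_KSUS,
    P_G_K1, P_G_KLEAK, P_G_KACH, P_G_F, P_G_NAB, P_G_CAB,
    P_I_NAK_MAX, P_K_NCX, P_D_NCX, P_GAMMA_NCX, P_KM_NAI, P_KM_KO,
    P_NA_O, P_NA_I, P_K_O, P_K_I, P_CA_O, P_ACH, P_TEMPERATURE,
    P_CM, P_C_CELL, P_CA_CONV, P_R_NSR, P_R_JSR,
    P_VMAX_UP, P_KMF_UP, P_KMR_UP, P_H_UP, P_TAU_TR, P_K_LEAK_SR,
    P_KO_CA, P_KOM, P_KI_CA, P_KIM, P_EC50_SR, P_MAX_SR, P_MIN_SR,
    P_KS_REL, P_K_LOCAL,
    P_TRPN_TOT, P_KD_TRPN, P_KON_TRPN,
    P_CMDN_TOT, P_KD_CMDN, P_KON_CMDN,
    P_CSQN_TOT, P_KD_CSQN, P_KON_CSQN,
    P_K_TEMP_NA, P_TAU_D_SHIFT,
    M_G_NA, M_G_CAL, M_G_CAT, M_G_TO, M_G_KUR, M_G_KR, M_G_KS,
    M_G_K1, M_G_KLEAK, M_G_KACH, M_G_F, M_G_NAB, M_G_CAB,
    M_I_NAK_MAX, M_K_NCX, M_VMAX_UP, M_KS_REL, M_K_LEAK_SR, M_J_TR,
    B_I_NA, B_I_CAL, B_I_CAT, B_I_TO, B_I_KSUS, B_I_K1, B_I_KACH,
    B_I_F, B_I_NAK, B_I_NCX, B_I_NAB, B_I_CAB,
    C_I_NA, C_I_CAL, C_I_CAT, C_I_TO, C_I_KSUS, C_I_K1, C_I_KACH,
    C_I_F, C_I_NAK, C_I_NCX, C_I_NAB, C_I_CAB,
    C_J_UP, C_J_REL, C_J_LEAK, C_J_TR, C_I_TOTAL,
)

_NJIT = dict(cache=False, fastmath=False)


@njit(**_NJIT)
def rtf(temperature):
    """R*T/F in mV."""
    return 1000.0 * GAS_R * temperature / FARADAY


@njit(**_NJIT)
def nernst(z, x_o, x_i, temperature):
    return rtf(temperature) / z * math.log(x_o / x_i)


# ---------------------------------------------------------------------------
# gating kinetics: (x_inf, tau_x [ms]) as functions of V [mV]
# ---------------------------------------------------------------------------

@njit(**_NJIT)
def kin_m(v, k_temp_na):
    # activation fitted to neonatal rat atrial data; tau from the Luo-Rudy
    # rate constants, slowed for room temperature by k_temp_na
    m_inf = 1.0 / (1.0 + math.exp(-(v + 44.0) / 6.0))
    dv = v + 47.13
    if abs(dv) < 1e-6:
        a_m = 3.2
    else:
        a_m = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    b_m = 0.08 * math.exp(-v / 11.0)
    return m_inf, k_temp_na / (a_m + b_m)


@njit(**_NJIT)
def kin_h(v, k_temp_na):
    h_inf = 1.0 / (1.0 + math.exp((v + 64.0) / 5.0))
    if v < -40.0:
        a_h = 0.135 * math.exp(-(80.0 + v) / 6.8)
        b_h = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
    else:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    return h_inf, k_temp_na / (a_h + b_h)


@njit(**_NJIT)
def kin_j(v, k_temp_na):
    # slow inactivation shares the fitted steady state with h
    j_inf = 1.0 / (1.0 + math.exp((v + 64.0) / 5.0))
    if v < -40.0:
        a_j = ((-1.2714e5 * math.exp(0.2444 * v)
                - 3.474e-5 * math.exp(-0.04391 * v)) * (v + 37.78)
               / (1.0 + math.exp(0.311 * (v + 79.23))))
        b_j = (0.1212 * math.exp(-0.01052 * v)
               / (1.0 + math.exp(-0.1378 * (v + 40.14))))
    else:
        a_j = 0.0
        b_j = (0.3 * math.exp(-2.535e-7 * v)
               / (1.0 + math.exp(-0.1 * (v + 32.0))))
    return j_inf, k_temp_na / (a_j + b_j)


@njit(**_NJIT)
def kin_d(v, tau_d_shift):
    d_inf = 1.0 / (1.0 + math.exp(-(v + 8.0) / 6.0))
    a_d = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    return d_inf, a_d * b_d + g_d + tau_d_shift


@njit(**_NJIT)
def kin_f(v):
    f_inf = 1.0 / (1.0 + math.exp((v + 40.0) / 4.5))
    tau = (22.0 + 15.0 * math.exp(-(v + 27.0) ** 2 / 300.0)
           + 30.0 / (1.0 + math.exp((25.0 - v) / 10.0)))
    return f_inf, tau


@njit(**_NJIT)
def kin_fca(ca_i):
    # Ca-dependent inactivation; half-inhibition at 0.75 uM cytosolic Ca
    fca_inf = 1.0 / (1.0 + (ca_i / 7.5e-4) ** 2)
    return fca_inf, 10.0


@njit(**_NJIT)
def kin_b(v):
    b_inf = 1.0 / (1.0 + math.exp(-(v + 37.5) / 5.4))
    tau = 1.0 + 5.0 / (1.0 + math.exp((v + 60.0) / 10.0))
    return b_inf, tau


@njit(**_NJIT)
def kin_g(v):
    g_inf = 1.0 / (1.0 + math.exp((v + 60.0) / 4.5))
    tau = 8.0 + 32.0 / (1.0 + math.exp((v + 60.0) / 10.0))
    return g_inf, tau


@njit(**_NJIT)
def kin_r(v):
    r_inf = 1.0 / (1.0 + math.exp(-(v + 10.6) / 11.42))
    tau = 1000.0 / (45.16 * math.exp(0.03577 * (v + 50.0))
                    + 98.9 * math.exp(-0.1 * (v + 38.0)))
    return r_inf, tau


@njit(**_NJIT)
def kin_s(v):
    s_inf = 1.0 / (1.0 + math.exp((v + 45.3) / 6.8841))
    tau = 350.0 * math.exp(-((v + 70.0) / 15.0) ** 2) + 35.0
    return s_inf, tau


@njit(**_NJIT)
def kin_s_slow(v):
    s_inf = 1.0 / (1.0 + math.exp((v + 45.3) / 6.8841))
    tau = 3700.0 * math.exp(-((v + 70.0) / 30.0) ** 2) + 35.0
    return s_inf, tau


@njit(**_NJIT)
def kin_ua(v):
    ua_inf = 1.0 / (1.0 + math.exp(-(v + 22.5) / 7.7))
    tau = 0.493 * math.exp(-0.0629 * v) + 2.058
    return ua_inf, tau


@njit(**_NJIT)
def kin_ui(v):
    ui_inf = 1.0 / (1.0 + math.exp((v + 45.2) / 5.7))
    tau = 1200.0 - 170.0 / (1.0 + math.exp((v + 45.2) / 5.7))
    return ui_inf, tau


@njit(**_NJIT)
def kin_xr(v):
    xr_inf = 1.0 / (1.0 + math.exp(-(v + 10.0) / 7.0))
    # slow deactivation below -50 mV keeps the current through phase 3
    tau = (20.0 + 180.0 * math.exp(-((v + 20.0) / 30.0) ** 2)
           + 500.0 / (1.0 + math.exp((v + 50.0) / 8.0)))
    return xr_inf, tau


@njit(**_NJIT)
def kin_xs1(v):
    xs_inf = 1.0 / (1.0 + math.exp(-(v - 9.0) / 13.8))
    tau = 200.0 + 500.0 / (1.0 + math.exp(-(v + 30.0) / 10.0))
    return xs_inf, tau


@njit(**_NJIT)
def kin_xs2(v):
    xs_inf, tau = kin_xs1(v)
    return xs_inf, 3.0 * tau


@njit(**_NJIT)
def kin_y(v):
    y_inf = 1.0 / (1.0 + math.exp((v + 78.65) / 6.33))
    tau = 1000.0 / (0.11885 * math.exp((v + 75.0) / 28.37)
                    + 0.56236 * math.exp(-(v + 75.0) / 14.19))
    return y_inf, tau


# ---------------------------------------------------------------------------
# membrane currents (pA/pF)
# ---------------------------------------------------------------------------

@njit(**_NJIT)
def cur_i_na(v, m, h, j, g_na, e_na):
    return g_na * m ** 3 * h * j * (v - e_na)


@njit(**_NJIT)
def cur_i_cal(v, d, f, fca, ca_i, ca_o, g_cal, temperature):
    """GHK driving force, Na+/K+ permeability ignored."""
    x = 2.0 * v / rtf(temperature)
    if abs(v) < 1e-6:
        drive = 0.5 * (ca_i - 0.341 * ca_o)
    else:
        ex = math.exp(x)
        drive = (v / rtf(temperature)) * (ca_i * ex - 0.341 * ca_o) / (ex - 1.0)
    return 4.0 * g_cal * d * f * fca * drive


@njit(**_NJIT)
def cur_i_cat(v, b, g, g_cat, e_ca):
    return g_cat * b * g * (v - e_ca + 106.5)


@njit(**_NJIT)
def cur_i_to(v, r, s, s_slow, g_to, e_k):
    return g_to * r * (0.706 * s + 0.294 * s_slow) * (v - e_k)


@njit(**_NJIT)
def cur_i_kur(v, ua, ui, g_kur, e_k):
    return g_kur * ua * ui * (v - e_k)


@njit(**_NJIT)
def cur_i_kr(v, xr, g_kr, e_k):
    r_inf = 1.0 / (1.0 + math.exp((v + 42.0) / 8.0))
    return g_kr * xr * r_inf * (v - e_k)


@njit(**_NJIT)
def cur_i_ks(v, xs1, xs2, g_ks, e_k):
    return g_ks * xs1 * xs2 * (v - e_k)


@njit(**_NJIT)
def cur_i_k1bar(v, k_o, g_k1, g_kleak, e_k):
    """Composite inward rectifier + linear K+ leak."""
    dv = v - e_k - 10.0
    rect = g_k1 * (k_o / (k_o + 210.0)) * dv / (1.0 + math.exp(0.041 * dv))
    return rect + g_kleak * (v - e_k)


@njit(**_NJIT)
def cur_i_kach(v, ach, g_scale, e_k):
    """Dose-dependent single-cell form."""
    if ach <= 0.0:
        return 0.0
    dose = 3.5 / (1.0 + 9.13652 / ach ** 0.477811)
    fac = 0.04 + 0.23 / (1.0 + math.exp((v + 102.0) / 10.0))
    return g_scale * dose * fac * (v - e_k - 10.0)


@njit(**_NJIT)
def cur_i_kach_c(v, g_scale, e_k):
    """Constitutively active tissue form (agonist independent)."""
    fac = 0.075 + 0.35 / (1.0 + math.exp((v + 102.0) / 10.0))
    return g_scale * 0.37488 * fac * (v - e_k - 10.0)


@njit(**_NJIT)
def cur_i_f(v, y, g_f, e_na, e_k):
    # Na+/K+ split with 0.2/0.8 weights
    return g_f * y * (0.2 * (v - e_na) + 0.8 * (v - e_k))


@njit(**_NJIT)
def cur_i_nak(v, i_nak_max, na_o, na_i, k_o, km_nai, km_ko, temperature):
    rt = rtf(temperature)
    sigma = (math.exp(na_o / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / rt)
                   + 0.0365 * sigma * math.exp(-v / rt))
    return (i_nak_max * f_nak * (k_o / (k_o + km_ko))
            / (1.0 + (km_nai / na_i) ** 1.5))


@njit(**_NJIT)
def cur_i_ncx(v, ca_i, k_ncx, d_ncx, gamma, na_o, na_i, ca_o, temperature):
    rt = rtf(temperature)
    num = (na_i ** 3 * ca_o * math.exp(gamma * v / rt)
           - na_o ** 3 * ca_i * math.exp((gamma - 1.0) * v / rt))
    den = 1.0 + d_ncx * (na_o ** 3 * ca_i + na_i ** 3 * ca_o)
    return k_ncx * num / den


@njit(**_NJIT)
def cur_i_nab(v, g_nab, e_na):
    return g_nab * (v - e_na)


@njit(**_NJIT)
def cur_i_cab(v, g_cab, e_ca):
    return g_cab * (v - e_ca)


# ---------------------------------------------------------------------------
# full right-hand side for one node
# ---------------------------------------------------------------------------

@njit(**_NJIT)
def eval_node(S, k, p, mult, block, mode, out):
    """Fill ``out`` (NOUT,) with currents/fluxes of node ``k``; returns I_ion."""
    v = S[S_V, k]
    ca_i = S[S_CA_I, k]
    ca_nsr = S[S_CA_NSR, k]
    ca_jsr = S[S_CA_JSR, k]
    temp = p[P_TEMPERATURE]

    e_na = nernst(1.0, p[P_NA_O], p[P_NA_I], temp)
    e_k = nernst(1.0, p[P_K_O], p[P_K_I], temp)
    e_ca = nernst(2.0, p[P_CA_O], max(ca_i, 1e-9), temp)

    i_na = cur_i_na(v, S[S_M, k], S[S_H, k], S[S_J, k],
                    p[P_G_NA] * mult[M_G_NA, k], e_na) * (1.0 - block[B_I_NA])
    i_cal = cur_i_cal(v, S[S_D, k], S[S_F, k], S[S_FCA, k], ca_i, p[P_CA_O],
                      p[P_G_CAL] * mult[M_G_CAL, k], temp) * (1.0 - block[B_I_CAL])
    i_cat = cur_i_cat(v, S[S_B, k], S[S_G, k],
                      p[P_G_CAT] * mult[M_G_CAT, k], e_ca) * (1.0 - block[B_I_CAT])
    i_to = cur_i_to(v, S[S_R, k], S[S_S, k], S[S_S_SLOW, k],
                    p[P_G_TO] * mult[M_G_TO, k], e_k) * (1.0 - block[B_I_TO])
    i_ksus = p[P_K_KSUS] * (
        cur_i_kur(v, S[S_UA, k], S[S_UI, k], p[P_G_KUR] * mult[M_G_KUR, k], e_k)
        + cur_i_kr(v, S[S_XR, k], p[P_G_KR] * mult[M_G_KR, k], e_k)
        + cur_i_ks(v, S[S_XS1, k], S[S_XS2, k], p[P_G_KS] * mult[M_G_KS, k], e_k)
    ) * (1.0 - block[B_I_KSUS])
    i_k1 = cur_i_k1bar(v, p[P_K_O], p[P_G_K1] * mult[M_G_K1, k],
                       p[P_G_KLEAK] * mult[M_G_KLEAK, k], e_k) * (1.0 - block[B_I_K1])
    if mode == MODE_SINGLE_CELL:
        i_kach = cur_i_kach(v, p[P_ACH], p[P_G_KACH] * mult[M_G_KACH, k], e_k)
    else:
        i_kach = cur_i_kach_c(v, p[P_G_KACH] * mult[M_G_KACH, k], e_k)
    i_kach *= (1.0 - block[B_I_KACH])
    i_f = cur_i_f(v, S[S_Y, k], p[P_G_F] * mult[M_G_F, k],
                  e_na, e_k) * (1.0 - block[B_I_F])
    i_nak = cur_i_nak(v, p[P_I_NAK_MAX] * mult[M_I_NAK_MAX, k], p[P_NA_O],
                      p[P_NA_I], p[P_K_O], p[P_KM_NAI], p[P_KM_KO],
                      temp) * (1.0 - block[B_I_NAK])
    i_ncx = cur_i_ncx(v, ca_i, p[P_K_NCX] * mult[M_K_NCX, k], p[P_D_NCX],
                      p[P_GAMMA_NCX], p[P_NA_O], p[P_NA_I], p[P_CA_O],
                      temp) * (1.0 - block[B_I_NCX])
    i_nab = cur_i_nab(v, p[P_G_NAB] * mult[M_G_NAB, k], e_na) * (1.0 - block[B_I_NAB])
    i_cab = cur_i_cab(v, p[P_G_CAB] * mult[M_G_CAB, k], e_ca) * (1.0 - block[B_I_CAB])

    i_total = (i_na + i_cal + i_k1 + i_to + i_cat + i_cab + i_ncx + i_nak
               + i_f + i_nab + i_ksus + i_kach)

    # --- SR / buffer fluxes -------------------------------------------------
    fr = (max(ca_i, 0.0) / p[P_KMF_UP]) ** p[P_H_UP]
    rv = (max(ca_nsr, 0.0) / p[P_KMR_UP]) ** p[P_H_UP]
    j_up = (p[P_VMAX_UP] * mult[M_VMAX_UP, k] * (fr - rv) / (1.0 + fr + rv))
    j_leak = p[P_K_LEAK_SR] * mult[M_K_LEAK_SR, k] * (ca_nsr - ca_i)
    j_tr = (ca_nsr - ca_jsr) / p[P_TAU_TR] * mult[M_J_TR, k]
    j_rel = (p[P_KS_REL] * mult[M_KS_REL, k] * S[S_RYR_O, k]
             * (ca_jsr - ca_i) * p[P_R_JSR])

    out[C_I_NA] = i_na
    out[C_I_CAL] = i_cal
    out[C_I_CAT] = i_cat
    out[C_I_TO] = i_to
    out[C_I_KSUS] = i_ksus
    out[C_I_K1] = i_k1
    out[C_I_KACH] = i_kach
    out[C_I_F] = i_f
    out[C_I_NAK] = i_nak
    out[C_I_NCX] = i_ncx
    out[C_I_NAB] = i_nab
    out[C_I_CAB] = i_cab
    out[C_J_UP] = j_up
    out[C_J_REL] = j_rel
    out[C_J_LEAK] = j_leak
    out[C_J_TR] = j_tr
    out[C_I_TOTAL] = i_total
    return i_total


@njit(**_NJIT)
def _advance_gate(x, x_inf, tau, dt, rush_larsen):
    if not tau > 1e-12:          # degenerate rates (blown-up voltage)
        x = x_inf
    elif rush_larsen:
        x = x_inf + (x - x_inf) * math.exp(-dt / tau)
    else:
        x = x + dt * (x_inf - x) / tau
    if x < 0.0:
        x = 0.0
    elif x > 1.0:
        x = 1.0
    return x


@njit(**_NJIT)
def step_node(S, k, p, mult, block, i_stim, dt, mode, rush_larsen, out):
    """Advance node ``k`` in place by dt; returns dV/dt before the update."""
    v = S[S_V, k]
    if not math.isfinite(v):     # already blown up; leave for the caller
        return 0.0
    i_ion = eval_node(S, k, p, mult, block, mode, out)
    dvdt = (-i_ion + i_stim) / p[P_CM]

    # --- HH gates ----------------------------------------------------------
    xi, tau = kin_m(v, p[P_K_TEMP_NA])
    S[S_M, k] = _advance_gate(S[S_M, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_h(v, p[P_K_TEMP_NA])
    S[S_H, k] = _advance_gate(S[S_H, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_j(v, p[P_K_TEMP_NA])
    S[S_J, k] = _advance_gate(S[S_J, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_d(v, p[P_TAU_D_SHIFT])
    S[S_D, k] = _advance_gate(S[S_D, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_f(v)
    S[S_F, k] = _advance_gate(S[S_F, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_fca(S[S_CA_I, k])
    S[S_FCA, k] = _advance_gate(S[S_FCA, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_b(v)
    S[S_B, k] = _advance_gate(S[S_B, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_g(v)
    S[S_G, k] = _advance_gate(S[S_G, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_r(v)
    S[S_R, k] = _advance_gate(S[S_R, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_s(v)
    S[S_S, k] = _advance_gate(S[S_S, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_s_slow(v)
    S[S_S_SLOW, k] = _advance_gate(S[S_S_SLOW, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_ua(v)
    S[S_UA, k] = _advance_gate(S[S_UA, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_ui(v)
    S[S_UI, k] = _advance_gate(S[S_UI, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_xr(v)
    S[S_XR, k] = _advance_gate(S[S_XR, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_xs1(v)
    S[S_XS1, k] = _advance_gate(S[S_XS1, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_xs2(v)
    S[S_XS2, k] = _advance_gate(S[S_XS2, k], xi, tau, dt, rush_larsen)
    xi, tau = kin_y(v)
    S[S_Y, k] = _advance_gate(S[S_Y, k], xi, tau, dt, rush_larsen)

    # --- RyR states (forward Euler, clamped to the simplex) ----------------
    ca_i = S[S_CA_I, k]
    ca_jsr = S[S_CA_JSR, k]
    trig = ca_i + p[P_K_LOCAL] * max(0.0, -(out[C_I_CAL] + out[C_I_CAT]))
    kcasr = (p[P_MAX_SR] - (p[P_MAX_SR] - p[P_MIN_SR])
             / (1.0 + (p[P_EC50_SR] / max(ca_jsr, 1e-6)) ** 2.5))
    ko_sr = p[P_KO_CA] / kcasr
    ki_sr = p[P_KI_CA] * kcasr
    rr = S[S_RYR_R, k]
    oo = S[S_RYR_O, k]
    ii = S[S_RYR_I, k]
    ri = 1.0 - rr - oo - ii
    f_ro = ko_sr * trig * trig * rr - p[P_KOM] * oo
    f_oi = ki_sr * trig * oo - p[P_KIM] * ii
    f_ir = p[P_KOM] * ii - ko_sr * trig * trig * ri
    f_rri = ki_sr * trig * rr - p[P_KIM] * ri
    rr += dt * (-f_ro - f_rri)
    oo += dt * (f_ro - f_oi)
    ii += dt * (f_oi - f_ir)
    S[S_RYR_R, k] = min(max(rr, 0.0), 1.0)
    S[S_RYR_O, k] = min(max(oo, 0.0), 1.0)
    S[S_RYR_I, k] = min(max(ii, 0.0), 1.0)

    # --- buffers (explicit mass-action ODEs; conservative under Euler) -----
    b_t = S[S_B_TRPN, k]
    b_c = S[S_B_CMDN, k]
    b_q = S[S_B_CSQN, k]
    j_trpn = (p[P_KON_TRPN] * ca_i * (p[P_TRPN_TOT] - b_t)
              - p[P_KON_TRPN] * p[P_KD_TRPN] * b_t)
    j_cmdn = (p[P_KON_CMDN] * ca_i * (p[P_CMDN_TOT] - b_c)
              - p[P_KON_CMDN] * p[P_KD_CMDN] * b_c)
    j_csqn = (p[P_KON_CSQN] * ca_jsr * (p[P_CSQN_TOT] - b_q)
              - p[P_KON_CSQN] * p[P_KD_CSQN] * b_q)

    # --- Ca compartments ---------------------------------------------------
    j_mem = -(out[C_I_CAL] + out[C_I_CAT] + out[C_I_CAB]
              - 2.0 * out[C_I_NCX]) * p[P_CA_CONV]
    d_cai = (j_mem - out[C_J_UP] + out[C_J_LEAK] + out[C_J_REL]
             - j_trpn - j_cmdn)
    d_nsr = ((out[C_J_UP] - out[C_J_LEAK]) / p[P_R_NSR]
             - out[C_J_TR] * p[P_R_JSR] / p[P_R_NSR])
    d_jsr = out[C_J_TR] - out[C_J_REL] / p[P_R_JSR] - j_csqn

    S[S_CA_I, k] = max(ca_i + dt * d_cai, 0.0)
    S[S_CA_NSR, k] = max(S[S_CA_NSR, k] + dt * d_nsr, 0.0)
    S[S_CA_JSR, k] = max(ca_jsr + dt * d_jsr, 0.0)
    S[S_B_TRPN, k] = min(max(b_t + dt * j_trpn, 0.0), p[P_TRPN_TOT])
    S[S_B_CMDN, k] = min(max(b_c + dt * j_cmdn, 0.0), p[P_CMDN_TOT])
    S[S_B_CSQN, k] = min(max(b_q + dt * j_csqn, 0.0), p[P_CSQN_TOT])

    # --- membrane potential ------------------------------------------------
    S[S_V, k] = v + dt * dvdt
    return dvdt


# ---------------------------------------------------------------------------
# single-cell driver
# ---------------------------------------------------------------------------

@njit(**_NJIT)
def run_cell(S, p, block, mode, rush_larsen, dt, n_steps,
             stim_amp, stim_t0, stim_period, stim_count, stim_dur,
             i_hold, rec):
    """Advance one cell ``n_steps``; record V/Ca/dVdt every step.

    ``rec`` is a (4, n_steps + 1) array receiving V, Ca_i, Ca_NSR+JSR rows:
    rows are (V, Ca_i, Ca_NSR, Ca_JSR); returns the per-step dV/dt array.
    A periodic rectangular stimulus train is applied: ``stim_count`` pulses
    of ``stim_amp`` (pA/pF) lasting ``stim_dur`` ms every ``stim_period`` ms
    starting at ``stim_t0``; ``i_hold`` adds a constant bias current.
    """
    mult = np.ones((19, 1))
    out = np.empty(NOUT)
    dvdt = np.empty(n_steps)
    rec[0, 0] = S[S_V, 0]
    rec[1, 0] = S[S_CA_I, 0]
    rec[2, 0] = S[S_CA_NSR, 0]
    rec[3, 0] = S[S_CA_JSR, 0]
    for it in range(n_steps):
        t = it * dt
        i_stim = i_hold
        if stim_count > 0 and t >= stim_t0:
            phase = (t - stim_t0) % stim_period
            pulse = (t - stim_t0) // stim_period
            if pulse < stim_count and phase < stim_dur:
                i_stim += stim_amp
        dvdt[it] = step_node(S, 0, p, mult, block, i_stim, dt, mode,
                             rush_larsen, out)
        rec[0, it + 1] = S[S_V, 0]
        rec[1, it + 1] = S[S_CA_I, 0]
        rec[2, it + 1] = S[S_CA_NSR, 0]
        rec[3, it + 1] = S[S_CA_JSR, 0]
        if not math.isfinite(S[S_V, 0]):
            break
    return dvdt


# ---------------------------------------------------------------------------
# tissue driver
# ---------------------------------------------------------------------------

@njit(**_NJIT)
def tissue_advance(S, p, mult, block, mode, rush_larsen, dt, n_steps,
                   diff_coef, dx, nb,
                   stim_idx, stim_amp,
                   v_fb, fb_ptr, fb_nbr, g_gap, g_fb, e_fb,
                   probe_idx, probe_out, probe_col):
    """Advance N coupled myocyte nodes (plus passive fibroblasts) n_steps.

    ``nb`` is a (4, N) neighbour-index array (self-index encodes a no-flux
    mirror).  ``stim_idx`` nodes receive a constant ``stim_amp`` (pA/pF) for
    the whole call; protocol timing is composed by the caller from short
    calls.  Fibroblast ``i`` couples to myocyte nodes
    ``fb_nbr[fb_ptr[i]:fb_ptr[i+1]]`` sharing ``g_gap`` equally.
    Probe voltages are written every step into ``probe_out`` starting at
    column ``probe_col``.  Returns the first non-finite node index or -1.
    """
    n = S.shape[1]
    nf = v_fb.shape[0]
    out = np.empty(NOUT)
    lap = np.empty(n)
    i_gap_m = np.zeros(n)
    inv_dx2 = 1.0 / (dx * dx)
    for it in range(n_steps):
        # diffusion on the pre-step voltage field
        for k in range(n):
            vk = S[S_V, k]
            lap[k] = ((S[S_V, nb[0, k]] + S[S_V, nb[1, k]]
                       + S[S_V, nb[2, k]] + S[S_V, nb[3, k]] - 4.0 * vk)
                      * inv_dx2)
        # fibroblast coupling
        if nf > 0:
            for k in range(n):
                i_gap_m[k] = 0.0
            for i in range(nf):
                lo = fb_ptr[i]
                hi = fb_ptr[i + 1]
                nn = hi - lo
                if nn == 0:
                    v_fb[i] = v_fb[i] + dt * (-g_fb * (v_fb[i] - e_fb))
                    continue
                g_pair = g_gap / nn
                i_in = 0.0
                for q in range(lo, hi):
                    mth = fb_nbr[q]
                    ig = g_pair * (S[S_V, mth] - v_fb[i])
                    i_gap_m[mth] += ig
                    i_in += ig
                v_fb[i] = v_fb[i] + dt * (i_in - g_fb * (v_fb[i] - e_fb))
        # ionic step + diffusion + coupling
        for k in range(n):
            v_old = S[S_V, k]
            step_node(S, k, p, mult, block, 0.0, dt, mode, rush_larsen, out)
            dv_extra = diff_coef * lap[k]
            if nf > 0:
                dv_extra -= i_gap_m[k] / p[P_CM]
            S[S_V, k] += dt * dv_extra
        for q in range(stim_idx.shape[0]):
            S[S_V, stim_idx[q]] += dt * stim_amp / p[P_CM]
        for q in range(probe_idx.shape[0]):
            probe_out[q, probe_col + it] = S[S_V, probe_idx[q]]
        # blow-up guard (check one representative node per step is too weak;
        # scan every 50 steps)
        if it % 50 == 49:
            for k in range(n):
                if not math.isfinite(S[S_V, k]):
                    return k
    for k in range(n):
        if not math.isfinite(S[S_V, k]):
            return k
    return -1
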