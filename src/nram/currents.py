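"""Individual membrane currents as plain functions of (V, gates, params).

These wrap the same compiled scalars the integrator uses, broadcasting over
NumPy arrays.  All currents are densities in pA/pF; outward is positive.
"""

from __future__ import annotations

import numpy as np

from . import _model
from .params import CellParams


def nernst_potential(z: int, x_o, x_i, temperature: float = 295.0):
    """Nernst equilibrium potential in mV.

    Raises ``ValueError`` for non-positive concentrations.
    """
    x_o = np.asarray(x_o, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    if np.any(x_o <= 0) or np.any(x_i <= 0):
        raise ValueError("concentrations must be positive")
    rt = 1000.0 * _model.GAS_R * temperature / _model.FARADAY
    out = rt / z * np.log(x_o / x_i)
    return float(out) if out.ndim == 0 else out


def reversal_potentials(params: CellParams, ca_i: float):
    """(E_Na, E_K, E_Ca) for the given milieu and cytosolic Ca."""
    t = params.temperature
    return (nernst_potential(1, params.na_o, params.na_i, t),
            nernst_potential(1, params.k_o, params.k_i, t),
            nernst_potential(2, params.ca_o, ca_i, t))


def _vec(fn, *args):
    args = [np.asarray(a, dtype=float) for a in args]
    bc = np.broadcast(*args)
    out = np.empty(bc.shape)
    flat = out.reshape(-1)
    for i, vals in enumerate(np.broadcast(*args)):
        flat[i] = fn(*map(float, vals))
    if out.ndim == 0:
        return float(out)
    return out


def i_na(v, m, h, j, params: CellParams):
    e_na = nernst_potential(1, params.na_o, params.na_i, params.temperature)
    return _vec(lambda vv, mm, hh, jj: _model.cur_i_na(
        vv, mm, hh, jj, params.g_na, e_na), v, m, h, j)


def i_cal(v, d, f, fca, ca_i, params: CellParams):
    if np.any(np.asarray(ca_i) <= 0):
        raise ValueError("ca_i must be positive")
    return _vec(lambda vv, dd, ff, fc, ca: _model.cur_i_cal(
        vv, dd, ff, fc, ca, params.ca_o, params.g_cal, params.temperature),
        v, d, f, fca, ca_i)


def i_cat(v, b, g, ca_i, params: CellParams):
    e_ca = nernst_potential(2, params.ca_o, ca_i, params.temperature)
    return _vec(lambda vv, bb, gg: _model.cur_i_cat(
        vv, bb, gg, params.g_cat, e_ca), v, b, g)


def i_to(v, r, s, s_slow, params: CellParams):
    e_k = nernst_potential(1, params.k_o, params.k_i, params.temperature)
    return _vec(lambda vv, rr, ss, sl: _model.cur_i_to(
        vv, rr, ss, sl, params.g_to, e_k), v, r, s, s_slow)


def i_ksus(v, ua, ui, xr, xs1, xs2, params: CellParams):
    """0.16 x (I_Kur + I_Kr + I_Ks)."""
    e_k = nernst_potential(1, params.k_o, params.k_i, params.temperature)
    return _vec(lambda vv, a, b, c, d, e: params.k_ksus * (
        _model.cur_i_kur(vv, a, b, params.g_kur, e_k)
        + _model.cur_i_kr(vv, c, params.g_kr, e_k)
        + _model.cur_i_ks(vv, d, e, params.g_ks, e_k)),
        v, ua, ui, xr, xs1, xs2)


def i_k1bar(v, params: CellParams):
    """Composite inward rectifier with K+ leak (reversal shifted +10 mV)."""
    e_k = nernst_potential(1, params.k_o, params.k_i, params.temperature)
    return _vec(lambda vv: _model.cur_i_k1bar(
        vv, params.k_o, params.g_k1, params.g_kleak, e_k), v)


def i_kach(v, ach, params: CellParams):
    """Single-cell, dose-dependent acetylcholine-activated K+ current."""
    e_k = nernst_potential(1, params.k_o, params.k_i, params.temperature)
    return _vec(lambda vv, aa: _model.cur_i_kach(
        vv, aa, params.g_kach, e_k), v, ach)


def i_kach_c(v, params: CellParams):
    """Constitutively active (agonist-independent) tissue form."""
    e_k = nernst_potential(1, params.k_o, params.k_i, params.temperature)
    return _vec(lambda vv: _model.cur_i_kach_c(vv, params.g_kach, e_k), v)


def i_f(v, y, params: CellParams):
    e_na = nernst_potential(1, params.na_o, params.na_i, params.temperature)
    e_k = nernst_potential(1, params.k_o, params.k_i, params.temperature)
    return _vec(lambda vv, yy: _model.cur_i_f(
        vv, yy, params.g_f, e_na, e_k), v, y)


def pumps_and_backgrounds(v, ca_i, params: CellParams):
    """(I_NaK, I_NCX, I_Nab, I_Cab) in pA/pF."""
    e_na = nernst_potential(1, params.na_o, params.na_i, params.temperature)
    e_ca = nernst_potential(2, params.ca_o, ca_i, params.temperature)
    inak = _vec(lambda vv: _model.cur_i_nak(
        vv, params.i_nak_max, params.na_o, params.na_i, params.k_o,
        params.km_nai, params.km_ko, params.temperature), v)
    incx = _vec(lambda vv, cc: _model.cur_i_ncx(
        vv, cc, params.k_ncx, params.d_ncx, params.gamma_ncx,
        params.na_o, params.na_i, params.ca_o, params.temperature), v, ca_i)
    inab = _vec(lambda vv: _model.cur_i_nab(vv, params.g_nab, e_na), v)
    icab = _vec(lambda vv: _model.cur_i_cab(vv, params.g_cab, e_ca), v)
    return inak, incx, inab, icab
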