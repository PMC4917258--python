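"""Steady-state activation/inactivation curves and time constants.

Thin NumPy wrappers around the compiled scalar kinetics, for inspection,
plotting and testing.  ``gate_kinetics`` dispatches on gate id; each entry
returns ``(x_inf, tau_ms)``.
"""

from __future__ import annotations

import numpy as np

from . import _model
from .params import CellParams

_VOLTAGE_GATES = {
    "m": lambda v, p: _model.kin_m(v, p.k_temp_na),
    "h": lambda v, p: _model.kin_h(v, p.k_temp_na),
    "j": lambda v, p: _model.kin_j(v, p.k_temp_na),
    "d": lambda v, p: _model.kin_d(v, p.tau_d_shift),
    "f": lambda v, p: _model.kin_f(v),
    "b": lambda v, p: _model.kin_b(v),
    "g": lambda v, p: _model.kin_g(v),
    "r": lambda v, p: _model.kin_r(v),
    "s": lambda v, p: _model.kin_s(v),
    "s_slow": lambda v, p: _model.kin_s_slow(v),
    "ua": lambda v, p: _model.kin_ua(v),
    "ui": lambda v, p: _model.kin_ui(v),
    "xr": lambda v, p: _model.kin_xr(v),
    "xs1": lambda v, p: _model.kin_xs1(v),
    "xs2": lambda v, p: _model.kin_xs2(v),
    "y": lambda v, p: _model.kin_y(v),
}

#: activation gates have x_inf increasing in V, inactivation gates decreasing
ACTIVATION_GATES = frozenset(
    {"m", "d", "b", "r", "ua", "xr", "xs1", "xs2"})
INACTIVATION_GATES = frozenset(
    {"h", "j", "f", "g", "s", "s_slow", "ui", "y"})
GATE_IDS = tuple(_VOLTAGE_GATES)


def gate_kinetics(gate_id: str, v, params: CellParams | None = None):
    """Return ``(x_inf, tau_x)`` for a voltage-dependent gate.

    Parameters
    ----------
    gate_id:
        One of :data:`GATE_IDS` (``fca`` is Ca-dependent; see
        :func:`fca_kinetics`).
    v:
        Membrane potential in mV, scalar or array.
    """
    if gate_id not in _VOLTAGE_GATES:
        raise KeyError(f"unknown gate id {gate_id!r}")
    params = params or CellParams()
    fn = _VOLTAGE_GATES[gate_id]
    v_arr = np.asarray(v, dtype=float)
    inf = np.empty(v_arr.shape)
    tau = np.empty(v_arr.shape)
    it = np.nditer(v_arr, flags=["multi_index"])
    for val in it:
        inf[it.multi_index], tau[it.multi_index] = fn(float(val), params)
    if np.isscalar(v) or np.ndim(v) == 0:
        return float(inf), float(tau)
    return inf, tau


def fca_kinetics(ca_i):
    """Ca-dependent inactivation of the L-type current: ``(fca_inf, tau)``."""
    ca_arr = np.atleast_1d(np.asarray(ca_i, dtype=float))
    out = np.array([_model.kin_fca(c) for c in ca_arr])
    inf, tau = out[:, 0], out[:, 1]
    if np.isscalar(ca_i) or np.ndim(ca_i) == 0:
        return float(inf[0]), float(tau[0])
    return inf, tau
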