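"""Single-cell state, current evaluation, and time stepping.

The cell state is a flat float64 vector ordered as
``constants.STATE_FIELDS`` with named attribute access.  The same layout,
stacked over nodes, is what the tissue solver integrates.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

from . import _model
from .constants import (
    CURRENT_FIELDS, GATE_SLICE, MODE_CONSTITUTIVE, MODE_SINGLE_CELL, NOUT,
    NVAR, STATE_FIELDS,
)
from .params import CellParams

MODES = {"single_cell": MODE_SINGLE_CELL, "constitutive": MODE_CONSTITUTIVE}


class IntegrationBlowupError(RuntimeError):
    """Raised when the forward-Euler step produces a non-finite variable."""


@dataclasses.dataclass
class CellState:
    """State vector of one myocyte (voltage, gates, Ca subsystem)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (NVAR,):
            raise ValueError(f"state must have shape ({NVAR},)")

    def __getattr__(self, name):
        if name in STATE_FIELDS:
            return float(self.values[STATE_FIELDS.index(name)])
        raise AttributeError(name)

    def copy(self) -> "CellState":
        return CellState(self.values.copy())

    @property
    def gates(self) -> np.ndarray:
        return self.values[GATE_SLICE]

    def check_finite(self) -> None:
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            names = ", ".join(STATE_FIELDS[i] for i in bad)
            raise IntegrationBlowupError(
                f"non-finite state variable(s): {names}")


@dataclasses.dataclass
class CurrentSet:
    """All membrane currents (pA/pF) and Ca fluxes (mM/ms) at one instant."""

    values: np.ndarray

    def __getattr__(self, name):
        if name in CURRENT_FIELDS:
            return float(self.values[CURRENT_FIELDS.index(name)])
        raise AttributeError(name)

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in zip(CURRENT_FIELDS, self.values)}


def _mode_id(mode) -> int:
    if isinstance(mode, str):
        try:
            return MODES[mode]
        except KeyError:
            raise ValueError(
                f"mode must be one of {sorted(MODES)}") from None
    return int(mode)


def initial_state(params: CellParams | None = None,
                  v: float = -72.0) -> CellState:
    """A heuristic pre-equilibration state: gates at x_inf(v), Ca primed."""
    from .kinetics import gate_kinetics, fca_kinetics, GATE_IDS

    params = params or CellParams()
    vec = np.zeros(NVAR)
    vec[STATE_FIELDS.index("v")] = v
    ca_i, ca_sr = 2.0e-4, 0.78
    for gid in GATE_IDS:
        inf, _ = gate_kinetics(gid, v, params)
        vec[STATE_FIELDS.index(gid)] = inf
    vec[STATE_FIELDS.index("fca")] = fca_kinetics(ca_i)[0]
    vec[STATE_FIELDS.index("ca_i")] = ca_i
    vec[STATE_FIELDS.index("ca_nsr")] = ca_sr
    vec[STATE_FIELDS.index("ca_jsr")] = ca_sr
    vec[STATE_FIELDS.index("ryr_r")] = 1.0
    vec[STATE_FIELDS.index("b_trpn")] = (
        params.trpn_tot * ca_i / (params.kd_trpn + ca_i))
    vec[STATE_FIELDS.index("b_cmdn")] = (
        params.cmdn_tot * ca_i / (params.kd_cmdn + ca_i))
    vec[STATE_FIELDS.index("b_csqn")] = (
        params.csqn_tot * ca_sr / (params.kd_csqn + ca_sr))
    return CellState(vec)


@functools.lru_cache(maxsize=16)
def _resting_vector(param_bytes: bytes, block_bytes: bytes, mode: int,
                    t_max: float, dt: float) -> bytes:
    p = np.frombuffer(param_bytes).copy()
    block = np.frombuffer(block_bytes).copy()
    params = CellParams()  # only used for the heuristic start
    S = initial_state().values.reshape(NVAR, 1).copy()
    n_steps = int(round(t_max / dt))
    rec = np.empty((4, n_steps + 1))
    _model.run_cell(S, p, block, mode, True, dt, n_steps,
                    0.0, 0.0, 1.0, 0, 0.0, 0.0, rec)
    return S[:, 0].tobytes()


def resting_state(params: CellParams | None = None, mode="single_cell",
                  t_max: float = 20000.0, dt: float = 0.02) -> CellState:
    """Integrate without stimulus until quiescent; returns the rest state.

    The unstimulated model is non-automatic and converges to a stable
    resting point near -72 mV; ``t_max`` (ms) bounds the settling run.
    """
    params = params or CellParams()
    vec = _resting_vector(params.to_vector().tobytes(),
                          params.block_vector().tobytes(),
                          _mode_id(mode), float(t_max), float(dt))
    state = CellState(np.frombuffer(vec).copy())
    state.check_finite()
    return state


def total_current(state: CellState, params: CellParams,
                  mode="single_cell") -> CurrentSet:
    """Evaluate every membrane current and Ca flux at the given state."""
    S = state.values.reshape(NVAR, 1).copy()
    out = np.empty(NOUT)
    mult = np.ones((19, 1))
    _model.eval_node(S, 0, params.to_vector(), mult,
                     params.block_vector(), _mode_id(mode), out)
    return CurrentSet(out)


def calcium_fluxes(state: CellState, params: CellParams) -> dict:
    """SR fluxes (J_up, J_rel, J_leak in cytosolic mM/ms; J_tr in JSR mM/ms)."""
    if (state.ca_i < 0 or state.ca_nsr < 0 or state.ca_jsr < 0):
        raise ValueError("negative Ca concentration")
    cs = total_current(state, params)
    return {k: getattr(cs, k) for k in ("j_up", "j_rel", "j_leak", "j_tr")}


def total_cell_calcium(state: CellState, params: CellParams) -> float:
    """Total Ca content in cytosolic-volume mM (free + buffered + SR)."""
    return (state.ca_i + state.b_trpn + state.b_cmdn
            + params.r_nsr * state.ca_nsr
            + params.r_jsr * (state.ca_jsr + state.b_csqn))


def step_cell(state: CellState, dt: float, i_stim: float,
              params: CellParams, mode="single_cell",
              rush_larsen: bool = True) -> CellState:
    """Advance the cell one forward-Euler step (gates per ``rush_larsen``)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    S = state.values.reshape(NVAR, 1).copy()
    out = np.empty(NOUT)
    mult = np.ones((19, 1))
    _model.step_node(S, 0, params.to_vector(), mult, params.block_vector(),
                     i_stim, dt, _mode_id(mode), rush_larsen, out)
    new = CellState(S[:, 0])
    new.check_finite()
    return new
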