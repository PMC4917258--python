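"""Single-cell stimulation protocols and action-potential metrics.

Conventions: stimulus amplitudes are current densities (pA/pF, positive =
depolarizing); printed whole-cell picoampere values convert through
``CellParams.c_cell``.  APD is measured from the instant of maximum
upstroke velocity to the crossing of ``peak - x% * amplitude`` on the
downstroke, with the amplitude referenced to the beat's own pre-stimulus
potential, which makes the duration independent of the stimulus shape.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _model
from .cell import (
    CellState, MODES, initial_state, resting_state, total_current,
)
from .constants import MODE_CONSTITUTIVE, MODE_SINGLE_CELL, NVAR
from .params import CellParams
from .recording import Recording

#: default single-cell stimulus: 7 pA (density units via c_cell) for 5 ms
STIM_AMPLITUDE = 7.0
STIM_DURATION = 5.0

#: saturating agonist dose (uM) used for the carbachol intervention
CARBACHOL_SATURATING_ACH = 1.0e4


def resolve_mode(params: CellParams, mode):
    """Map a protocol-level mode name to (params, kernel mode id).

    ``single_cell``: dose-dependent law at the params' ACh level.
    ``carbachol``: dose-dependent law at a saturating agonist dose.
    ``constitutive`` (alias ``control``): agonist-independent tissue form.
    ``blocked`` (alias ``tertiapin``): tissue form fully blocked.
    """
    if not isinstance(mode, str):
        return params, int(mode)
    name = mode.lower()
    if name in MODES:
        return params, MODES[name]
    if name == "carbachol":
        return params.replace(ach=CARBACHOL_SATURATING_ACH), MODE_SINGLE_CELL
    if name == "control":
        return params, MODE_CONSTITUTIVE
    if name in ("blocked", "tertiapin"):
        return params.with_block("i_kach", 1.0), MODE_CONSTITUTIVE
    raise ValueError(f"unknown mode {mode!r}")


def _run(state: CellState, params: CellParams, mode_id: int, dt: float,
         n_steps: int, stim_amp: float, stim_t0: float, stim_period: float,
         stim_count: int, stim_dur: float, i_hold: float = 0.0,
         rush_larsen: bool = True):
    S = state.values.reshape(NVAR, 1).copy()
    rec = np.empty((4, n_steps + 1))
    dvdt = _model.run_cell(S, params.to_vector(), params.block_vector(),
                           mode_id, rush_larsen, dt, n_steps,
                           stim_amp, stim_t0, stim_period, stim_count,
                           stim_dur, i_hold, rec)
    new_state = CellState(S[:, 0])
    new_state.check_finite()
    t = np.arange(n_steps + 1) * dt
    recording = Recording(t=t, v=rec[0], ca_i=rec[1], ca_nsr=rec[2],
                          ca_jsr=rec[3])
    return recording, new_state, dvdt


def pace_to_steady_state(params: CellParams | None = None,
                         bcl: float = 1000.0, n_beats: int = 15,
                         stim_amplitude: float = STIM_AMPLITUDE,
                         stim_duration: float = STIM_DURATION,
                         mode="single_cell", dt: float = 0.02,
                         start: CellState | None = None,
                         i_hold: float = 0.0,
                         rush_larsen: bool = True) -> Recording:
    """Pace one cell at a fixed cycle length from rest.

    Returns a full V/Ca recording with ``stim_times`` and, in ``meta``:
    per-beat APD80 values, capture flags, and whether consecutive-beat
    APD80 settled below 1 ms (``steady``).  Loss of 1:1 capture is reported
    in the flags, not raised.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    params = params or CellParams()
    run_params, mode_id = resolve_mode(params, mode)
    amp_density = stim_amplitude / run_params.c_cell
    if start is None:
        start = resting_state(run_params, mode_id)
    n_steps = int(round(bcl * n_beats / dt))
    rec, state, dvdt = _run(start, run_params, mode_id, dt, n_steps,
                            amp_density, 0.0, bcl, n_beats, stim_duration,
                            i_hold=i_hold, rush_larsen=rush_larsen)
    rec.stim_times = np.arange(n_beats) * bcl
    apds, captured = [], []
    for ib in range(n_beats):
        beat = rec.window(ib * bcl, (ib + 1) * bcl)
        try:
            metrics = ap_metrics(beat, stim_time=ib * bcl)
            ok = metrics.amplitude > 40.0
            apds.append(metrics.apd80 if ok else np.nan)
        except ValueError:
            ok = False
            apds.append(np.nan)
        captured.append(ok)
    apds = np.asarray(apds)
    steady = (len(apds) >= 2 and np.isfinite(apds[-2:]).all()
              and abs(apds[-1] - apds[-2]) < 1.0)
    rec.meta.update(bcl=bcl, mode=mode, apd80_per_beat=apds,
                    captured=np.asarray(captured), steady=bool(steady),
                    final_state=state, dvdt=dvdt)
    return rec


@dataclasses.dataclass
class APMetrics:
    """Scalar characteristics of a single action potential."""

    rmp: float          # pre-stimulus membrane potential, mV
    amplitude: float    # peak minus RMP, mV
    dvdt_max: float     # maximum upstroke velocity, mV/ms
    apd50: float        # ms from dV/dt_max instant to 50% repolarization
    apd80: float        # ms, same reference, 80% repolarization
    takeoff: float      # mV at which the upstroke accelerates

    def __post_init__(self):
        if self.apd50 > self.apd80 + 1e-9:
            raise ValueError("APD50 must not exceed APD80")


def _crossing_time(t, v, level, start_idx):
    """First downward crossing of ``level`` at or after ``start_idx``."""
    below = v[start_idx:] <= level
    if not below.any():
        return None
    i = start_idx + int(np.argmax(below))
    if i == 0 or v[i - 1] <= level:
        return float(t[i])
    frac = (v[i - 1] - level) / (v[i - 1] - v[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def ap_metrics(trace: Recording, stim_time: float | None = None) -> APMetrics:
    """Measure one action potential in ``trace``.

    Raises ``ValueError`` when no upstroke (dV/dt > 1 mV/ms with at least
    10 mV of excursion) is present.
    """
    t, v = np.asarray(trace.t, float), np.asarray(trace.v, float)
    if t.size < 3:
        raise ValueError("trace too short")
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    if dvdt[i_up] <= 1.0 or v.max() - v.min() < 10.0:
        raise ValueError("no upstroke found")
    if stim_time is None and trace.stim_times is not None \
            and len(trace.stim_times):
        stim_time = float(trace.stim_times[0])
    if stim_time is not None and stim_time > t[0]:
        rmp = float(v[np.searchsorted(t, stim_time) - 1])
    else:
        rmp = float(v[: max(i_up, 1)].min())
    i_peak = i_up + int(np.argmax(v[i_up:]))
    peak = float(v[i_peak])
    amplitude = peak - rmp
    # take-off: first sample of the upstroke where dV/dt exceeds 10% of max
    i0 = i_up
    while i0 > 0 and dvdt[i0 - 1] > 0.1 * dvdt[i_up]:
        i0 -= 1
    takeoff = float(v[i0])
    t_ref = float(t[i_up])
    apds = {}
    for pct in (50, 80):
        level = peak - pct / 100.0 * amplitude
        tc = _crossing_time(t, v, level, i_peak)
        if tc is None:
            raise ValueError(f"repolarization to {pct}% not reached")
        apds[pct] = tc - t_ref
    return APMetrics(rmp=rmp, amplitude=amplitude,
                     dvdt_max=float(dvdt[i_up]), apd50=apds[50],
                     apd80=apds[80], takeoff=takeoff)


@dataclasses.dataclass
class RestitutionTable:
    """APD80 restitution from a dynamic (descending-BCL) protocol."""

    bcl: np.ndarray
    apd80: np.ndarray
    captured: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"bcl_ms": self.bcl, "apd80_ms": self.apd80,
                             "captured": self.captured})


def dynamic_restitution(params: CellParams | None = None,
                        bcl_list=None, beats_per_bcl: int = 20,
                        mode="constitutive",
                        stim_amplitude: float = STIM_AMPLITUDE,
                        stim_duration: float = STIM_DURATION,
                        dt: float = 0.02) -> RestitutionTable:
    """Dynamic restitution: pace down a descending BCL staircase.

    The state carries over between BCL steps (dynamic protocol); the
    last-beat APD80 is reported per BCL, with capture flagged from the
    presence of one upstroke per stimulus over the final five stimuli.
    """
    params = params or CellParams()
    if bcl_list is None:
        bcl_list = [1000, 800, 600, 500, 400, 300, 250, 200, 150,
                    125, 100, 80, 60]
    bcl_list = list(map(float, bcl_list))
    if any(b2 >= b1 for b1, b2 in zip(bcl_list, bcl_list[1:])):
        raise ValueError("bcl_list must be strictly descending")
    run_params, mode_id = resolve_mode(params, mode)
    amp = stim_amplitude / run_params.c_cell
    state = resting_state(run_params, mode_id)
    rows = []
    for bcl in bcl_list:
        n_steps = int(round(bcl * beats_per_bcl / dt))
        rec, state, _ = _run(state, run_params, mode_id, dt, n_steps,
                             amp, 0.0, bcl, beats_per_bcl, stim_duration)
        # capture over the last five stimuli
        n_check = min(5, beats_per_bcl)
        caught = []
        for ib in range(beats_per_bcl - n_check, beats_per_bcl):
            seg = rec.window(ib * bcl, (ib + 1) * bcl)
            caught.append(bool(seg.v.max() > -20.0))
        captured = all(caught)
        apd = np.nan
        if captured:
            beat = rec.window((beats_per_bcl - 1) * bcl,
                              beats_per_bcl * bcl)
            try:
                apd = ap_metrics(beat, stim_time=(beats_per_bcl - 1)
                                 * bcl).apd80
            except ValueError:
                captured = False
        rows.append((bcl, apd, captured))
    arr = np.array([(b, a) for b, a, _ in rows])
    return RestitutionTable(bcl=arr[:, 0], apd80=arr[:, 1],
                            captured=np.array([c for _, _, c in rows]))


def holding_current_for(params: CellParams | None = None,
                        v_target: float = -85.0,
                        mode="single_cell") -> float:
    """Constant bias current (pA/pF) making ``v_target`` a steady state.

    The returned value is the total ionic current at ``v_target`` with all
    gates at their steady states there (the root of dV/dt = 0); negative
    values are hyperpolarizing.
    """
    if not -120.0 <= v_target <= -40.0:
        raise ValueError("v_target must lie in [-120, -40] mV")
    params = params or CellParams()
    run_params, mode_id = resolve_mode(params, mode)
    rest = resting_state(run_params, mode_id)
    state = initial_state(run_params, v=v_target)
    # keep the relaxed Ca subsystem from the true rest state
    for name in ("ca_i", "ca_nsr", "ca_jsr", "ryr_r", "ryr_o", "ryr_i",
                 "b_trpn", "b_cmdn", "b_csqn"):
        from .constants import STATE_FIELDS
        idx = STATE_FIELDS.index(name)
        state.values[idx] = rest.values[idx]
    return total_current(state, run_params, mode_id).i_total
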