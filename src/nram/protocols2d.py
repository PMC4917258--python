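"""Tissue-level experiments: planar pacing, S1-S2 cross-field spiral
initiation, burst pacing, channel-block interventions, capture scanning.

Stimulus amplitudes follow the same density convention as the single-cell
protocols (printed pA values divided by ``CellParams.c_cell``); the S1/S2
standard is 100 pA for 2 ms.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .monolayer import TissueGrid
from .params import CellParams
from .recording import FrameStack
from .tissue import (
    DT_DEFAULT, ProtocolSpec, TissueState, _Solver, init_tissue_state,
    run_simulation,
)

S1_AMPLITUDE = 100.0   # pA (density via c_cell)
S1_DURATION = 2.0      # ms

#: threshold used both for activity detection and 1:1 capture
ACTIVITY_LEVEL = -20.0

#: repolarization level defining the waveback
WAVEBACK_LEVEL = -60.0

#: no crossing of ACTIVITY_LEVEL for this long = activity terminated
QUIESCENCE_WINDOW = 500.0  # ms


def edge_nodes(grid: TissueGrid, edge: str = "left",
               width: int = 5) -> np.ndarray:
    """Flat myocyte indices of a ``width``-node line along a domain edge."""
    rows, cols = grid.myocyte_coords()
    if edge == "left":
        lo = cols.min()
        sel = cols < lo + width
    elif edge == "right":
        hi = cols.max()
        sel = cols > hi - width
    elif edge == "top":
        lo = rows.min()
        sel = rows < lo + width
    elif edge == "bottom":
        hi = rows.max()
        sel = rows > hi - width
    else:
        raise ValueError(f"unknown edge {edge!r}")
    return np.flatnonzero(sel)


def region_nodes(grid: TissueGrid, row_range=None, col_range=None):
    """Flat myocyte indices inside [row_range) x [col_range)."""
    rows, cols = grid.myocyte_coords()
    sel = np.ones(rows.size, dtype=bool)
    if row_range is not None:
        sel &= (rows >= row_range[0]) & (rows < row_range[1])
    if col_range is not None:
        sel &= (cols >= col_range[0]) & (cols < col_range[1])
    return np.flatnonzero(sel)


def _amp(params: CellParams, amplitude_pa: float) -> float:
    return amplitude_pa / params.c_cell


def planar_pacing(grid: TissueGrid, cl: float, n_beats: int,
                  params: CellParams | None = None, mode="constitutive",
                  edge: str = "left", amplitude: float = S1_AMPLITUDE,
                  duration: float = S1_DURATION, extra_time: float = 0.0,
                  frame_stride: float = 1.0, probe_nodes=None,
                  state: TissueState | None = None, dt: float = DT_DEFAULT):
    """Line-stimulus pacing train along a domain edge.

    Returns ``(FrameStack, probe recordings, final state, captured)``
    where ``captured`` flags one far-field activation per stimulus.
    """
    params = params or CellParams()
    stim = edge_nodes(grid, edge)
    if probe_nodes is None:
        opposite = {"left": "right", "right": "left",
                    "top": "bottom", "bottom": "top"}[edge]
        far = edge_nodes(grid, opposite, width=1)
        probe_nodes = [int(far[far.size // 2])]
    proto = ProtocolSpec().stimulus(0.0, stim, _amp(params, amplitude),
                                    duration, count=n_beats, period=cl)
    total = cl * n_beats + extra_time
    frames, recs, state = run_simulation(
        grid, proto, total, params=params, mode=mode, dt=dt,
        frame_stride=frame_stride, probe_nodes=probe_nodes, state=state)
    captured = _capture_flags(recs[0].t, recs[0].v, cl, n_beats)
    return frames, recs, state, captured


def _capture_flags(t, v, cl, n_beats, level: float = ACTIVITY_LEVEL):
    """Per-stimulus flag: did the far-field probe activate in that cycle?"""
    flags = []
    for ib in range(n_beats):
        sel = (t >= ib * cl) & (t < (ib + 1) * cl)
        flags.append(bool((v[sel] > level).any()))
    return np.asarray(flags)


@dataclasses.dataclass
class S1S2Result:
    frames: FrameStack
    s2_time: float
    induced: bool
    state: TissueState


def s1s2_cross_field(grid: TissueGrid, params: CellParams | None = None,
                     mode="constitutive", s1_amplitude: float = S1_AMPLITUDE,
                     s2_amplitude: float = S1_AMPLITUDE,
                     duration: float = S1_DURATION,
                     s2_row_fraction: float = 162.0 / 256.0,
                     waveback_level: float = WAVEBACK_LEVEL,
                     follow_time: float = 1000.0,
                     frame_stride: float = 2.0,
                     dt: float = DT_DEFAULT) -> S1S2Result:
    """Standard S1-S2 cross-field spiral initiation.

    S1 is a line stimulus along the left border (columns < 5); when the
    waveback of the S1 wave (repolarization through ``waveback_level``)
    reaches the mid column, S2 is applied over the upper
    ``1 - s2_row_fraction`` of the domain.  The S2 timing is detected
    automatically and is deterministic for a given grid.
    """
    params = params or CellParams()
    solver = _Solver(grid, params, mode=mode, dt=dt)
    state = init_tissue_state(grid, params, mode)
    rows, cols = grid.myocyte_coords()
    mid_col = int((cols.min() + cols.max()) // 2)
    mid_nodes = np.flatnonzero(cols == mid_col)
    s2_nodes = np.flatnonzero(rows >= s2_row_fraction * grid.ny)
    s1_nodes = edge_nodes(grid, "left")

    frames, times = [], []
    chunk = max(1, int(round(1.0 / dt)))   # 1 ms resolution
    stride_chunks = max(1, int(round(frame_stride)))

    def snap(t):
        frames.append(grid.field_from_flat(state.v).copy())
        times.append(t)

    # S1
    t = 0.0
    snap(t)
    solver.advance(state, int(round(duration / dt)), stim_idx=s1_nodes,
                   stim_amp=_amp(params, s1_amplitude))
    t += duration
    # wait for the waveback to cross the mid column
    excited = False
    s2_time = None
    max_wait = int(round(400.0 / dt))
    waited = 0
    ic = 0
    while waited < max_wait:
        solver.advance(state, chunk)
        waited += chunk
        t += chunk * dt
        ic += 1
        if ic % stride_chunks == 0:
            snap(t)
        vm = state.v[mid_nodes]
        if not excited and (vm > ACTIVITY_LEVEL).any():
            excited = True
        if excited and np.median(vm) < waveback_level:
            s2_time = t
            break
    if s2_time is None:
        raise RuntimeError("S1 waveback never crossed the mid column")
    # S2
    if s2_amplitude != 0.0:
        solver.advance(state, int(round(duration / dt)), stim_idx=s2_nodes,
                       stim_amp=_amp(params, s2_amplitude))
        t += duration
    # follow
    n_follow = int(round(follow_time / dt))
    done = 0
    ic = 0
    while done < n_follow:
        solver.advance(state, chunk)
        done += chunk
        t += chunk * dt
        ic += 1
        if ic % stride_chunks == 0:
            snap(t)
    stack = FrameStack(frames=np.array(frames), times=np.array(times),
                       dx=grid.dx, meta=dict(s2_time=s2_time))
    induced = bool((frames[-1][np.isfinite(frames[-1])]
                    > ACTIVITY_LEVEL).any())
    return S1S2Result(frames=stack, s2_time=s2_time, induced=induced,
                      state=state)


@dataclasses.dataclass
class BurstResult:
    frames: FrameStack | None
    induced: bool
    state: TissueState


def burst_pacing(grid: TissueGrid, cl: float = 80.0, n_stimuli: int = 20,
                 params: CellParams | None = None, mode="constitutive",
                 region=None, amplitude: float = S1_AMPLITUDE,
                 duration: float = S1_DURATION,
                 follow_time: float = QUIESCENCE_WINDOW + 100.0,
                 frame_stride: float = 2.0, record_frames: bool = True,
                 state: TissueState | None = None,
                 dt: float = DT_DEFAULT) -> BurstResult:
    """High-frequency train from an edge region; detect induced reentry.

    ``induced`` is True when activity is still present during the last
    100 ms of a ``QUIESCENCE_WINDOW`` after the final stimulus (sustained
    self-driven activation, i.e. at least two rotations at the observed
    reentry periods).
    """
    params = params or CellParams()
    if region is None:
        region = edge_nodes(grid, "left")
    proto = ProtocolSpec().stimulus(0.0, region, _amp(params, amplitude),
                                    duration, count=n_stimuli, period=cl)
    total = cl * n_stimuli + follow_time
    frames, _recs, out_state = run_simulation(
        grid, proto, total, params=params, mode=mode, dt=dt,
        frame_stride=frame_stride, state=state,
        record_frames=record_frames, probe_nodes=None)
    induced = False
    if record_frames:
        tail = frames.times > total - 100.0
        tail_frames = frames.frames[tail]
        induced = bool(np.nanmax(tail_frames) > ACTIVITY_LEVEL)
    return BurstResult(frames=frames, induced=induced, state=out_state)


def apply_block(grid: TissueGrid, state: TissueState, current_id: str,
                fraction: float, duration: float,
                params: CellParams | None = None, mode="constitutive",
                frame_stride: float = 2.0, dt: float = DT_DEFAULT):
    """Continue a run with ``current_id`` scaled by (1 - fraction).

    Returns ``(FrameStack, final state)``; with ``fraction`` 0 the
    continuation is identical to an unblocked one (paired-run equality).
    """
    params = params or CellParams()
    proto = ProtocolSpec().block(0.0, current_id, fraction)
    frames, _recs, out_state = run_simulation(
        grid, proto, duration, params=params, mode=mode, dt=dt,
        frame_stride=frame_stride, state=state)
    return frames, out_state


def is_terminated(frames: FrameStack, t_from: float,
                  window: float = QUIESCENCE_WINDOW) -> bool:
    """No node crosses the activity level for ``window`` ms after t_from."""
    sel = (frames.times >= t_from) & (frames.times <= t_from + window)
    if not sel.any():
        return True
    return bool(np.nanmax(frames.frames[sel]) <= ACTIVITY_LEVEL)


def min_capture_cl(grid: TissueGrid, cl_grid, mode="constitutive",
                   params: CellParams | None = None, n_beats: int = 6,
                   n_check: int = 5, amplitude: float = S1_AMPLITUDE,
                   duration: float = S1_DURATION,
                   dt: float = DT_DEFAULT) -> float:
    """Smallest cycle length with 1:1 capture, scanned in descending order.

    Capture = one propagated activation at a far-field probe per stimulus
    over the final ``n_check`` stimuli.  The scan starts fresh from rest
    at each cycle length and stops at the first failure; returns the
    smallest captured cycle length (NaN when even the largest fails).
    """
    params = params or CellParams()
    cl_grid = sorted(set(float(c) for c in cl_grid), reverse=True)
    rows, cols = grid.myocyte_coords()
    probe = int(np.flatnonzero(cols == cols.max())[0])
    stim = edge_nodes(grid, "left")
    best = np.nan
    rest = init_tissue_state(grid, params, mode)
    for cl in cl_grid:
        solver = _Solver(grid, params, mode=mode, dt=dt)
        state = rest.copy()
        n_total = int(round(cl * n_beats / dt))
        pro = np.empty((1, n_total))
        pidx = np.array([probe], dtype=np.int64)
        steps_done = 0
        for ib in range(n_beats):
            ns = int(round(duration / dt))
            solver.advance(state, ns, stim_idx=stim,
                           stim_amp=_amp(params, amplitude),
                           probe_idx=pidx, probe_out=pro,
                           probe_col=steps_done)
            steps_done += ns
            ns2 = int(round(cl / dt)) - ns
            solver.advance(state, ns2, probe_idx=pidx, probe_out=pro,
                           probe_col=steps_done)
            steps_done += ns2
        t = np.arange(steps_done) * dt
        flags = _capture_flags(t[:steps_done], pro[0, :steps_done], cl,
                               n_beats)
        if flags[-n_check:].all():
            best = cl
        else:
            break
    return best
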