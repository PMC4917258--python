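"""2D monodomain solver: forward Euler + 5-point Laplacian, no-flux borders.

The transmembrane potential obeys dV/dt = -(I_ion - I_stim)/Cm + D lap(V)
on the myocyte nodes of a :class:`~nram.monolayer.TissueGrid`; fibroblast
nodes carry a passive membrane coupled to neighbouring myocytes through
G_gap and are excluded from the diffusion operator.  The default numerics
are dt = 0.02 ms and dx = 0.00625 cm, which satisfy the diffusion
stability bound dt <= dx^2/(4 D).
"""

from __future__ import annotations

import dataclasses
import logging
import uuid

import numpy as np

from . import _model
from .cell import IntegrationBlowupError, resting_state
from .protocols import resolve_mode
from .constants import NVAR, S_V, STATE_FIELDS
from .monolayer import FIBROBLAST, TissueGrid
from .params import CellParams
from .recording import FrameStack, Recording

DT_DEFAULT = 0.02  # ms

logger = logging.getLogger("nram.tissue")


def laplacian_neumann(v_field: np.ndarray, dx: float,
                      diff_coef: float = 1.0,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """D * discrete Laplacian with zero-flux (mirror) boundaries.

    ``v_field`` is (ny, nx); ``mask`` marks the diffusing domain (True
    inside).  Neighbours outside the mask are mirrored, so the discrete
    divergence theorem holds: the masked sum of the output is zero.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    v = np.asarray(v_field, dtype=float)
    if mask is None:
        mask = np.ones_like(v, dtype=bool)
    out = np.zeros_like(v)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nbr_v = np.roll(v, shift, axis=axis)
        nbr_m = np.roll(mask, shift, axis=axis)
        # roll wraps around; edge rows/cols must mirror, not wrap
        edge = np.zeros_like(mask)
        if axis == 0:
            idx = 0 if shift == 1 else -1
            edge[idx, :] = True
        else:
            idx = 0 if shift == 1 else -1
            edge[:, idx] = True
        use_nbr = nbr_m & ~edge
        contrib = np.where(use_nbr, nbr_v, v)
        out += contrib - v
    out[~mask] = 0.0
    return diff_coef * out / (dx * dx)


@dataclasses.dataclass
class TissueState:
    """Solver state: per-myocyte state matrix plus fibroblast potentials."""

    S: np.ndarray          # (NVAR, n_myocytes)
    v_fb: np.ndarray       # (n_fibroblasts,)
    t: float = 0.0

    def copy(self) -> "TissueState":
        return TissueState(self.S.copy(), self.v_fb.copy(), self.t)

    @property
    def v(self) -> np.ndarray:
        return self.S[S_V]


def init_tissue_state(grid: TissueGrid, params: CellParams | None = None,
                      mode="constitutive") -> TissueState:
    """All nodes start from the single-cell resting state."""
    params = params or CellParams()
    run_params, mode_id = resolve_mode(params, mode)
    rest = resting_state(run_params, mode_id)
    S = np.repeat(rest.values.reshape(NVAR, 1), grid.n_myocytes, axis=1)
    v_fb = np.full(grid.n_fibroblasts, rest.v)
    return TissueState(np.ascontiguousarray(S), v_fb)


class _Solver:
    """Pre-packed kernel arguments for one (grid, params, mode) context."""

    def __init__(self, grid: TissueGrid, params: CellParams,
                 mode="constitutive", dt: float = DT_DEFAULT,
                 rush_larsen: bool = True, fb_coupled: bool = True):
        if dt <= 0:
            raise ValueError("dt must be positive")
        stability = grid.dx ** 2 / (4.0 * grid.diff_coef)
        if dt > stability:
            raise ValueError(
                f"dt={dt} exceeds the diffusion stability bound "
                f"{stability:.4f} ms")
        self.grid = grid
        self.params, self.mode = resolve_mode(params, mode)
        self.dt = dt
        self.rush_larsen = rush_larsen
        self.p_vec = self.params.to_vector()
        self.block_vec = self.params.block_vector()
        self.mult = np.ascontiguousarray(grid.multipliers)
        self.nb = grid.neighbor_table()
        self.fb_ptr, self.fb_nbr = grid.fibroblast_links()
        self.g_gap = grid.g_gap_fb if fb_coupled else 0.0
        self.g_fb = grid.fb.g_fb
        self.e_fb = grid.fb.e_fb
        self._empty = np.zeros(0, dtype=np.int64)
        self._empty_probe = np.zeros((0, 0))

    def advance(self, state: TissueState, n_steps: int,
                stim_idx=None, stim_amp: float = 0.0,
                probe_idx=None, probe_out=None, probe_col: int = 0):
        stim = self._empty if stim_idx is None else \
            np.asarray(stim_idx, dtype=np.int64)
        if probe_idx is None:
            probe_idx, probe_out = self._empty, np.zeros((0, n_steps))
        bad = _model.tissue_advance(
            state.S, self.p_vec, self.mult, self.block_vec, self.mode,
            self.rush_larsen, self.dt, n_steps, self.grid.diff_coef,
            self.grid.dx, self.nb, stim, stim_amp, state.v_fb,
            self.fb_ptr, self.fb_nbr, self.g_gap, self.g_fb, self.e_fb,
            np.asarray(probe_idx, dtype=np.int64), probe_out, probe_col)
        state.t += n_steps * self.dt
        if bad >= 0:
            r, c = (self.grid.myocyte_coords()[0][bad],
                    self.grid.myocyte_coords()[1][bad])
            raise IntegrationBlowupError(
                f"non-finite V at node (row={r}, col={c}) t={state.t:.2f} ms")

    def set_block(self, current_id: str, fraction: float) -> None:
        self.params = self.params.with_block(current_id, fraction)
        self.block_vec = self.params.block_vector()


def step_tissue(state: TissueState, dt: float, grid: TissueGrid,
                params: CellParams | None = None, mode="constitutive",
                n_steps: int = 1, stim_idx=None, stim_amp: float = 0.0,
                rush_larsen: bool = True,
                fb_coupled: bool = True) -> TissueState:
    """Advance a tissue state ``n_steps`` of ``dt`` (functional wrapper).

    ``stim_idx`` selects myocyte nodes receiving a constant depolarizing
    ``stim_amp`` (pA/pF) for the whole call.
    """
    params = params or CellParams()
    solver = _Solver(grid, params, mode=mode, dt=dt,
                     rush_larsen=rush_larsen, fb_coupled=fb_coupled)
    new = state.copy()
    solver.advance(new, n_steps, stim_idx=stim_idx, stim_amp=stim_amp)
    return new


# ---------------------------------------------------------------------------
# declarative protocol execution
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StimulusEvent:
    """Rectangular stimulus on a node-index set."""

    time: float                # ms, onset
    nodes: np.ndarray          # flat myocyte indices
    amplitude: float           # pA/pF
    duration: float            # ms
    count: int = 1             # pulses
    period: float = 0.0        # ms between pulse onsets when count > 1


@dataclasses.dataclass
class BlockEvent:
    """Scale a current by (1 - fraction) from ``time`` onward."""

    time: float
    current_id: str
    fraction: float


@dataclasses.dataclass
class ProtocolSpec:
    """Ordered stimulus/block events plus bookkeeping."""

    events: list = dataclasses.field(default_factory=list)

    def stimulus(self, time, nodes, amplitude, duration, count=1, period=0.0):
        self.events.append(StimulusEvent(
            time=float(time), nodes=np.asarray(nodes, dtype=np.int64),
            amplitude=float(amplitude), duration=float(duration),
            count=int(count), period=float(period)))
        return self

    def block(self, time, current_id, fraction):
        self.events.append(BlockEvent(float(time), current_id,
                                      float(fraction)))
        return self

    def expanded_stimuli(self):
        """Flatten pulse trains into (onset, offset, nodes, amp) tuples."""
        out = []
        for ev in self.events:
            if isinstance(ev, StimulusEvent):
                for i in range(ev.count):
                    t0 = ev.time + i * ev.period
                    out.append((t0, t0 + ev.duration, ev.nodes,
                                ev.amplitude))
        return sorted(out, key=lambda x: x[0])

    def block_events(self):
        return sorted((ev for ev in self.events
                       if isinstance(ev, BlockEvent)),
                      key=lambda ev: ev.time)


def run_simulation(grid: TissueGrid, protocol: ProtocolSpec,
                   duration: float, params: CellParams | None = None,
                   mode="constitutive", dt: float = DT_DEFAULT,
                   frame_stride: float = 1.0, probe_nodes=None,
                   state: TissueState | None = None,
                   rush_larsen: bool = True, fb_coupled: bool = True,
                   record_frames: bool = True):
    """Execute a protocol and record frames and/or point traces.

    Deterministic given (grid, protocol, params).  Returns
    ``(FrameStack | None, probe Recordings, TissueState)``.  Probe traces
    are sampled at every time step; frames every ``frame_stride`` ms.
    """
    params = params or CellParams()
    stims = protocol.expanded_stimuli()
    blocks = protocol.block_events()
    for t0, _, _, _ in stims:
        if t0 >= duration:
            raise ValueError("protocol event beyond simulation duration")
    solver = _Solver(grid, params, mode=mode, dt=dt,
                     rush_larsen=rush_larsen, fb_coupled=fb_coupled)
    if state is None:
        state = init_tissue_state(grid, params, mode)
    state = state.copy()

    n_total = int(round(duration / dt))
    probe_idx = (np.asarray(probe_nodes, dtype=np.int64)
                 if probe_nodes is not None else np.zeros(0, dtype=np.int64))
    probe_out = np.empty((probe_idx.size, n_total))

    stride_steps = max(1, int(round(frame_stride / dt)))
    frames, frame_times = [], []

    # breakpoints: every stimulus onset/offset and block time, on the step grid
    marks = {0, n_total}
    for t0, t1, _, _ in stims:
        marks.add(int(round(t0 / dt)))
        marks.add(min(int(round(t1 / dt)), n_total))
    for ev in blocks:
        marks.add(min(int(round(ev.time / dt)), n_total))
    if record_frames:
        marks.update(range(0, n_total + 1, stride_steps))
    marks = sorted(marks)

    def active_stim(step):
        t = step * dt
        sel = [(nodes, amp) for (t0, t1, nodes, amp) in stims
               if t0 - 1e-9 <= t < t1 - 1e-9]
        if not sel:
            return None, 0.0
        if len(sel) == 1:
            return sel[0]
        nodes = np.concatenate([n for n, _ in sel])
        return nodes, sel[0][1]

    run_id = uuid.uuid4().hex[:8]
    logger.info("run=%s start: %d nodes, %.0f ms, dt=%g ms",
                run_id, grid.n_myocytes, duration, dt)
    log_every = max(1, int(round(100.0 / dt)))
    next_log = log_every
    bi = 0
    warned_active = False
    for a, b in zip(marks[:-1], marks[1:]):
        if b <= a:
            continue
        while bi < len(blocks) and int(round(blocks[bi].time / dt)) <= a:
            solver.set_block(blocks[bi].current_id, blocks[bi].fraction)
            bi += 1
        if record_frames and a % stride_steps == 0:
            frames.append(grid.field_from_flat(state.v).copy())
            frame_times.append(a * dt)
        nodes, amp = active_stim(a)
        solver.advance(state, b - a, stim_idx=nodes, stim_amp=amp,
                       probe_idx=probe_idx, probe_out=probe_out,
                       probe_col=a)
        warned_active = warned_active or bool((state.v > -20).any())
        if b >= next_log:
            logger.info("run=%s t=%.0f/%.0f ms", run_id, b * dt, duration)
            next_log += log_every
    if record_frames and n_total % stride_steps == 0:
        frames.append(grid.field_from_flat(state.v).copy())
        frame_times.append(duration)

    stack = None
    if record_frames:
        stack = FrameStack(frames=np.array(frames),
                           times=np.array(frame_times), dx=grid.dx,
                           meta=dict(mode=mode, dt=dt))
    recs = [Recording(t=np.arange(n_total) * dt, v=probe_out[i])
            for i in range(probe_idx.size)]
    if stims and not warned_active:
        import warnings
        warnings.warn("no supra-threshold activity recorded",
                      RuntimeWarning, stacklevel=2)
    return stack, recs, state
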