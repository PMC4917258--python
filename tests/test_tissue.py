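"""Monodomain solver: Laplacian with no-flux borders, conservation,
single-cell equivalence, determinism, fibroblast coupling, protocols."""

import numpy as np
import pytest

from nram.cell import IntegrationBlowupError, resting_state
from nram.constants import MODE_CONSTITUTIVE
from nram.monolayer import build_monolayer, build_strip
from nram.params import CellParams
from nram.protocols import _run
from nram.protocols2d import edge_nodes, min_capture_cl, region_nodes
from nram.tissue import (
    ProtocolSpec, _Solver, init_tissue_state, laplacian_neumann,
    run_simulation, step_tissue,
)


# ---------------------------------------------------------------------------
# Laplacian
# ---------------------------------------------------------------------------

def test_laplacian_zero_for_uniform_field():
    v = np.full((8, 8), -72.0)
    out = laplacian_neumann(v, dx=0.00625)
    assert np.allclose(out, 0.0)


def test_laplacian_single_node_delta_hand_stencil():
    """A unit delta in the interior spreads with the 5-point weights; at a
    corner, missing neighbours are mirrored (coefficient -2 instead of
    -4)."""
    dx = 1.0
    v = np.zeros((5, 5))
    v[2, 2] = 1.0
    out = laplacian_neumann(v, dx)
    assert out[2, 2] == pytest.approx(-4.0)
    assert out[1, 2] == out[3, 2] == out[2, 1] == out[2, 3] == \
        pytest.approx(1.0)
    v2 = np.zeros((5, 5))
    v2[0, 0] = 1.0
    out2 = laplacian_neumann(v2, dx)
    assert out2[0, 0] == pytest.approx(-2.0)   # two mirrored neighbours


def test_laplacian_conserves_masked_sum(rng):
    """Discrete divergence theorem: the masked sum of D lap(V) is zero."""
    yy, xx = np.mgrid[0:16, 0:16]
    mask = (yy - 7.5) ** 2 + (xx - 7.5) ** 2 < 49
    v = rng.normal(-70, 10, size=(16, 16))
    out = laplacian_neumann(v, dx=0.00625, diff_coef=1.2e-4, mask=mask)
    assert out[mask].sum() == pytest.approx(0.0, abs=1e-12)
    assert np.all(out[~mask] == 0.0)


def test_pure_diffusion_conserves_total_voltage(rng):
    """Iterated diffusion with no reaction conserves the field sum to
    machine precision (no-flux boundaries)."""
    v = rng.normal(-70, 15, size=(12, 12))
    total0 = v.sum()
    for _ in range(2000):
        v = v + 0.02 * laplacian_neumann(v, dx=0.00625, diff_coef=1.2e-4)
    assert v.sum() == pytest.approx(total0, rel=1e-13)
    assert np.ptp(v) < np.ptp(v) + 1  # field stays finite


def test_laplacian_rejects_bad_dx():
    with pytest.raises(ValueError):
        laplacian_neumann(np.zeros((4, 4)), dx=0.0)


# ---------------------------------------------------------------------------
# solver basics
# ---------------------------------------------------------------------------

def test_stability_bound_enforced(params):
    grid = build_strip(nx=8, ny=2)
    with pytest.raises(ValueError, match="stability"):
        _Solver(grid, params, dt=1.0)


def test_uniform_tissue_equals_single_cell(params, rest_constitutive):
    """With identical nodes and a whole-domain stimulus the diffusion
    term vanishes and the tissue trajectory equals the single cell's
    exactly."""
    grid = build_strip(nx=4, ny=4)
    state = init_tissue_state(grid, params, "constitutive")
    solver = _Solver(grid, params, "constitutive")
    all_nodes = np.arange(grid.n_myocytes)
    solver.advance(state, int(5.0 / 0.02), stim_idx=all_nodes,
                   stim_amp=7.0)
    solver.advance(state, int(195.0 / 0.02))
    _, single, _ = _run(rest_constitutive, params, MODE_CONSTITUTIVE,
                        0.02, int(200 / 0.02), 7.0, 0.0, 1000.0, 1, 5.0)
    assert np.ptp(state.v) == 0.0
    assert state.v[0] == pytest.approx(single.v, abs=1e-9)


def test_resting_tissue_stays_at_rest(params):
    """An empty protocol leaves every node within 1 mV of rest."""
    grid = build_strip(nx=8, ny=4)
    frames, _, state = run_simulation(grid, ProtocolSpec(), 200.0,
                                      params=params, frame_stride=50.0)
    rest = resting_state(params, "constitutive")
    assert np.nanmax(np.abs(frames.frames[-1] - rest.v)) < 1.0


def test_rerun_is_bit_identical(params):
    """Determinism: identical grid + protocol give identical frames."""
    grid = build_monolayer(nx=20, ny=20, diameter=0.12, fib_fraction=0.15,
                           variability=(80, 120), seed=11)
    proto = ProtocolSpec().stimulus(0.0, edge_nodes(grid, "left", 2),
                                    50.0, 2.0)
    out = []
    for _ in range(2):
        frames, _, _ = run_simulation(grid, proto, 40.0, params=params,
                                      frame_stride=5.0)
        out.append(frames.frames)
    assert np.array_equal(out[0], out[1], equal_nan=True)


def test_blowup_reports_node_coordinates(params):
    grid = build_strip(nx=4, ny=2)
    bad = params.replace(g_na=1e9, g_cal=1e9)
    state = init_tissue_state(grid, params, "constitutive")
    solver = _Solver(grid, bad, "constitutive")
    with pytest.raises(IntegrationBlowupError, match="row"):
        solver.advance(state, 500, stim_idx=np.arange(8), stim_amp=100.0)


def test_step_tissue_functional_wrapper(params):
    grid = build_strip(nx=6, ny=2)
    state = init_tissue_state(grid, params, "constitutive")
    new = step_tissue(state, 0.02, grid, params, n_steps=10)
    assert new is not state
    assert new.t == pytest.approx(0.2)
    assert np.all(np.isfinite(new.v))


# ---------------------------------------------------------------------------
# stimulus regions, block events, fibroblast coupling
# ---------------------------------------------------------------------------

def test_edge_and_region_helpers():
    grid = build_strip(nx=10, ny=4)
    left = edge_nodes(grid, "left", width=2)
    rows, cols = grid.myocyte_coords()
    assert np.all(cols[left] < 2)
    box = region_nodes(grid, row_range=(0, 2), col_range=(5, 10))
    assert np.all((rows[box] < 2) & (cols[box] >= 5))
    with pytest.raises(ValueError):
        edge_nodes(grid, "diagonal")


def test_zero_fraction_block_is_identity(params):
    """A block event with fraction 0 leaves the run unchanged."""
    grid = build_strip(nx=12, ny=2)
    stim = edge_nodes(grid, "left", 2)
    base = ProtocolSpec().stimulus(0.0, stim, 100.0, 2.0)
    nul = ProtocolSpec().stimulus(0.0, stim, 100.0, 2.0) \
                        .block(20.0, "i_kach", 0.0)
    fa, _, _ = run_simulation(grid, base, 60.0, params=params,
                              frame_stride=10.0)
    fb, _, _ = run_simulation(grid, nul, 60.0, params=params,
                              frame_stride=10.0)
    assert np.array_equal(np.nan_to_num(fa.frames),
                          np.nan_to_num(fb.frames))


def test_block_event_changes_only_through_kach(params):
    """Frames before a mid-run block are identical; frames after differ."""
    grid = build_strip(nx=12, ny=2)
    stim = edge_nodes(grid, "left", 2)
    base = ProtocolSpec().stimulus(0.0, stim, 100.0, 2.0)
    blk = ProtocolSpec().stimulus(0.0, stim, 100.0, 2.0) \
                        .block(15.0, "i_kach", 1.0)
    fa, _, _ = run_simulation(grid, base, 60.0, params=params,
                              frame_stride=5.0)
    fb, _, _ = run_simulation(grid, blk, 60.0, params=params,
                              frame_stride=5.0)
    pre = fa.times <= 15.0
    assert np.array_equal(np.nan_to_num(fa.frames[pre]),
                          np.nan_to_num(fb.frames[pre]))
    assert not np.array_equal(np.nan_to_num(fa.frames),
                              np.nan_to_num(fb.frames))


def test_fibroblast_coupling_loads_the_myocytes(params):
    """Coupled passive fibroblasts perturb propagation; with coupling
    off they are pure obstacles and the result differs."""
    grid = build_monolayer(nx=24, ny=24, diameter=0.145,
                           fib_fraction=0.25, variability=(100, 100),
                           seed=3)
    stim = edge_nodes(grid, "left", 3)
    proto = ProtocolSpec().stimulus(0.0, stim, 100.0, 2.0)
    on, _, _ = run_simulation(grid, proto, 50.0, params=params,
                              frame_stride=10.0, fb_coupled=True)
    off, _, _ = run_simulation(grid, proto, 50.0, params=params,
                               frame_stride=10.0, fb_coupled=False)
    assert not np.array_equal(np.nan_to_num(on.frames),
                              np.nan_to_num(off.frames))


def test_min_capture_scan_trivial_long_cycles(params):
    """With only long cycle lengths on the grid, the smallest tested one
    is returned (everything captures)."""
    grid = build_strip(nx=24, ny=2)
    cl = min_capture_cl(grid, [600.0, 500.0], mode="constitutive",
                        params=params, n_beats=2, n_check=2)
    assert cl == 500.0
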