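"""Single-cell protocols: AP metrics, pacing, restitution, holding
current."""

import numpy as np
import pytest

from nram.fixtures import synthetic_ap_trace
from nram.params import CellParams
from nram.protocols import (
    _run, ap_metrics, dynamic_restitution, holding_current_for,
    pace_to_steady_state, resolve_mode,
)
from nram.recording import Recording
from nram.constants import MODE_SINGLE_CELL


# ---------------------------------------------------------------------------
# AP metrics on analytic traces
# ---------------------------------------------------------------------------

def test_square_pulse_apd50_equals_apd80():
    """A rectangular 50 ms pulse has APD50 = APD80 = 50 ms."""
    rec = synthetic_ap_trace(rmp=0.0, peak=100.0, plateau_ms=50.0,
                             repol_ms=0.5, upstroke_ms=0.5)
    m = ap_metrics(rec)
    assert m.apd50 == pytest.approx(50.0, abs=1.0)
    assert m.apd80 == pytest.approx(50.0, abs=1.0)
    assert m.amplitude == pytest.approx(100.0, abs=0.5)


def test_linear_ramp_triangle_geometry():
    """Linear repolarization over 100 ms: APD80 = 80 ms, APD50 = 50 ms."""
    rec = synthetic_ap_trace(rmp=0.0, peak=100.0, plateau_ms=0.0,
                             repol_ms=100.0, upstroke_ms=0.5)
    m = ap_metrics(rec)
    assert m.apd80 == pytest.approx(80.0, abs=1.0)
    assert m.apd50 == pytest.approx(50.0, abs=1.0)
    assert m.rmp == pytest.approx(0.0, abs=1e-9)


def test_metrics_invariant_apd50_le_apd80():
    rec = synthetic_ap_trace()
    m = ap_metrics(rec)
    assert m.apd50 <= m.apd80


def test_no_upstroke_raises():
    t = np.arange(0, 100, 0.1)
    flat = Recording(t=t, v=np.full(t.size, -72.0))
    with pytest.raises(ValueError, match="upstroke"):
        ap_metrics(flat)


# ---------------------------------------------------------------------------
# pacing
# ---------------------------------------------------------------------------

def test_pacing_reaches_steady_state(paced_1hz):
    apds = paced_1hz.meta["apd80_per_beat"]
    assert paced_1hz.meta["steady"]
    assert abs(apds[-1] - apds[-2]) < 1.0
    assert paced_1hz.meta["captured"].all()


def test_zero_amplitude_stimulus_gives_no_ap(params):
    rec = pace_to_steady_state(params, bcl=500.0, n_beats=2,
                               stim_amplitude=0.0)
    assert rec.v.max() - rec.v.min() < 5.0
    assert not rec.meta["captured"].any()


def test_doubling_beats_leaves_apd_stable(params):
    """Steady state: the final APD80 moves < 1 ms when the train is
    twice as long."""
    a = pace_to_steady_state(params, bcl=1000.0, n_beats=10)
    b = pace_to_steady_state(params, bcl=1000.0, n_beats=20)
    assert a.meta["apd80_per_beat"][-1] == pytest.approx(
        b.meta["apd80_per_beat"][-1], abs=1.0)


def test_invalid_beat_count(params):
    with pytest.raises(ValueError):
        pace_to_steady_state(params, n_beats=0)


# ---------------------------------------------------------------------------
# restitution
# ---------------------------------------------------------------------------

def test_restitution_requires_descending_bcls(params):
    with pytest.raises(ValueError):
        dynamic_restitution(params, bcl_list=[500, 600], beats_per_bcl=2)


def test_restitution_monotone_and_capture(params):
    """APD80 does not increase as the cycle length shortens; capture is
    lost at very short cycle lengths; long cycle lengths give the
    fully-rested APD."""
    table = dynamic_restitution(
        params, bcl_list=[800.0, 400.0, 200.0, 120.0, 30.0],
        beats_per_bcl=6, mode="constitutive")
    captured = table.captured
    apd = table.apd80
    assert captured[0] and captured[1]
    assert not captured[-1]                     # 30 ms cannot capture 1:1
    ok = np.isfinite(apd)
    assert np.all(np.diff(apd[ok]) <= 1.0)      # non-increasing (1 ms slack)
    # decoupled beats: APD at 800 ms within 1 ms of the 1 Hz value
    ref = pace_to_steady_state(params, bcl=800.0, n_beats=6,
                               mode="constitutive")
    assert apd[0] == pytest.approx(ref.meta["apd80_per_beat"][-1], abs=1.5)


def test_block_lengthens_apd_fraction_ordered(params):
    """Tissue-form APD80 at 1 Hz grows monotonically with the blocked
    fraction of the constitutive K+ current."""
    apds = []
    for frac in (0.0, 0.5, 1.0):
        p = params.with_block("i_kach", frac)
        rec = pace_to_steady_state(p, bcl=1000.0, n_beats=5,
                                   mode="constitutive")
        apds.append(rec.meta["apd80_per_beat"][-1])
    assert apds[0] < apds[1] < apds[2]


# ---------------------------------------------------------------------------
# holding current
# ---------------------------------------------------------------------------

def test_holding_current_zero_at_natural_rmp(params, rest_single):
    i_hold = holding_current_for(params, v_target=rest_single.v)
    assert abs(i_hold) < 0.02


def test_holding_current_hyperpolarizing_at_minus_85(params, rest_single):
    """Holding at -85 mV needs a hyperpolarizing bias; applying it for
    1 s keeps V within 0.5 mV of target."""
    i_hold = holding_current_for(params, v_target=-85.0)
    assert i_hold < 0.0
    state = rest_single.copy()
    state.values[0] = -85.0
    rec, final, _ = _run(state, params, MODE_SINGLE_CELL, 0.02,
                         int(1000 / 0.02), 0.0, 0.0, 1000.0, 0, 0.0,
                         i_hold=i_hold)
    assert abs(final.v - (-85.0)) < 0.5


def test_holding_current_monotone_in_target(params):
    vals = [holding_current_for(params, v) for v in (-70.0, -80.0, -90.0)]
    assert vals[0] > vals[1] > vals[2]


def test_holding_current_range_validation(params):
    with pytest.raises(ValueError):
        holding_current_for(params, v_target=-20.0)


def test_mode_resolution(params):
    p_cch, mid = resolve_mode(params, "carbachol")
    assert p_cch.ach > 100.0 and mid == MODE_SINGLE_CELL
    p_tert, mid2 = resolve_mode(params, "tertiapin")
    assert p_tert.block["i_kach"] == 1.0
    with pytest.raises(ValueError):
        resolve_mode(params, "bogus")
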