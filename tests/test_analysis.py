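"""Map/trajectory/spectral analysis on synthetic recordings with known
ground truth."""

import numpy as np
import pytest

from nram.analysis import (
    ActivationMap, activation_map, apd_map, conduction_velocity,
    cv_from_probes, dominant_period, tip_trajectory, wavelength,
)
from nram.fixtures import (
    plane_wave_movie, rotor_movie, synthetic_ap_trace,
)
from nram.recording import FrameStack, Recording


def test_activation_map_recovers_prescribed_delays():
    """A plane wave moving at 0.5 nodes/ms gives a linear activation
    profile with slope 2 ms/node."""
    movie = plane_wave_movie(n=48, speed_nodes_per_ms=0.5)
    amap = activation_map(movie, threshold=-26.0)
    prof = np.nanmean(amap.times, axis=0)
    sl = np.polyfit(np.arange(10, 38), prof[10:38], 1)[0]
    assert sl == pytest.approx(2.0, rel=0.05)
    # straight isochrones: no variation across rows
    assert np.nanmax(np.nanstd(amap.times[:, 10:38], axis=0)) < 0.2


def test_conduction_velocity_exact_on_uniform_gradient():
    """times = x * g  =>  CV = 1/g exactly."""
    g = 2.0   # ms per node
    dx = 0.00625
    times = np.tile(np.arange(64) * g, (4, 1))
    cv = conduction_velocity(ActivationMap(times=times), dx, margin=5)
    assert cv == pytest.approx(dx / g * 1000.0, rel=1e-9)


def test_conduction_velocity_margin_plateau():
    times = np.tile(np.arange(64) * 1.5, (4, 1))
    a = conduction_velocity(ActivationMap(times=times), 0.00625, margin=5)
    b = conduction_velocity(ActivationMap(times=times), 0.00625, margin=20)
    assert a == pytest.approx(b, rel=1e-9)


def test_cv_from_probes():
    assert cv_from_probes(10.0, 20.0, 0.25) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        cv_from_probes(20.0, 10.0, 0.25)


def test_apd_map_recovers_designed_step():
    """Frames assembled from two AP shapes give a dispersion equal to
    the designed APD step."""
    fast = synthetic_ap_trace(rmp=-72.0, peak=40.0, repol_ms=50.0,
                              t_up=10.0, dt=1.0, t_total=200.0)
    slow = synthetic_ap_trace(rmp=-72.0, peak=40.0, repol_ms=80.0,
                              t_up=10.0, dt=1.0, t_total=200.0)
    ny = nx = 8
    frames = np.empty((fast.t.size, ny, nx))
    for j in range(ny):
        for i in range(nx):
            frames[:, j, i] = slow.v if i >= nx // 2 else fast.v
    stack = FrameStack(frames=frames, times=fast.t, dx=0.00625)
    amap, disp = apd_map(stack, stim_time=10.0)
    # APD80 difference of the two designs: 0.8 * (80 - 50) = 24 ms
    assert disp == pytest.approx(24.0, abs=2.0)


def test_apd_map_uniform_tissue_zero_dispersion():
    tr = synthetic_ap_trace(rmp=-72.0, peak=40.0, repol_ms=60.0,
                            t_up=10.0, dt=1.0, t_total=200.0)
    frames = np.tile(tr.v[:, None, None], (1, 6, 6))
    stack = FrameStack(frames=frames, times=tr.t, dx=0.00625)
    _, disp = apd_map(stack, stim_time=10.0)
    assert disp == pytest.approx(0.0, abs=1e-9)


def test_tip_found_at_rotor_center():
    """A rigidly rotating spiral has its phase singularity at the
    rotation center; the tracker stays within one node of it."""
    movie = rotor_movie(n=48, n_frames=60)
    traj = tip_trajectory(movie)
    ok = np.isfinite(traj.x)
    assert ok.sum() > 40
    assert abs(np.nanmean(traj.x) - 23.5) < 1.0
    assert abs(np.nanmean(traj.y) - 23.5) < 1.0


def test_tip_orbit_is_circular_around_meander_center():
    """With the rotor center moving on a circle, the tracked tip traces
    a closed near-circular orbit around the same center (the detected
    point trails the true singularity, so the radius is smaller but the
    circular geometry must be exact)."""
    movie = rotor_movie(n=64, n_frames=90, orbit_radius=6.0)
    traj = tip_trajectory(movie)
    ok = np.isfinite(traj.x)
    assert ok.sum() > 70
    cx, cy = np.nanmean(traj.x), np.nanmean(traj.y)
    assert cx == pytest.approx(31.5, abs=1.0)
    assert cy == pytest.approx(31.5, abs=1.0)
    r = np.hypot(traj.x - cx, traj.y - cy)
    assert 1.5 < np.nanmean(r) < 7.0
    assert np.nanstd(r) < 0.2 * np.nanmean(r)


def test_plane_wave_has_no_tip():
    movie = plane_wave_movie(n=32)
    traj = tip_trajectory(movie)
    assert np.isfinite(traj.x).sum() <= 2


def test_dominant_period_pure_tone():
    """A 12.5 Hz sinusoid has an 80 ms dominant period."""
    t = np.arange(0, 4000.0, 1.0)
    v = np.sin(2 * np.pi * t / 80.0)
    period, res = dominant_period(Recording(t=t, v=v))
    assert period == pytest.approx(80.0, abs=res + 1.0)


def test_dominant_period_two_tone_picks_stronger():
    t = np.arange(0, 4000.0, 1.0)
    v = 1.0 * np.sin(2 * np.pi * t / 120.0) \
        + 0.3 * np.sin(2 * np.pi * t / 60.0)
    period, res = dominant_period(Recording(t=t, v=v))
    assert period == pytest.approx(120.0, abs=res + 2.0)


def test_wavelength_arithmetic():
    assert wavelength(22.2, 40.0) == pytest.approx(0.888)
    assert wavelength(22.2, 0.0) == 0.0
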