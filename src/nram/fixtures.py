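"""Deterministic synthetic inputs for testing and demonstration.

Everything is generated programmatically from an explicit seed: tiny
grids, rigid-rotor voltage movies with a known tip path, action-potential
traces with known metrics, and APD maps with a designed dispersion.
"""

from __future__ import annotations

import numpy as np

from .monolayer import build_monolayer
from .recording import FrameStack, Recording


def rotor_movie(n: int = 64, n_frames: int = 100, dt_ms: float = 2.0,
                period_ms: float = 80.0, wavelength_nodes: float = 40.0,
                center=None, orbit_radius: float = 0.0,
                v_rest: float = -72.0, v_peak: float = 20.0,
                dx: float = 0.00625, seed: int = 0) -> FrameStack:
    """A rigidly rotating Archimedean-spiral voltage movie.

    The phase field is ``theta - 2*pi*(t/T) - 2*pi*r/lambda`` about a
    center that itself moves on a circle of ``orbit_radius`` nodes, so the
    true tip path is known exactly (a point for radius 0).
    """
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    frames = np.empty((n_frames, n, n))
    times = np.arange(n_frames) * dt_ms
    for k, t in enumerate(times):
        ang = 2.0 * np.pi * t / period_ms
        cx = center[0] + orbit_radius * np.cos(ang)
        cy = center[1] + orbit_radius * np.sin(ang)
        r = np.hypot(xx - cx, yy - cy)
        th = np.arctan2(yy - cy, xx - cx)
        phase = th - ang - 2.0 * np.pi * r / wavelength_nodes
        act = 1.0 / (1.0 + np.exp(-4.0 * np.cos(phase)))
        frames[k] = v_rest + (v_peak - v_rest) * act
    return FrameStack(frames=frames, times=times, dx=dx,
                      meta=dict(period_ms=period_ms, center=center,
                                orbit_radius=orbit_radius, seed=seed))


def plane_wave_movie(n: int = 64, n_frames: int = 60, dt_ms: float = 2.0,
                     speed_nodes_per_ms: float = 0.5,
                     width_nodes: float = 10.0, v_rest: float = -72.0,
                     v_peak: float = 20.0, dx: float = 0.00625
                     ) -> FrameStack:
    """A planar pulse sweeping left to right at a known speed."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    frames = np.empty((n_frames, n, n))
    times = np.arange(n_frames) * dt_ms
    for k, t in enumerate(times):
        front = speed_nodes_per_ms * t
        up = 1.0 / (1.0 + np.exp(-(front - xx)))
        down = 1.0 / (1.0 + np.exp(-(front - width_nodes - xx)))
        frames[k] = v_rest + (v_peak - v_rest) * (up - down)
    return FrameStack(frames=frames, times=times, dx=dx)


def synthetic_ap_trace(rmp: float = -72.0, peak: float = 40.0,
                       plateau_ms: float = 0.0, repol_ms: float = 100.0,
                       upstroke_ms: float = 1.0, t_total: float = 400.0,
                       t_up: float = 50.0, dt: float = 0.1) -> Recording:
    """A triangular AP with analytically known metrics.

    Instant rise at ``t_up`` over ``upstroke_ms``, optional flat plateau,
    then linear repolarization to ``rmp`` over ``repol_ms``: by
    construction APD_x = plateau + x% * repol (measured from the
    upstroke).
    """
    t = np.arange(0.0, t_total, dt)
    v = np.full(t.size, rmp)
    amp = peak - rmp
    rise = (t >= t_up) & (t < t_up + upstroke_ms)
    v[rise] = rmp + amp * (t[rise] - t_up) / upstroke_ms
    top = (t >= t_up + upstroke_ms) & (t < t_up + upstroke_ms + plateau_ms)
    v[top] = peak
    t_r0 = t_up + upstroke_ms + plateau_ms
    fall = (t >= t_r0) & (t < t_r0 + repol_ms)
    v[fall] = peak - amp * (t[fall] - t_r0) / repol_ms
    return Recording(t=t, v=v, stim_times=np.array([t_up]),
                     meta=dict(rmp=rmp, peak=peak, repol_ms=repol_ms,
                               plateau_ms=plateau_ms))


def apd_map_fixture(n: int = 48, base_ms: float = 45.0,
                    gradient_ms: float = 0.0, step_ms: float = 0.0,
                    seed: int = 0) -> np.ndarray:
    """A circular APD80 map with a linear gradient and/or a step region.

    Designed dispersion = gradient + step (plus nothing random), so QC
    behaviour is known by construction.
    """
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (0.48 * n) ** 2
    apd = base_ms + gradient_ms * xx / (n - 1)
    if step_ms:
        region = (xx > 0.6 * n) & (yy > 0.6 * n)
        apd = np.where(region, apd + step_ms, apd)
    return np.where(mask, apd, np.nan)


def grid32(seed: int = 0):
    """A miniature monolayer (32x32, 2 mm disc) for fast tests."""
    return build_monolayer(nx=32, ny=32, dx=0.00625, diameter=0.19,
                           fib_fraction=0.17, variability=(50.0, 150.0),
                           seed=seed)


def make_fixture(kind: str, seed: int = 0, out_dir="."):
    """Generate a named fixture and write it under ``out_dir``.

    Kinds: ``rotor`` (npz movie), ``plane`` (npz movie), ``ap_trace``
    (csv), ``apd_map`` (csv), ``grid32`` (npz grid).  Deterministic for a
    fixed seed; returns the written path.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "rotor":
        path = out_dir / f"rotor_seed{seed}.npz"
        rotor_movie(seed=seed).save(path)
    elif kind == "plane":
        path = out_dir / f"plane_seed{seed}.npz"
        plane_wave_movie().save(path)
    elif kind == "ap_trace":
        path = out_dir / f"ap_trace_seed{seed}.csv"
        synthetic_ap_trace().to_csv(path)
    elif kind == "apd_map":
        path = out_dir / f"apd_map_seed{seed}.csv"
        np.savetxt(path, apd_map_fixture(gradient_ms=10.0), delimiter=",")
    elif kind == "grid32":
        path = out_dir / f"grid32_seed{seed}.npz"
        grid32(seed=seed).save(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
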