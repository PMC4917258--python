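"""Post-processing of tissue recordings.

Activation and APD maps, conduction velocity, spiral-tip trajectories
(isoline-intersection method), dominant period, and wavelength.  All
operations are pure functions of their inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .recording import FrameStack, Recording

ACTIVATION_THRESHOLD = -20.0  # mV, rising
TIP_ISO_LEVEL = -30.0         # mV isoline for tip detection


@dataclasses.dataclass
class ActivationMap:
    """Per-node first-activation times (ms), NaN where never activated."""

    times: np.ndarray
    isochrone_ms: float = 6.0
    t0: float = 0.0


def activation_map(frames: FrameStack,
                   threshold: float = ACTIVATION_THRESHOLD,
                   t0: float = 0.0,
                   isochrone_ms: float = 6.0) -> ActivationMap:
    """First upward threshold crossing per node after ``t0``.

    Crossing times are linearly interpolated between frames.
    """
    sel = frames.times >= t0
    ts = frames.times[sel]
    vs = frames.frames[sel]
    above = vs > threshold
    first = above.argmax(axis=0)          # 0 when never above
    ever = above.any(axis=0)
    ny, nx = vs.shape[1:]
    out = np.full((ny, nx), np.nan)
    jj, ii = np.nonzero(ever)
    for j, i in zip(jj, ii):
        k = first[j, i]
        if k == 0:
            out[j, i] = ts[0]
            continue
        v0, v1 = vs[k - 1, j, i], vs[k, j, i]
        frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
        out[j, i] = ts[k - 1] + frac * (ts[k] - ts[k - 1])
    return ActivationMap(times=out, isochrone_ms=isochrone_ms, t0=t0)


def conduction_velocity(act: ActivationMap | np.ndarray, dx: float,
                        axis: str = "x", margin: int = 20) -> float:
    """Planar CV (cm/s) from an activation map by linear regression.

    Activation time is averaged across the transverse direction and
    regressed against distance along the propagation ``axis``; ``margin``
    nodes at each end (stimulus and boundary regions) are excluded.
    """
    times = act.times if isinstance(act, ActivationMap) else np.asarray(act)
    if axis == "x":
        prof = np.nanmean(times, axis=0)
    else:
        prof = np.nanmean(times, axis=1)
    n = prof.size
    lo, hi = margin, n - margin
    if hi - lo < 3:
        raise ValueError("profile too short for the requested margin")
    x = np.arange(lo, hi) * dx
    y = prof[lo:hi]
    ok = np.isfinite(y)
    slope = np.polyfit(x[ok], y[ok], 1)[0]   # ms/cm
    if slope <= 0:
        raise ValueError("activation profile is not advancing")
    return 1000.0 / slope / 1.0              # cm/s


def cv_from_probes(t1: float, t2: float, distance_cm: float) -> float:
    """CV (cm/s) from two activation times a known distance apart."""
    if t2 <= t1:
        raise ValueError("second probe must activate later")
    return distance_cm / (t2 - t1) * 1000.0


def apd_map(frames: FrameStack, stim_time: float = 0.0,
            repol_fraction: float = 0.8):
    """Per-node APD map from a paced-beat frame stack.

    Returns ``(apd_map, dispersion)``: APD measured per node from the
    maximum-dV/dt frame to the crossing of peak - fraction*(peak - RMP),
    RMP taken just before ``stim_time``; dispersion = max - min over
    finite nodes.
    """
    ts = frames.times
    vs = frames.frames
    i_stim = max(int(np.searchsorted(ts, stim_time)) - 1, 0)
    rmp = vs[i_stim]
    after = ts >= stim_time
    va = vs[after]
    ta = ts[after]
    dv = np.diff(va, axis=0)
    i_up = dv.argmax(axis=0)
    ny, nx = va.shape[1:]
    out = np.full((ny, nx), np.nan)
    peak_all = va.max(axis=0)
    amp = peak_all - rmp
    jj, ii = np.nonzero(np.isfinite(amp) & (amp > 40.0))
    for j, i in zip(jj, ii):
        tr = va[:, j, i]
        k_up = i_up[j, i]
        k_peak = k_up + int(np.argmax(tr[k_up:]))
        level = peak_all[j, i] - repol_fraction * amp[j, i]
        below = tr[k_peak:] <= level
        if not below.any():
            continue
        k = k_peak + int(below.argmax())
        if k == 0:
            continue
        v0, v1 = tr[k - 1], tr[k]
        frac = (v0 - level) / (v0 - v1) if v1 != v0 else 0.0
        t_cross = ta[k - 1] + frac * (ta[k] - ta[k - 1])
        out[j, i] = t_cross - ta[k_up]
    finite = np.isfinite(out)
    dispersion = float(np.nanmax(out) - np.nanmin(out)) if finite.any() \
        else np.nan
    return out, dispersion


@dataclasses.dataclass
class TipTrajectory:
    """Spiral-tip positions over time (grid units) with NaN gaps."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dx: float = 1.0

    def core_size_cm(self) -> float:
        """Maximum pairwise extent of the trajectory (cm)."""
        ok = np.isfinite(self.x)
        if ok.sum() < 2:
            return 0.0
        xs, ys = self.x[ok] * self.dx, self.y[ok] * self.dx
        span_x = xs.max() - xs.min()
        span_y = ys.max() - ys.min()
        return float(np.hypot(span_x, span_y))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t_ms": self.t, "x_mm": self.x * self.dx * 10,
                             "y_mm": self.y * self.dx * 10})


def _contour_intersections(a: np.ndarray, b: np.ndarray):
    """Intersection points of the zero contours of two 2D fields."""
    from skimage import measure

    pts = []
    ca = measure.find_contours(a, 0.0)
    cb = measure.find_contours(b, 0.0)
    if not ca or not cb:
        return pts
    bpts = np.vstack(cb)
    for poly in ca:
        for p in poly[::2]:
            d = np.min(np.sum((bpts - p) ** 2, axis=1))
            if d < 1.0:
                pts.append(p)
    return pts


def tip_trajectory(frames: FrameStack, v_iso: float = TIP_ISO_LEVEL,
                   gap_tolerance: int = 5,
                   max_step: float = 6.0) -> TipTrajectory:
    """Spiral-tip trajectory by the isoline-intersection method.

    The tip in each frame is the intersection of the V = ``v_iso``
    isoline with the dV/dt = 0 contour (dV/dt from consecutive frames).
    Candidate points are linked frame-to-frame by nearest neighbour;
    frames with no tip leave NaN gaps.
    """
    vs = frames.frames
    ts = frames.times
    n = vs.shape[0] - 1
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    last = None
    for k in range(n):
        a = vs[k] - v_iso
        b = vs[k + 1] - vs[k]
        a = np.nan_to_num(a, nan=-1e3)
        b = np.nan_to_num(b, nan=0.0)
        pts = _contour_intersections(a, b)
        if not pts:
            continue
        pts = np.asarray(pts)
        if last is None:
            # prefer the innermost candidate (away from boundaries)
            center = np.array(vs.shape[1:]) / 2.0
            pick = pts[np.argmin(np.sum((pts - center) ** 2, axis=1))]
        else:
            d = np.sqrt(np.sum((pts - last) ** 2, axis=1))
            i = int(np.argmin(d))
            if d[i] > max_step * max(1, gap_tolerance):
                continue
            pick = pts[i]
        ys[k], xs[k] = pick
        last = pick
    return TipTrajectory(t=ts[:n], x=xs, y=ys, dx=frames.dx)


def dominant_period(trace: Recording | np.ndarray, dt: float | None = None,
                    min_period: float = 20.0) -> tuple[float, float]:
    """Dominant period (ms) of a voltage signal and the spectral resolution.

    The trace is detrended, Hann-windowed, and the period is the inverse
    of the power-spectrum peak below the ``min_period`` cut-off frequency.
    Returns ``(period_ms, resolution_ms)`` where the resolution is the
    period difference to the neighbouring frequency bin.
    """
    from scipy import signal as sps

    if isinstance(trace, Recording):
        v = np.asarray(trace.v, float)
        dt = trace.dt
    else:
        v = np.asarray(trace, float)
        if dt is None:
            raise ValueError("dt required for a bare array")
    v = sps.detrend(v)
    w = np.hanning(v.size)
    spec = np.abs(np.fft.rfft(v * w)) ** 2
    freqs = np.fft.rfftfreq(v.size, d=dt)   # 1/ms
    valid = (freqs > 0) & (freqs < 1.0 / min_period)
    if not valid.any():
        raise ValueError("trace too short for spectral analysis")
    idx = np.flatnonzero(valid)[np.argmax(spec[valid])]
    period = 1.0 / freqs[idx]
    res = abs(1.0 / freqs[idx] - 1.0 / freqs[idx + 1])
    return float(period), float(res)


def wavelength(cv_cm_s: float, apd_ms: float) -> float:
    """Wavelength (cm) = CV x APD."""
    return cv_cm_s * apd_ms / 1000.0
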