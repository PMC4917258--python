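"""Time-series containers for simulation output."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass
class Recording:
    """A single-cell (or single-probe) voltage/Ca recording.

    ``t`` in ms; ``v`` in mV; Ca concentrations in mM.  ``stim_times`` holds
    stimulus onset times so analysis can reference beats to their stimulus.
    """

    t: np.ndarray
    v: np.ndarray
    ca_i: np.ndarray | None = None
    ca_nsr: np.ndarray | None = None
    ca_jsr: np.ndarray | None = None
    stim_times: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def window(self, t0: float, t1: float) -> "Recording":
        sel = (self.t >= t0) & (self.t < t1)
        st = None
        if self.stim_times is not None:
            st = self.stim_times[(self.stim_times >= t0)
                                 & (self.stim_times < t1)]
        return Recording(
            t=self.t[sel], v=self.v[sel],
            ca_i=None if self.ca_i is None else self.ca_i[sel],
            ca_nsr=None if self.ca_nsr is None else self.ca_nsr[sel],
            ca_jsr=None if self.ca_jsr is None else self.ca_jsr[sel],
            stim_times=st, meta=dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.t, "V_mV": self.v}
        if self.ca_i is not None:
            cols["Ca_i_mM"] = self.ca_i
        if self.ca_nsr is not None:
            cols["Ca_NSR_mM"] = self.ca_nsr
        if self.ca_jsr is not None:
            cols["Ca_JSR_mM"] = self.ca_jsr
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path) -> "Recording":
        df = pd.read_csv(Path(path))
        return cls(
            t=df["time_ms"].to_numpy(), v=df["V_mV"].to_numpy(),
            ca_i=df["Ca_i_mM"].to_numpy() if "Ca_i_mM" in df else None,
            ca_nsr=df["Ca_NSR_mM"].to_numpy() if "Ca_NSR_mM" in df else None,
            ca_jsr=df["Ca_JSR_mM"].to_numpy() if "Ca_JSR_mM" in df else None)


@dataclasses.dataclass
class FrameStack:
    """Voltage frames of a tissue run at a fixed recording stride.

    ``frames`` has shape (n_frames, ny, nx) with NaN outside the domain
    mask; ``times`` in ms; ``dx`` in cm.
    """

    frames: np.ndarray
    times: np.ndarray
    dx: float
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def stride_ms(self) -> float:
        return float(self.times[1] - self.times[0])

    def save(self, path) -> None:
        np.savez_compressed(
            Path(path), frames=self.frames, times=self.times,
            dx=np.array(self.dx))

    @classmethod
    def load(cls, path) -> "FrameStack":
        with np.load(Path(path)) as z:
            return cls(frames=z["frames"], times=z["times"],
                       dx=float(z["dx"]))
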