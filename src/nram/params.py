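"""Model parameters: container, defaults, and structured-text (YAML) I/O.

The defaults reproduce the published neonatal rat atrial myocyte model.
Printed constants (the 0.16 sustained-current scale, the 0.048925 composite
inward-rectifier prefactor which already contains the 47.5%-of-ventricle
adjustment, the 0.01 K+ leak slope, the I_KACh dose law) are hard numbers
from the model's defining equations.  Constants inherited from the source
ventricular/atrial models (gating time constants, pump/exchanger kinetics,
SR and buffer parameters) are transcriptions of those published models, and
the remaining free magnitudes (maximal conductances, SR flux rates) were
calibrated against the model's published targets: resting potential
-72.0 mV, dV/dt_max 114 mV/ms, amplitude 132.74 mV, APD50/APD80 27/58 ms,
mean Ca_i ~0.36 uM, NSR ~775 uM, JSR ~715 uM, planar CV 22.2 cm/s.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .constants import BLOCK_FIELDS, NBLOCK, NPAR, PARAM_FIELDS


@dataclasses.dataclass
class CellParams:
    """All scalar parameters of the single-cell model.

    Conductances in nS/pF, concentrations in mM (ACh in uM), temperature in
    K, volumes as ratios to the cytosolic volume, fluxes in mM/ms.
    ``block`` maps a current id (see ``constants.BLOCK_FIELDS``) to a block
    fraction in [0, 1] (tertiapin-Q = ``{"i_kach": 1.0}``).
    """

    # maximal conductances and scale factors
    g_na: float = 21.0
    g_cal: float = 15.3
    g_cat: float = 0.15
    g_to: float = 0.015
    g_kur: float = 0.045
    g_kr: float = 0.4
    g_ks: float = 0.004
    k_ksus: float = 0.16          # printed composite scale
    g_k1: float = 0.048925        # printed prefactor (47.5% of NRVM absorbed)
    g_kleak: float = 0.01         # printed linear K+ leak slope
    g_kach: float = 1.9          # scale on the printed I_KACh laws
    g_f: float = 0.003
    g_nab: float = 0.0009
    g_cab: float = 0.0003
    i_nak_max: float = 0.95
    k_ncx: float = 2.6e-5
    d_ncx: float = 1.0e-4
    gamma_ncx: float = 0.5
    km_nai: float = 10.0
    km_ko: float = 1.5
    # milieu (patch-clamp solutions; intracellular Na+/K+ constant in time)
    na_o: float = 140.0
    na_i: float = 8.0
    k_o: float = 5.4
    k_i: float = 140.0
    ca_o: float = 1.8
    ach: float = 1.0              # uM, single-cell dose law
    temperature: float = 295.0    # K (room temperature)
    # capacitance bookkeeping
    cm: float = 1.0               # uF/cm^2: pA/pF == uA/cm^2
    c_cell: float = 1.0           # pF: converts printed pA amplitudes
    # Ca2+ geometry and conversion
    ca_conv: float = 5.0e-5       # mM/ms per pA/pF of Ca-carrying current
    r_nsr: float = 0.03           # V_NSR / V_cyto
    r_jsr: float = 0.03 / 9.0     # V_JSR / V_cyto (JSR = 10% of total SR)
    # SERCA / SR transfer / SR leak
    vmax_up: float = 1.35e-4
    kmf_up: float = 2.5e-4
    kmr_up: float = 1.7
    h_up: float = 1.787
    tau_tr: float = 8.0
    k_leak_sr: float = 2.0e-5
    # RyR
    ko_ca: float = 450.0
    kom: float = 0.2
    ki_ca: float = 0.5
    kim: float = 0.005
    ec50_sr: float = 0.45
    max_sr: float = 15.0
    min_sr: float = 1.0
    ks_rel: float = 16.0
    k_local: float = 0.02         # mM of trigger Ca per pA/pF of Ca influx
    # buffers
    trpn_tot: float = 0.035
    kd_trpn: float = 5.0e-4
    kon_trpn: float = 40.0
    cmdn_tot: float = 0.05
    kd_cmdn: float = 2.38e-3
    kon_cmdn: float = 34.0
    csqn_tot: float = 24.0
    kd_csqn: float = 0.63
    kon_csqn: float = 1.0
    # named modification hooks
    k_temp_na: float = 1.4        # room-temperature slowing of Na+ taus
    tau_d_shift: float = 10.0     # printed +10 ms L-type activation shift
    # drug / intervention model
    block: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in PARAM_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite")
        for name in ("g_na", "g_cal", "g_cat", "g_to", "g_kur", "g_kr",
                     "g_ks", "g_k1", "g_kleak", "g_kach", "g_f", "g_nab",
                     "g_cab", "i_nak_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name!r} must be >= 0")
        for name in ("na_o", "na_i", "k_o", "k_i", "ca_o", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name!r} must be positive")
        jsr_frac = self.r_jsr / (self.r_jsr + self.r_nsr)
        if abs(jsr_frac - 0.1) > 1e-6:
            raise ValueError(
                "JSR must be 10% of the total SR volume "
                f"(got V_JSR/V_SR = {jsr_frac:.4f})")
        for key, frac in self.block.items():
            if key not in BLOCK_FIELDS:
                raise ValueError(f"unknown block target {key!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"block fraction for {key!r} not in [0, 1]")

    # -- packing for the compiled kernels ------------------------------------
    def to_vector(self) -> np.ndarray:
        vec = np.empty(NPAR)
        for i, name in enumerate(PARAM_FIELDS):
            vec[i] = getattr(self, name)
        return vec

    def block_vector(self) -> np.ndarray:
        vec = np.zeros(NBLOCK)
        for key, frac in self.block.items():
            vec[BLOCK_FIELDS.index(key)] = frac
        return vec

    # -- convenience --------------------------------------------------------
    def replace(self, **kwargs) -> "CellParams":
        return dataclasses.replace(self, **kwargs)

    def with_block(self, current_id: str, fraction: float) -> "CellParams":
        new_block = dict(self.block)
        new_block[current_id] = fraction
        return dataclasses.replace(self, block=new_block)

    # -- structured-text round trip ------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block"] = dict(self.block)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "CellParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "CellParams":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)


def default_params() -> CellParams:
    """The bundled paper-default parameter set."""
    return CellParams()
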