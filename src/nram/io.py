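"""Run configuration, manifests, and file I/O helpers.

Configs are YAML with a flat, explicitly validated schema; every run
writes a manifest echoing the resolved configuration and package version.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .params import CellParams


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a simulation run."""

    # numerics (paper defaults)
    dt: float = 0.02                 # ms
    dx: float = 0.00625              # cm
    diff_coef: float = 0.00012       # cm^2/ms
    duration: float = 1000.0         # ms
    record_stride: float = 1.0       # ms between frames
    # model / intervention
    mode: str = "constitutive"       # single_cell|carbachol|constitutive|...
    fb_coupled: bool = True
    gate_integrator: str = "rush_larsen"   # or "euler"
    # grid
    grid_kind: str = "monolayer"     # monolayer|strip|square
    nx: int = 256
    ny: int = 256
    diameter: float = 1.56           # cm
    fib_fraction: float = 0.17
    variability: tuple = (100.0, 100.0)
    seed: int = 0
    # files
    params_file: str | None = None
    grid_file: str | None = None
    output_prefix: str = "run"

    def __post_init__(self):
        for name in ("dt", "dx", "diff_coef", "duration", "record_stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.variability = tuple(self.variability)

    @property
    def rush_larsen(self) -> bool:
        if self.gate_integrator not in ("rush_larsen", "euler"):
            raise ValueError("gate_integrator must be rush_larsen or euler")
        return self.gate_integrator == "rush_larsen"

    def cell_params(self) -> CellParams:
        if self.params_file:
            return CellParams.load(self.params_file)
        return CellParams()

    def build_grid(self):
        from .monolayer import build_monolayer, build_square, build_strip

        if self.grid_file:
            from .monolayer import TissueGrid
            return TissueGrid.load(self.grid_file)
        if self.grid_kind == "monolayer":
            return build_monolayer(
                nx=self.nx, ny=self.ny, dx=self.dx, diameter=self.diameter,
                fib_fraction=self.fib_fraction,
                variability=self.variability, seed=self.seed,
                diff_coef=self.diff_coef)
        if self.grid_kind == "strip":
            return build_strip(nx=self.nx, ny=self.ny, dx=self.dx,
                               seed=self.seed, diff_coef=self.diff_coef)
        if self.grid_kind == "square":
            return build_square(self.nx, dx=self.dx, seed=self.seed,
                                diff_coef=self.diff_coef)
        raise ValueError(f"unknown grid_kind {self.grid_kind!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take the paper defaults; unknown keys are rejected with
    their key paths.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**data)


def write_manifest(path, config: RunConfig, extra: dict | None = None):
    """Write a JSON manifest with the resolved config and code version."""
    from . import __version__

    payload = {"config": config.to_dict(), "version": __version__}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
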