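"""Virtual monolayer construction and quality control.

A monolayer is a circular patch of myocytes on a square lattice (the
culture-dish geometry: a 15.6 mm disc inscribed in a 256 x 256 grid at
dx = 0.00625 cm), with a configurable fraction of randomly placed passive
myofibroblasts and per-myocyte conductance variability: each myocyte draws
19 independent uniform multipliers, one per maximal conductance/flux (the
list is ``constants.MULT_FIELDS``), from [X1/100, X2/100].

Accepted monolayers must show a spatially uniform APD80 map with
dispersion of at most 20 ms at 1 Hz pacing; :func:`qc_monolayer` applies
that rule.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import MULT_FIELDS, NMULT

#: node type codes
OUTSIDE, MYOCYTE, FIBROBLAST = 0, 1, 2


@dataclasses.dataclass
class FibroblastParams:
    """Passive (RC) myofibroblast membrane, per-pF normalized."""

    g_fb: float = 0.03    # nS/pF membrane conductance
    e_fb: float = -49.6   # mV reversal of the passive membrane
    c_fb: float = 6.3     # pF whole-cell capacitance (bookkeeping)


@dataclasses.dataclass
class TissueGrid:
    """A 2D simulation domain (lattice + cell types + heterogeneity).

    ``type_map`` is (ny, nx) with codes OUTSIDE/MYOCYTE/FIBROBLAST;
    ``multipliers`` is (19, n_myocytes) ordered like the flattened myocyte
    nodes (row-major over the masked lattice).
    """

    nx: int
    ny: int
    dx: float
    type_map: np.ndarray
    multipliers: np.ndarray
    diff_coef: float = 0.00012      # cm^2/ms
    g_gap_fb: float = 0.5           # nS/pF myocyte-fibroblast coupling
    fb: FibroblastParams = dataclasses.field(default_factory=FibroblastParams)
    seed: int | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    # -- derived indexing ----------------------------------------------------
    def __post_init__(self):
        self.type_map = np.asarray(self.type_map)
        if self.type_map.shape != (self.ny, self.nx):
            raise ValueError("type_map shape mismatch")
        myo = self.type_map == MYOCYTE
        self._myo_rows, self._myo_cols = np.nonzero(myo)
        n_myo = self._myo_rows.size
        if self.multipliers.shape != (NMULT, n_myo):
            raise ValueError(
                f"multipliers must have shape ({NMULT}, {n_myo})")
        index = -np.ones((self.ny, self.nx), dtype=np.int64)
        index[self._myo_rows, self._myo_cols] = np.arange(n_myo)
        self._myo_index = index

    @property
    def mask(self) -> np.ndarray:
        """Inside-domain mask (myocyte or fibroblast)."""
        return self.type_map != OUTSIDE

    @property
    def n_myocytes(self) -> int:
        return self._myo_rows.size

    @property
    def n_fibroblasts(self) -> int:
        return int((self.type_map == FIBROBLAST).sum())

    @property
    def myo_index(self) -> np.ndarray:
        """(ny, nx) map into the flat myocyte arrays (-1 elsewhere)."""
        return self._myo_index

    def myocyte_coords(self):
        """(rows, cols) of myocyte nodes, in flat-array order."""
        return self._myo_rows, self._myo_cols

    def neighbor_table(self) -> np.ndarray:
        """(4, n_myo) neighbour indices with no-flux mirrors.

        A neighbour that is outside the domain or a fibroblast node maps
        back to the node itself, which implements the zero-flux mirror in
        the 5-point stencil (fibroblasts do not enter diffusion).
        """
        n = self.n_myocytes
        nb = np.empty((4, n), dtype=np.int64)
        shifts = ((0, -1), (0, 1), (-1, 0), (1, 0))
        for a, (dr, dc) in enumerate(shifts):
            rr = self._myo_rows + dr
            cc = self._myo_cols + dc
            valid = ((rr >= 0) & (rr < self.ny) & (cc >= 0) & (cc < self.nx))
            tgt = np.arange(n)
            inside = self._myo_index[rr[valid], cc[valid]]
            sel = np.where(valid)[0]
            good = inside >= 0
            tgt[sel[good]] = inside[good]
            nb[a] = tgt
        return nb

    def fibroblast_links(self):
        """CSR lists (fb_ptr, fb_nbr) of myocyte neighbours per fibroblast."""
        rows, cols = np.nonzero(self.type_map == FIBROBLAST)
        ptr = [0]
        nbr = []
        for r, c in zip(rows, cols):
            for dr, dc in ((0, -1), (0, 1), (-1, 0), (1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < self.ny and 0 <= cc < self.nx:
                    k = self._myo_index[rr, cc]
                    if k >= 0:
                        nbr.append(k)
            ptr.append(len(nbr))
        return (np.asarray(ptr, dtype=np.int64),
                np.asarray(nbr, dtype=np.int64))

    def field_from_flat(self, values: np.ndarray,
                        fill: float = np.nan) -> np.ndarray:
        """Scatter a flat per-myocyte array back onto the (ny, nx) lattice."""
        out = np.full((self.ny, self.nx), fill)
        out[self._myo_rows, self._myo_cols] = values
        return out

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(
            path, type_map=self.type_map, multipliers=self.multipliers,
            dx=self.dx, diff_coef=self.diff_coef, g_gap_fb=self.g_gap_fb,
            seed=-1 if self.seed is None else self.seed)

    @classmethod
    def load(cls, path) -> "TissueGrid":
        with np.load(path) as z:
            tm = z["type_map"]
            seed = int(z["seed"])
            return cls(nx=tm.shape[1], ny=tm.shape[0], dx=float(z["dx"]),
                       type_map=tm, multipliers=z["multipliers"],
                       diff_coef=float(z["diff_coef"]),
                       g_gap_fb=float(z["g_gap_fb"]),
                       seed=None if seed < 0 else seed)


def variability_multipliers(x1: float, x2: float, n_cells: int,
                            seed=None) -> np.ndarray:
    """Draw the (19, n_cells) conductance/flux multipliers.

    ``x1``/``x2`` are percentages: each multiplier is uniform on
    [0.01*x1, 0.01*x2], independently per (cell, quantity) pair.
    """
    if not 0 < x1 <= x2:
        raise ValueError("require 0 < X1 <= X2")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.01 * x1, 0.01 * x2, size=(NMULT, n_cells))


def build_monolayer(nx: int = 256, ny: int = 256, dx: float = 0.00625,
                    diameter: float = 1.56, fib_fraction: float = 0.17,
                    variability=(100.0, 100.0), seed=None,
                    diff_coef: float = 0.00012, g_gap_fb: float = 0.5,
                    ) -> TissueGrid:
    """Build a circular virtual monolayer.

    ``diameter`` in cm (default the 15.6 mm culture dish) must fit in the
    ``nx*dx`` x ``ny*dx`` box.  Exactly ``round(fib_fraction * n_masked)``
    fibroblasts are placed uniformly at random among masked nodes.
    Reproducible for a fixed ``seed``.
    """
    if not 0.0 <= fib_fraction < 1.0:
        raise ValueError("fib_fraction must be in [0, 1)")
    if diameter > min(nx, ny) * dx * (1 + 1e-9):
        raise ValueError("domain diameter exceeds the grid extent")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = diameter / 2.0 / dx
    mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2
    type_map = np.where(mask, MYOCYTE, OUTSIDE).astype(np.int8)
    masked_flat = np.flatnonzero(mask.ravel())
    n_fb = int(round(fib_fraction * masked_flat.size))
    fb_nodes = rng.choice(masked_flat, size=n_fb, replace=False)
    type_map.ravel()[fb_nodes] = FIBROBLAST
    n_myo = int((type_map == MYOCYTE).sum())
    mult = variability_multipliers(variability[0], variability[1], n_myo,
                                   seed=rng)
    return TissueGrid(nx=nx, ny=ny, dx=dx, type_map=type_map,
                      multipliers=mult, diff_coef=diff_coef,
                      g_gap_fb=g_gap_fb, seed=seed,
                      meta=dict(diameter=diameter,
                                fib_fraction=fib_fraction,
                                variability=tuple(variability)))


def build_strip(nx: int, ny: int = 4, dx: float = 0.00625,
                variability=(100.0, 100.0), seed=None,
                diff_coef: float = 0.00012) -> TissueGrid:
    """A rectangular all-myocyte strip (planar-wave and capture runs)."""
    type_map = np.full((ny, nx), MYOCYTE, dtype=np.int8)
    mult = variability_multipliers(variability[0], variability[1], nx * ny,
                                   seed=seed)
    return TissueGrid(nx=nx, ny=ny, dx=dx, type_map=type_map,
                      multipliers=mult, diff_coef=diff_coef, seed=seed)


def build_square(n: int, dx: float = 0.00625, seed=None,
                 diff_coef: float = 0.00012) -> TissueGrid:
    """A homogeneous square domain (spiral-wave characterization)."""
    return build_strip(nx=n, ny=n, dx=dx, seed=seed, diff_coef=diff_coef)


@dataclasses.dataclass
class QCResult:
    accepted: bool
    reason: str
    dispersion: float
    n_domains: int


def qc_monolayer(apd80_map: np.ndarray, max_dispersion: float = 20.0,
                 boundary_margin: int = 2,
                 domain_threshold: float = 10.0) -> QCResult:
    """Accept/reject an APD80 map (NaN outside the domain).

    Rejects when the max-min APD80 spread over interior nodes exceeds
    ``max_dispersion`` ms, or when the map splits into more than one
    contiguous APD domain (regions differing from the map median by more
    than ``domain_threshold`` ms), the operational reading of "non-uniform
    distribution of APD".  ``boundary_margin`` nodes nearest the domain
    edge are excluded as boundary artifacts.
    """
    from scipy import ndimage

    apd = np.asarray(apd80_map, dtype=float)
    valid = np.isfinite(apd)
    if boundary_margin > 0:
        interior = ndimage.binary_erosion(valid, iterations=boundary_margin)
    else:
        interior = valid
    vals = apd[interior]
    if vals.size == 0:
        return QCResult(False, "empty map", np.nan, 0)
    dispersion = float(np.nanmax(vals) - np.nanmin(vals))
    med = float(np.nanmedian(vals))
    outlier = interior & (np.abs(apd - med) > domain_threshold)
    labels, n_domains = ndimage.label(outlier)
    # ignore speckle: count only contiguous regions of >= 9 nodes
    sizes = ndimage.sum(outlier, labels, range(1, n_domains + 1))
    n_big = int((np.asarray(sizes) >= 9).sum())
    if dispersion > max_dispersion:
        return QCResult(False, "dispersion", dispersion, n_big)
    if n_big > 0:
        return QCResult(False, "non-uniform APD distribution",
                        dispersion, n_big)
    return QCResult(True, "", dispersion, n_big)
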