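"""Overlapping-sphere packings: the analytic analogue of aggregate beds.

Rasterized periodic packings of equal spheres (simple cubic, bcc, fcc or
Poisson-random) reproduce the exponential decline of the mean solid-to-void
contact distance with porosity, and its vanishing-porosity intercept set by
the sphere radius — the idealized counterpart of irregular aggregate
packings, where the intercept is set by the aggregate size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .distance_metrics import fit_distance_porosity

__all__ = [
    "PackingModel",
    "rasterize_packing",
    "periodic_contact_distance",
    "distance_porosity_curve",
]

_UNIT_CELLS = {
    "simple_cubic": np.array([[0.0, 0.0, 0.0]]),
    "bcc": np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
    "fcc": np.array([
        [0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5],
    ]),
}


@dataclass
class PackingModel:
    """A periodic packing of equal spheres on a cubic unit cell.

    ``spacing`` is the lattice constant in voxels (= grid resolution of the
    unit cell); for ``lattice="random"``, ``n_random`` Poisson centres are
    drawn per cell with the given ``seed``.
    """

    lattice: str = "simple_cubic"
    spacing: int = 32
    n_random: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice not in (*_UNIT_CELLS, "random"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.spacing < 4:
            raise ValueError("spacing must be >= 4 voxels")

    def centres(self) -> np.ndarray:
        if self.lattice == "random":
            rng = np.random.default_rng(self.seed)
            return rng.uniform(0, 1, size=(self.n_random, 3))
        return _UNIT_CELLS[self.lattice]


def rasterize_packing(m: PackingModel, overlap: float) -> np.ndarray:
    """Solid mask of one unit cell; ``overlap`` is the radius/spacing ratio.

    Spheres of radius ``overlap * spacing`` are drawn around every (periodic)
    lattice centre; at ``overlap = 0.5`` simple-cubic spheres just touch and
    the porosity is 1 − π/6.  A fully solid cell is returned as such (flagged
    zero porosity) rather than raising.
    """
    if overlap <= 0:
        raise ValueError("overlap must be positive")
    n = m.spacing
    r = overlap * n
    g = (np.mgrid[0:n, 0:n, 0:n].astype(np.float64) + 0.5) / n  # cell coords
    solid = np.zeros((n, n, n), dtype=bool)
    for c in m.centres():
        for shift in np.ndindex(3, 3, 3):  # periodic images
            cc = c + np.array(shift) - 1.0
            d2 = ((g - cc[:, None, None, None]) ** 2).sum(axis=0)
            solid |= d2 <= (r / n) ** 2
    return solid


def periodic_contact_distance(solid: np.ndarray) -> float:
    """Mean distance (voxels) from solid voxels to the void, periodic metric.

    The cell is tiled 3x per axis, the exact EDT computed on the tiling and
    the central copy cropped, so distances wrap correctly across the cell
    boundary.
    """
    if not solid.any():
        raise ValueError("empty solid phase")
    void = ~solid
    if not void.any():
        raise ValueError("no void: contact distance undefined")
    tiled = np.tile(~void, (3, 3, 3))
    dt = ndi.distance_transform_edt(tiled)
    n = solid.shape[0]
    core = dt[n:2 * n, n:2 * n, n:2 * n]
    return float(core[solid].mean())


def distance_porosity_curve(
    m: PackingModel,
    overlaps,
    fit: bool = True,
) -> tuple[np.ndarray, tuple[float, float] | None]:
    """(porosity, mean contact distance) along an overlap sweep.

    For each overlap the cell is rasterized and the mean solid-to-void
    contact distance computed; cells whose void vanishes on the grid are
    skipped.  Needs >= 3 valid points.  Optionally returns the exponential
    fit (a, b) of d̄ = a·exp(−b·φ); the intercept ``a`` is the
    vanishing-porosity contact distance, proportional to the sphere radius.
    """
    pts = []
    for o in overlaps:
        solid = rasterize_packing(m, o)
        phi = 1.0 - solid.mean()
        if phi <= 0 or not solid.any():
            continue
        pts.append((phi, periodic_contact_distance(solid)))
    if len(pts) < 3:
        raise ValueError("fewer than 3 overlap values with nonzero void")
    pts = np.asarray(pts)
    params = fit_distance_porosity(pts) if fit else None
    return pts, params
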