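"""Pore-space statistics: porosity profiles, pore sizes, Γ connectivity.

Pore connectivity Γ is the second moment of the pore cluster-size
distribution,

    Γ = (1 / N_v²) Σ_i n_i²,

with N_v the total pore voxel count and n_i the size of cluster i: Γ = 1 when
all pores form one percolating cluster and Γ → 0 as the pore space fragments
into many similar clusters.  Pore sizes use the maximum-inscribed-sphere
(local thickness) construction on the exact Euclidean distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .core_io import ClassCode, LabelVolume, RoiMask, plane_fractions

__all__ = [
    "ClusterStats",
    "PoreSizeDistribution",
    "porosity_profile",
    "local_thickness",
    "pore_size_distribution",
    "gamma_connectivity",
    "connectivity_vs_diameter",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndi.generate_binary_structure(3, 1)


@dataclass
class ClusterStats:
    """Cluster-size inventory of one phase."""

    n_voxels: int          # N_v
    n_clusters: int        # N_c
    sizes: np.ndarray      # n_i, voxels

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        assert self.sizes.sum() == self.n_voxels

    @property
    def gamma(self) -> float:
        """Second moment of the cluster-size distribution, in (0, 1]."""
        return float((self.sizes.astype(np.float64) ** 2).sum() / self.n_voxels**2)


@dataclass
class PoreSizeDistribution:
    """Volume-weighted pore-diameter histogram (diameters in μm)."""

    bin_edges: np.ndarray
    frequency: np.ndarray          # volume fraction per bin
    cumulative: np.ndarray         # monotone, ends at 1
    mean_diameter: float           # volume-weighted mean local thickness, μm


def porosity_profile(
    l: LabelVolume, roi: RoiMask | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-z-plane pore area fraction (connected + enclosed pores together).

    Returns ``(heights_um, fraction_per_plane, global_mean)``; planes with an
    empty ROI carry NaN.  Height increases toward the piston.
    """
    pore = l.pore_mask()
    prof = plane_fractions(pore, roi)
    heights = np.arange(l.shape[0]) * l.voxel_size
    if roi is None:
        mean = float(pore.mean())
    else:
        mean = float(pore[roi.mask].mean()) if roi.mask.any() else float("nan")
    return heights, prof, mean


def local_thickness(
    l: LabelVolume | np.ndarray, max_radii: int = 64
) -> np.ndarray:
    """Pore diameter field by the maximum-inscribed-sphere method (μm).

    Each pore voxel receives the diameter of the largest ball fully contained
    in the pore phase that covers it: with R(c) the exact Euclidean distance
    from a candidate centre c to the solid, the thickness at x is
    ``2·max{R(c) : |x−c| < R(c)} − 1`` voxels (so an isolated pore voxel has
    diameter 1).  Implemented by sweeping candidate radii in descending order
    and painting the union of inscribed balls of each radius; the exact sphere
    centres are the distance-transform ridge.  Radii are the distinct distance
    values, thinned to at most ``max_radii`` levels for large volumes.
    """
    if isinstance(l, LabelVolume):
        pore = l.pore_mask()
        voxel = l.voxel_size
    else:
        pore = np.asarray(l, dtype=bool)
        voxel = 1.0
    thickness = np.zeros(pore.shape, dtype=np.float64)
    if not pore.any():
        return thickness
    dt = ndi.distance_transform_edt(pore)
    radii = np.unique(dt[pore])[::-1]
    if radii.size > max_radii:
        radii = np.unique(np.quantile(radii, np.linspace(0, 1, max_radii)))[::-1]
    for r in radii:
        seeds = dt >= r
        # voxels strictly within r of a seed centre: covered by that ball
        cover = ndi.distance_transform_edt(~seeds) < r
        cover &= pore
        new = cover & (thickness == 0)
        thickness[new] = 2.0 * r - 1.0
    thickness[pore & (thickness == 0)] = 1.0
    return thickness * voxel


def pore_size_distribution(
    thickness: np.ndarray,
    bins: np.ndarray | None = None,
    voxel_size: float = 8.0,
) -> PoreSizeDistribution:
    """Volume-weighted pore-size histogram from a local-thickness field.

    ``thickness`` is in μm (zeros mark non-pore voxels).  Bins default to a
    one-voxel diameter width.  Raises on an empty pore phase.
    """
    vals = np.asarray(thickness, dtype=np.float64)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("empty pore phase: pore-size distribution undefined")
    if bins is None:
        top = np.ceil(vals.max() / voxel_size) * voxel_size
        bins = np.arange(0.0, top + voxel_size, voxel_size)
    freq, edges = np.histogram(vals, bins=bins)
    freq = freq.astype(np.float64) / vals.size
    cum = np.cumsum(freq)
    return PoreSizeDistribution(
        bin_edges=edges, frequency=freq, cumulative=cum,
        mean_diameter=float(vals.mean()),
    )


def gamma_connectivity(
    l: LabelVolume | np.ndarray,
    phase: tuple[ClassCode, ...] | None = None,
    connectivity: int = 26,
) -> ClusterStats:
    """Cluster statistics and Γ of one phase (default: total pore space)."""
    if isinstance(l, LabelVolume):
        phase = phase or (ClassCode.PORE_CONNECTED, ClassCode.PORE_ENCLOSED)
        mask = l.mask(*phase)
    else:
        mask = np.asarray(l, dtype=bool)
    if not mask.any():
        raise ValueError("empty phase: Γ undefined")
    struct = _STRUCT26 if connectivity == 26 else _STRUCT6
    lab, n = ndi.label(mask, structure=struct)
    sizes = np.bincount(lab.ravel())[1:]
    return ClusterStats(n_voxels=int(mask.sum()), n_clusters=int(n), sizes=sizes)


def connectivity_vs_diameter(
    l: LabelVolume,
    thickness: np.ndarray | None = None,
    diameters: np.ndarray | None = None,
    connectivity: int = 26,
) -> list[tuple[float, float | None]]:
    """Γ of the pore subset with local thickness ≥ d, for each threshold d.

    Thresholding the thickness field isolates the larger pores; the collapse
    of Γ(d) under compaction signals loss of the wide transport pathways.
    Returns ``(d, Γ)`` pairs with ``Γ = None`` for empty subsets.
    """
    if thickness is None:
        thickness = local_thickness(l)
    if diameters is None:
        top = thickness.max()
        step = l.voxel_size
        diameters = np.arange(0.0, top + step, step)
    out: list[tuple[float, float | None]] = []
    for d in diameters:
        subset = thickness >= d if d > 0 else thickness > 0
        if not subset.any():
            out.append((float(d), None))
            continue
        out.append((float(d), gamma_connectivity(subset, connectivity=connectivity).gamma))
    return out
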