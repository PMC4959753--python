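"""Digital volume correlation between states of one sample.

The displacement of the coarse garnet grain matrix between two scans is
recovered self-containedly by block matching: volumes are downscaled and
gray-windowed so only the grain matrix carries signal, each block of the
deformed volume is located in the reference by exhaustive normalized
cross-correlation, the integer peak is refined to sub-voxel precision by
quadratic interpolation, low-confidence blocks are in-filled from neighbours,
and the control-point field is smoothed.  Displacements are reported as
material motion (deformed position minus reference position) in micrometres
of the original grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import match_template

from .core_io import VolumeGrid

__all__ = [
    "DisplacementField",
    "preprocess_for_dvc",
    "estimate_displacement",
    "displacement_profile",
]


@dataclass
class DisplacementField:
    """Displacement vectors on a regular coarse grid of control points."""

    grid_points: np.ndarray     # (n, 3) block centres, voxels of the original grid
    vectors: np.ndarray         # (n, 3) (dz, dy, dx), μm
    quality: np.ndarray         # (n,) normalized correlation in [−1, 1]
    grid_shape: tuple[int, int, int]
    voxel_size: float
    block_size: int

    def vectors_grid(self) -> np.ndarray:
        """Vectors reshaped to (3, gz, gy, gx)."""
        return self.vectors.T.reshape(3, *self.grid_shape)


def preprocess_for_dvc(
    v: VolumeGrid, downscale: int = 4, window: tuple[float, float] | None = None
) -> VolumeGrid:
    """Block-mean downscaling plus gray windowing isolating the grain matrix.

    Values below the window go to 0 and the window is stretched to [0, 255],
    so pores and aggregates are black and garnet has maximal contrast.
    """
    if downscale < 1:
        raise ValueError("downscale must be >= 1")
    data = v.data.astype(np.float64)
    if downscale > 1:
        nz, ny, nx = (s // downscale * downscale for s in data.shape)
        data = data[:nz, :ny, :nx]
        data = data.reshape(
            nz // downscale, downscale, ny // downscale, downscale,
            nx // downscale, downscale).mean(axis=(1, 3, 5))
    if window is not None:
        lo, hi = window
        if not hi > lo:
            raise ValueError("empty gray window")
        data = np.clip((data - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return VolumeGrid(data.astype(np.float32), v.voxel_size * downscale)


def _quadratic_refine(corr: np.ndarray, peak: tuple[int, ...]) -> np.ndarray:
    """Per-axis 3-point quadratic sub-voxel refinement of a correlation peak."""
    offset = np.zeros(3)
    for ax in range(3):
        p = list(peak)
        if peak[ax] == 0 or peak[ax] == corr.shape[ax] - 1:
            continue
        p[ax] = peak[ax] - 1
        c_m = corr[tuple(p)]
        p[ax] = peak[ax] + 1
        c_p = corr[tuple(p)]
        c_0 = corr[tuple(peak)]
        denom = c_m - 2 * c_0 + c_p
        if denom < 0:
            offset[ax] = 0.5 * (c_m - c_p) / denom
    return offset


def estimate_displacement(
    reference: VolumeGrid,
    deformed: VolumeGrid,
    block_size: int = 16,
    search_radius: int = 12,
    quality_threshold: float = 0.5,
    smooth_sigma: float = 0.75,
) -> DisplacementField:
    """Block-matching DVC from ``deformed`` onto ``reference``.

    Each ``block_size`` cube of the deformed volume is searched in the
    reference within ``search_radius``; displacement is the material motion
    deformed − reference.  Blocks with correlation below
    ``quality_threshold`` (or without signal) are in-filled by
    inverse-distance weighting of confident neighbours; the control grid is
    then smoothed with a small Gaussian (``smooth_sigma`` in control-point
    spacings) before cubic interpolation by :meth:`interpolate`.
    """
    if reference.shape != deformed.shape:
        raise ValueError("reference and deformed must share shape")
    ref = reference.data.astype(np.float64)
    def_ = deformed.data.astype(np.float64)
    b, s = block_size, search_radius
    grid_shape = tuple(max(1, n // b) for n in ref.shape)
    centres, vecs, quals = [], [], []
    for iz in range(grid_shape[0]):
        for iy in range(grid_shape[1]):
            for ix in range(grid_shape[2]):
                lo = np.array([iz * b, iy * b, ix * b])
                hi = lo + b
                block = def_[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                centres.append(lo + b / 2.0)
                if block.std() < 1e-9:
                    vecs.append(np.full(3, np.nan))
                    quals.append(-1.0)
                    continue
                slo = np.maximum(lo - s, 0)
                shi = np.minimum(hi + s, ref.shape)
                region = ref[slo[0]:shi[0], slo[1]:shi[1], slo[2]:shi[2]]
                if region.std() < 1e-9 or any(
                        rs < bs for rs, bs in zip(region.shape, block.shape)):
                    vecs.append(np.full(3, np.nan))
                    quals.append(-1.0)
                    continue
                corr = match_template(region, block)
                peak = np.unravel_index(np.argmax(corr), corr.shape)
                z0 = lo - slo  # corr index of the zero-shift position
                if any((p == 0 and z != 0) or (p == cs - 1 and z != cs - 1)
                       for p, z, cs in zip(peak, z0, corr.shape) if cs > 1):
                    # best match pinned at the search border away from zero
                    # shift: truncated and unreliable, leave to in-fill
                    vecs.append(np.full(3, np.nan))
                    quals.append(-1.0)
                    continue
                sub = _quadratic_refine(corr, peak)
                # position of the block in the reference
                ref_pos = slo + np.array(peak, dtype=np.float64) + sub
                vecs.append(lo - ref_pos)  # material motion deformed − reference
                quals.append(float(corr[peak]))
    centres = np.asarray(centres)
    vecs = np.asarray(vecs)
    quals = np.asarray(quals)

    good = (quals >= quality_threshold) & ~np.isnan(vecs).any(axis=1)
    if not good.any():
        raise ValueError("no block carries signal: displacement undefined")

    if smooth_sigma > 0 and min(grid_shape) > 1:
        # confidence-weighted smoothing: low-quality blocks carry no weight,
        # so their (soon in-filled) values never contaminate good ones
        w = good.astype(np.float64).reshape(grid_shape)
        ws = ndi.gaussian_filter(w, smooth_sigma, mode="nearest")
        vg = vecs.T.reshape(3, *grid_shape)
        sm = []
        for comp in vg:
            num = ndi.gaussian_filter(np.where(w > 0, comp, 0.0), smooth_sigma,
                                      mode="nearest")
            with np.errstate(invalid="ignore", divide="ignore"):
                sm.append(np.where(ws > 0, num / ws, np.nan))
        vg = np.stack(sm)
        vecs = np.where(good[:, None], vg.reshape(3, -1).T, vecs)

    bad = ~good
    if bad.any():  # inverse-distance in-fill from confident neighbours
        for i in np.flatnonzero(bad):
            d = np.linalg.norm(centres[good] - centres[i], axis=1)
            wgt = 1.0 / np.maximum(d, 1e-9)
            vecs[i] = (wgt[:, None] * vecs[good]).sum(axis=0) / wgt.sum()

    return DisplacementField(
        grid_points=centres,
        vectors=vecs * deformed.voxel_size,
        quality=quals,
        grid_shape=grid_shape,
        voxel_size=deformed.voxel_size,
        block_size=block_size,
    )


def displacement_profile(
    f: DisplacementField, quality_threshold: float = 0.5
) -> np.ndarray:
    """Per-height averages over confident blocks.

    Returns an array of rows ``(height_um, mean_dz_um, mean_lateral_um)``;
    heights without any confident block fall back to all blocks of that
    height (they were in-filled from neighbours).
    """
    heights = np.unique(f.grid_points[:, 0])
    rows = []
    for h in heights:
        sel = f.grid_points[:, 0] == h
        conf = sel & (f.quality >= quality_threshold)
        use = conf if conf.any() else sel
        v = f.vectors[use]
        lateral = np.linalg.norm(v[:, 1:], axis=1).mean()
        rows.append((h * f.voxel_size, v[:, 0].mean(), lateral))
    return np.asarray(rows)
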