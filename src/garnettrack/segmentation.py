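"""Segmentation of microtomography volumes into pores, matrix and garnet.

The chain mirrors the front half of the analysis workflow: non-local-means
denoising, automatic three-class thresholding (multi-level Otsu), tentative
segmentation, removal of partial-volume films by morphological opening of the
matrix class, scale-normalized Laplacian-of-Gaussian blob detection with
hysteresis thresholding for the tracer particles (with coarse grains masked
out), and finally splitting the pore space into interaggregate (connected)
and enclosed components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, threshold_multiotsu
from skimage.morphology import ball
from skimage.restoration import denoise_nl_means

from .core_io import ClassCode, LabelVolume, RoiMask, VolumeGrid

__all__ = [
    "ThresholdPair",
    "BlobDetection",
    "denoise_nlm",
    "estimate_noise_sigma",
    "find_thresholds",
    "segment_tentative",
    "clean_partial_volume",
    "default_scales",
    "detect_particles",
    "identify_grains",
    "finalize_segmentation",
    "classify_pores",
    "segment_volume",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndi.generate_binary_structure(3, 1)

#: default LoG scales (voxels): geometric ladder covering garnet particle
#: radii 2.8-6.3 voxels (45-100 um diameter at 8 um/voxel), r = sigma*sqrt(3)
DEFAULT_SCALES = (1.5, 2.2, 3.2, 4.6, 6.6)


@dataclass(frozen=True)
class ThresholdPair:
    """Gray thresholds separating pore|matrix (t_low) and matrix|garnet (t_high)."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("require t_low < t_high")


@dataclass(frozen=True)
class BlobDetection:
    """One detected particle: centroid (z, y, x voxels), LoG scale and response."""

    centroid: tuple[float, float, float]
    sigma: float
    response: float

    @property
    def radius(self) -> float:
        """Equivalent ball radius in voxels (r = sigma * sqrt(3))."""
        return self.sigma * np.sqrt(3.0)


def estimate_noise_sigma(v: VolumeGrid) -> float:
    """Robust noise estimate: MAD of the discrete Laplacian response.

    For i.i.d. Gaussian noise the 3-D 6-neighbour Laplacian has variance
    42 sigma^2 (coefficients -6 and six 1s), so sigma = 1.4826 MAD / sqrt(42).
    """
    lap = ndi.laplace(v.data.astype(np.float64))
    mad = np.median(np.abs(lap - np.median(lap)))
    return float(1.4826 * mad / np.sqrt(42.0))


def denoise_nlm(
    v: VolumeGrid,
    patch_radius: int = 1,
    search_radius: int = 3,
    h: float | None = None,
) -> VolumeGrid:
    """Non-local-means denoising; ``h`` defaults to 0.8 x estimated noise sigma."""
    if h is None:
        h = 0.8 * estimate_noise_sigma(v)
    if h <= 0:
        raise ValueError("filtering strength h must be > 0")
    sigma = estimate_noise_sigma(v)
    den = denoise_nl_means(
        v.data.astype(np.float64),
        patch_size=2 * patch_radius + 1,
        patch_distance=search_radius,
        h=h,
        sigma=sigma,
        fast_mode=True,
    )
    return VolumeGrid(den.astype(np.float32), v.voxel_size)


def find_thresholds(v: VolumeGrid, roi: RoiMask | None = None) -> ThresholdPair:
    """Automatic three-class thresholds maximizing between-class variance.

    Multi-level Otsu on the (ROI-restricted) histogram.  Raises on degenerate
    histograms (fewer than three distinct gray values), advising manual
    thresholds.
    """
    data = v.data[roi.mask] if roi is not None else v.data.ravel()
    if np.unique(data).size < 3:
        raise ValueError(
            "histogram degenerate (<3 distinct gray values); supply thresholds manually")
    t_low, t_high = threshold_multiotsu(data, classes=3, nbins=256)
    return ThresholdPair(float(t_low), float(t_high))


def segment_tentative(v: VolumeGrid, thresholds: ThresholdPair) -> LabelVolume:
    """Simple three-class thresholding: pore / matrix / tentative garnet.

    Tentative garnet is provisionally stored as ``PARTICLE``; grains are split
    off and unconfirmed voxels dropped by :func:`finalize_segmentation`.
    """
    labels = np.full(v.shape, ClassCode.MATRIX, dtype=np.uint8)
    labels[v.data <= thresholds.t_low] = ClassCode.PORE_CONNECTED
    labels[v.data > thresholds.t_high] = ClassCode.PARTICLE
    return LabelVolume(labels, v.voxel_size, "tentative threshold segmentation")


def clean_partial_volume(
    l: LabelVolume, d_se: int = 5, min_object: int = 27
) -> LabelVolume:
    """Remove partial-volume films from the matrix class.

    The matrix class is opened with a ball structuring element of diameter
    ``d_se`` voxels (must be odd, >= 3); voxels removed by the opening and
    matrix objects smaller than ``min_object`` voxels become ``UNASSIGNED``.
    This deletes the thin spurious matrix films that blur paints around
    bright particles.
    """
    if d_se < 3 or d_se % 2 == 0:
        raise ValueError("d_se must be an odd integer >= 3 (ball diameter)")
    matrix = l.labels == ClassCode.MATRIX
    se = ball((d_se - 1) // 2)
    opened = ndi.binary_opening(matrix, structure=se)
    if min_object > 1:
        lab, n = ndi.label(opened, structure=_STRUCT6)
        if n:
            sizes = np.bincount(lab.ravel())
            small = np.flatnonzero(sizes < min_object)
            small = small[small > 0]
            if small.size:
                opened &= ~np.isin(lab, small)
    out = l.labels.copy()
    out[matrix & ~opened] = ClassCode.UNASSIGNED
    return LabelVolume(out, l.voxel_size, l.provenance + " + partial-volume cleanup")


def default_scales() -> tuple[float, ...]:
    return DEFAULT_SCALES


def _scale_normalized_log(data: np.ndarray, scales) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel max (and argmax scale index) of -sigma^2 LoG over scales."""
    best = np.full(data.shape, -np.inf, dtype=np.float32)
    best_idx = np.zeros(data.shape, dtype=np.int8)
    for i, s in enumerate(scales):
        resp = (-(s**2) * ndi.gaussian_laplace(data, s)).astype(np.float32)
        upd = resp > best
        best[upd] = resp[upd]
        best_idx[upd] = i
    return best, best_idx


def detect_particles(
    v: VolumeGrid,
    scales=DEFAULT_SCALES,
    grain_mask: np.ndarray | RoiMask | None = None,
    t_high_hyst: float | None = None,
    t_low_hyst: float | None = None,
) -> tuple[list[BlobDetection], LabelVolume]:
    """Scale-normalized LoG blob detection with hysteresis thresholding.

    The response ``sigma^2 * (-LoG)`` is maximized per voxel over the scale
    ladder; voxels above ``t_high_hyst`` seed region growth through voxels
    above ``t_low_hyst``.  Defaults are 0.6x / 0.3x the 99.9th percentile of
    the response.  Detections inside ``grain_mask`` (the dilated rind of
    coarse grains) are discarded.  Returns detections and the particle mask.
    """
    scales = tuple(scales)
    if not scales:
        raise ValueError("scale list must be non-empty")
    data = v.data.astype(np.float64)
    best, best_idx = _scale_normalized_log(data, scales)
    gmask = grain_mask.mask if isinstance(grain_mask, RoiMask) else grain_mask
    if t_high_hyst is None or t_low_hyst is None:
        ref = float(np.percentile(best, 99.9))
        t_high_hyst = 0.6 * ref if t_high_hyst is None else t_high_hyst
        t_low_hyst = 0.3 * ref if t_low_hyst is None else t_low_hyst
    if not t_low_hyst < t_high_hyst:
        raise ValueError("require t_low_hyst < t_high_hyst")
    mask = apply_hysteresis_threshold(best, t_low_hyst, t_high_hyst)
    if gmask is not None:
        mask &= ~gmask
    detections: list[BlobDetection] = []
    # one detection per scale-space maximum: adjacent particles grown into a
    # single hysteresis component still yield separate blobs
    peaks = (best == ndi.maximum_filter(best, size=3)) & mask & (best >= t_high_hyst)
    plab, pn = ndi.label(peaks, structure=_STRUCT26)  # merge plateau peaks
    if pn:
        centroids = ndi.center_of_mass(peaks, plab, index=range(1, pn + 1))
        argpos = ndi.maximum_position(best, plab, index=range(1, pn + 1))
        for c, p in zip(centroids, argpos):
            detections.append(BlobDetection(
                centroid=tuple(float(x) for x in c),
                sigma=float(scales[best_idx[p]]),
                response=float(best[p]),
            ))
    part = np.zeros(v.shape, dtype=np.uint8)
    part[mask] = ClassCode.PARTICLE
    part[~mask] = ClassCode.UNASSIGNED
    return detections, LabelVolume(part, v.voxel_size, "LoG particle mask")


def identify_grains(
    tentative: LabelVolume,
    scales=DEFAULT_SCALES,
    d_se: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Split coarse grains out of the tentative garnet class.

    Connected garnet components larger than twice the largest particle volume
    implied by the scale ladder are grains.  Returns ``(grain_labels_mask,
    grain_rind_mask)``; the rind (grains dilated by ``d_se``) is masked out
    during particle detection because grain edges mimic blob responses.
    """
    garnet = tentative.labels == ClassCode.PARTICLE
    rmax = max(scales) * np.sqrt(3.0)
    cutoff = 2.0 * (4.0 / 3.0) * np.pi * rmax**3
    lab, n = ndi.label(garnet, structure=_STRUCT26)
    grain = np.zeros(garnet.shape, dtype=bool)
    if n:
        sizes = np.bincount(lab.ravel())
        big = np.flatnonzero(sizes > cutoff)
        big = big[big > 0]
        if big.size:
            grain = np.isin(lab, big)
    rind = ndi.binary_dilation(grain, structure=ball((d_se - 1) // 2)) if grain.any() else grain
    return grain, rind


def finalize_segmentation(
    tentative: LabelVolume,
    particle_mask: LabelVolume | np.ndarray,
    grain_labels: np.ndarray | None = None,
) -> LabelVolume:
    """Assemble the final six-class volume.

    Tentative garnet components are kept as ``PARTICLE`` where the LoG
    hysteresis mask confirms them (the LoG result overwrites the tentative
    garnet class, whose thresholded extent defines the particle boundary);
    unconfirmed garnet voxels become ``UNASSIGNED`` and grains overwrite
    everything.
    """
    pmask = particle_mask.labels == ClassCode.PARTICLE \
        if isinstance(particle_mask, LabelVolume) else np.asarray(particle_mask, dtype=bool)
    if pmask.shape != tentative.shape:
        raise ValueError("particle mask shape mismatch")
    if grain_labels is not None and grain_labels.shape != tentative.shape:
        raise ValueError("grain mask shape mismatch")
    out = tentative.labels.copy()
    garnet = out == ClassCode.PARTICLE
    if grain_labels is not None:
        garnet &= ~np.asarray(grain_labels, dtype=bool)
    lab, n = ndi.label(garnet, structure=_STRUCT26)
    confirmed = np.zeros_like(garnet)
    if n:
        supported = np.unique(lab[pmask & garnet])
        supported = supported[supported > 0]
        confirmed = np.isin(lab, supported)
    out[garnet & ~confirmed] = ClassCode.UNASSIGNED
    out[confirmed] = ClassCode.PARTICLE
    if grain_labels is not None:
        out[np.asarray(grain_labels, dtype=bool)] = ClassCode.GRAIN
    return LabelVolume(out, tentative.voxel_size, tentative.provenance + " + finalized")


def classify_pores(
    l: LabelVolume,
    connectivity: int = 26,
    roi: RoiMask | None = None,
) -> LabelVolume:
    """Label pore components as interaggregate (connected) vs enclosed.

    Components touching the volume boundary (or, with an ROI, reaching
    outside it) are the interaggregate pore space; all others are enclosed
    in aggregates.  Pore-phase connectivity defaults to 26-neighbourhood.
    """
    struct = _STRUCT26 if connectivity == 26 else _STRUCT6
    pore = l.pore_mask()
    out = l.labels.copy()
    lab, n = ndi.label(pore, structure=struct)
    if n == 0:
        return LabelVolume(out, l.voxel_size, l.provenance + " + pores classified")
    exterior = np.zeros(pore.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            exterior[tuple(sl)] = True
    if roi is not None:
        exterior |= ndi.binary_dilation(~roi.mask, structure=struct)
    touching = np.unique(lab[exterior & pore])
    touching = touching[touching > 0]
    conn = np.isin(lab, touching)
    out[pore & conn] = ClassCode.PORE_CONNECTED
    out[pore & ~conn] = ClassCode.PORE_ENCLOSED
    return LabelVolume(out, l.voxel_size, l.provenance + " + pores classified")


def segment_volume(
    v: VolumeGrid,
    roi: RoiMask | None = None,
    denoise: bool = True,
    d_se: int = 5,
    min_object: int = 27,
    scales=DEFAULT_SCALES,
    t_high_hyst: float | None = None,
    t_low_hyst: float | None = None,
    thresholds: ThresholdPair | None = None,
) -> tuple[LabelVolume, dict]:
    """Run the full segmentation chain; returns labels and a metadata dict."""
    work = denoise_nlm(v) if denoise else v
    if thresholds is None:
        thresholds = find_thresholds(work, roi)
    tentative = segment_tentative(work, thresholds)
    grain, rind = identify_grains(tentative, scales=scales, d_se=d_se)
    cleaned = clean_partial_volume(tentative, d_se=d_se, min_object=min_object)
    detections, pmask = detect_particles(
        work, scales=scales, grain_mask=rind,
        t_high_hyst=t_high_hyst, t_low_hyst=t_low_hyst)
    final = finalize_segmentation(cleaned, pmask, grain)
    final = classify_pores(final, roi=roi)
    meta = {
        "t_low": thresholds.t_low,
        "t_high": thresholds.t_high,
        "n_detections": len(detections),
        "detections": [
            {"centroid": d.centroid, "sigma": d.sigma,
             "radius_vox": d.radius, "response": d.response}
            for d in detections
        ],
        "class_counts": final.counts(),
    }
    return final, meta
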