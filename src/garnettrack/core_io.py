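"""Volume containers, standard-format I/O and region-of-interest masks.

The whole package works on isotropic 3-D volumes in ``(z, y, x)`` axis order,
with *z* the compaction axis pointing from the bottom of the sample toward the
piston.  Gray volumes are plain scalar fields (8-bit convention, values in
[0, 255]); segmented volumes are categorical fields over :class:`ClassCode`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "ClassCode",
    "VolumeGrid",
    "LabelVolume",
    "RoiMask",
    "LABEL_TO_DISK",
    "DISK_TO_LABEL",
    "read_volume",
    "write_volume",
    "make_cylindrical_roi",
    "rescale_to_8bit",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


class ClassCode(IntEnum):
    """Segmentation classes of the final label volume.

    ``PORE_CONNECTED`` is the interaggregate pore space (connected to the
    sample exterior), ``PORE_ENCLOSED`` the occluded pores fully surrounded
    by solid.  Together they form the total resolved pore space.  ``PARTICLE``
    is the fine garnet tracer (45-100 um), ``GRAIN`` the coarse garnet marker
    grains (0.5-1.2 mm).  ``UNASSIGNED`` collects removed partial-volume and
    unconfirmed high-attenuation voxels.
    """

    PORE_CONNECTED = 0
    PORE_ENCLOSED = 1
    MATRIX = 2
    PARTICLE = 3
    GRAIN = 4
    UNASSIGNED = 5


#: on-disk 8-bit encoding (human-inspectable in any viewer)
LABEL_TO_DISK = {
    ClassCode.PORE_CONNECTED: 0,
    ClassCode.PORE_ENCLOSED: 50,
    ClassCode.MATRIX: 100,
    ClassCode.UNASSIGNED: 150,
    ClassCode.PARTICLE: 200,
    ClassCode.GRAIN: 250,
}
DISK_TO_LABEL = {v: k for k, v in LABEL_TO_DISK.items()}

PORE_CODES = (ClassCode.PORE_CONNECTED, ClassCode.PORE_ENCLOSED)


@dataclass
class VolumeGrid:
    """A 3-D scalar field with an isotropic voxel size.

    Parameters
    ----------
    data
        3-D array in ``(z, y, x)`` order.
    voxel_size
        Edge length of a voxel in micrometres (the case study scans at 8 um).
    """

    data: np.ndarray
    voxel_size: float = 8.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3-D with all dimensions >= 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3-D categorical field over :class:`ClassCode`."""

    labels: np.ndarray
    voxel_size: float = 8.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        valid = set(int(c) for c in ClassCode)
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown class codes: {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *codes: ClassCode) -> np.ndarray:
        """Boolean mask of voxels belonging to any of ``codes``."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in codes:
            out |= self.labels == int(c)
        return out

    def pore_mask(self) -> np.ndarray:
        return self.mask(*PORE_CODES)

    def counts(self) -> dict[str, int]:
        """Voxel count per class (classes partition the volume)."""
        bc = np.bincount(self.labels.ravel(), minlength=len(ClassCode))
        return {c.name: int(bc[int(c)]) for c in ClassCode}


@dataclass
class RoiMask:
    """Boolean region-of-interest mask plus a geometry descriptor.

    The samples of the case study are cylindrical syringes (inner diameter
    12.5 mm); analyses restrict to an axis-aligned cylinder to avoid the
    container wall.
    """

    mask: np.ndarray
    geometry: dict = field(default_factory=lambda: {"kind": "full"})

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")


def make_cylindrical_roi(v: VolumeGrid | LabelVolume, radius_fraction: float = 1.0) -> RoiMask:
    """Axis-aligned cylindrical ROI inscribed in the (y, x) cross-section.

    ``radius_fraction`` scales the inscribed radius; the mask spans the full
    z extent.  Raises ``ValueError`` outside ``(0, 1]`` or if the mask would
    be empty.
    """
    if not 0 < radius_fraction <= 1:
        raise ValueError("radius_fraction must be in (0, 1]")
    nz, ny, nx = v.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = radius_fraction * min(ny, nx) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    if not disk.any():
        raise ValueError("radius_fraction too small: empty ROI")
    mask = np.broadcast_to(disk, (nz, ny, nx)).copy()
    return RoiMask(mask, {"kind": "cylinder", "center": (cy, cx), "radius": radius})


def rescale_to_8bit(data: np.ndarray) -> np.ndarray:
    """Linearly map an arbitrary-range gray volume onto [0, 255] float32."""
    data = np.asarray(data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros(data.shape, dtype=np.float32)
    return ((data - lo) * (255.0 / (hi - lo))).astype(np.float32)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_tiff(path: Path) -> np.ndarray:
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FormatError(f"no TIFF slices found in {path}")
        arrs = [tifffile.imread(str(p)) for p in slices]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent slice dimensions: {sorted(shapes)}")
        if arrs[0].ndim != 2:
            raise FormatError("each slice file must be a single 2-D image")
        return np.stack(arrs, axis=0)
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2-D/3-D TIFF, got ndim={data.ndim}")
    return data


def read_volume(
    path: str | Path,
    format: str | None = None,
    voxel_size: float | None = None,
    as_labels: bool = False,
) -> VolumeGrid | LabelVolume:
    """Read a gray or label volume from a TIFF stack or an MHD/raw pair.

    ``format`` is ``"tiff_stack"`` or ``"mhd_raw"``; if omitted it is guessed
    from the suffix (a directory is treated as a one-file-per-slice stack).
    ``voxel_size`` overrides file metadata; TIFF carries it in a JSON sidecar
    written by :func:`write_volume` (falls back to 8 um).
    """
    path = Path(path)
    if format is None:
        if path.suffix.lower() == ".mhd":
            format = "mhd_raw"
        elif path.is_dir() or path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff_stack"
        else:
            raise ValueError(f"cannot guess format of {path}")
    if format == "tiff_stack":
        data = _read_tiff(path)
        meta_path = path.with_suffix(path.suffix + ".json") if path.suffix else path / "meta.json"
        vs = voxel_size
        if vs is None and meta_path.exists():
            vs = json.loads(meta_path.read_text()).get("voxel_size_um")
        vs = 8.0 if vs is None else vs
    elif format == "mhd_raw":
        if not path.exists():
            raise FormatError(f"missing file: {path}")
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        vs = voxel_size if voxel_size is not None else float(img.GetSpacing()[0])
    else:
        raise ValueError(f"unknown format {format!r}")
    if as_labels:
        labels = np.vectorize(lambda v: int(DISK_TO_LABEL.get(int(v), ClassCode.UNASSIGNED)),
                              otypes=[np.uint8])(data)
        return LabelVolume(labels, voxel_size=vs, provenance=f"read from {path}")
    return VolumeGrid(data, voxel_size=vs)


def write_volume(v: VolumeGrid | LabelVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume losslessly.

    Gray volumes keep their dtype; label volumes are written 8-bit using the
    documented :data:`LABEL_TO_DISK` map.  For TIFF a small JSON sidecar
    records the voxel size.
    """
    path = Path(path)
    if format is None:
        format = "mhd_raw" if path.suffix.lower() == ".mhd" else "tiff_stack"
    if isinstance(v, LabelVolume):
        lut = np.zeros(len(ClassCode), dtype=np.uint8)
        for code, disk in LABEL_TO_DISK.items():
            lut[int(code)] = disk
        data = lut[v.labels]
    else:
        data = v.data
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tiff_stack":
        tifffile.imwrite(str(path), data)
        sidecar = {"voxel_size_um": v.voxel_size, "axis_order": "zyx"}
        if isinstance(v, LabelVolume):
            sidecar["label_map"] = {c.name: d for c, d in LABEL_TO_DISK.items()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    elif format == "mhd_raw":
        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        img.SetSpacing((v.voxel_size,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def plane_fractions(mask3d: np.ndarray, roi: RoiMask | None = None) -> np.ndarray:
    """Per-z-plane true-fraction of ``mask3d`` restricted to the ROI.

    Planes with an empty ROI yield NaN (undefined, not zero).
    """
    mask3d = np.asarray(mask3d, dtype=bool)
    if roi is None:
        return mask3d.mean(axis=(1, 2))
    hits = (mask3d & roi.mask).sum(axis=(1, 2)).astype(float)
    area = roi.mask.sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = hits / area
    out[area == 0] = np.nan
    return out
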