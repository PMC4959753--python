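"""Seeded synthetic phantoms of garnet-labeled aggregate packings.

The generator emulates the laboratory system end to end so the image-analysis
pipeline can be exercised without scan data: sieved soil aggregates (convex
bumpy spheres) are deposited under gravity into a column, their surfaces are
coated with small high-attenuation tracer particles plus a few coarse marker
grains, the packing can be uniaxially compacted with a depth-dependent strain,
and structure turnover (new channels, micro-cracks, pore refilling) can be
applied repeatedly.  A simple imaging model (class gray levels, Gaussian
partial-volume blur, additive noise) renders ground-truth labels to gray data.

All randomness flows from ``PhantomSpec.seed``; every operation is
deterministic given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .core_io import ClassCode, LabelVolume, VolumeGrid

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_packing",
    "coat_with_particles",
    "compact",
    "apply_turnover",
    "render_grayscale",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
SOLID_CODES = (ClassCode.MATRIX, ClassCode.PARTICLE, ClassCode.GRAIN)


class GenerationError(RuntimeError):
    """Raised when a phantom request cannot be satisfied."""


@dataclass
class PhantomSpec:
    """Parameters of the synthetic experiment.

    Defaults emulate the case study at desk scale: a 192 cube at 8 um/voxel,
    aggregate radii 8-16 voxels (geometric similarity to the 0.5-2 mm sieved
    aggregates is traded for runtime; lengths are always reported as voxels
    times ``voxel_size``), an initial interaggregate porosity of 0.30, tracer
    particle radii 3-6 voxels (the 45-100 um garnet diameter range at 8 um),
    and a few coarse marker grains.
    """

    shape: tuple[int, int, int] = (192, 192, 192)
    voxel_size: float = 8.0
    aggregate_radius_range: tuple[float, float] = (8.0, 16.0)
    target_porosity: float = 0.30
    coat_thickness: float = 1.0
    particle_radius_range: tuple[float, float] = (3.0, 6.0)
    coat_coverage: float = 0.2
    max_particles: int | None = None
    detach_fraction: float = 0.0
    n_grains: int = 2
    grain_radius_range: tuple[float, float] = (10.0, 16.0)
    pore_mean: float = 40.0
    matrix_mean: float = 130.0
    particle_mean: float = 220.0
    grain_mean: float = 235.0
    blur_sigma: float = 1.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pore_mean < self.matrix_mean < self.particle_mean <= self.grain_mean):
            raise ValueError("gray levels must satisfy pore < matrix < particle <= grain")
        if self.aggregate_radius_range[0] < 1 or self.particle_radius_range[0] < 1:
            raise ValueError("radii must be >= 1 voxel")
        if not 0 <= self.coat_coverage <= 1:
            raise ValueError("coat_coverage must be in [0, 1]")
        if not 0 <= self.detach_fraction <= 1:
            raise ValueError("detach_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth accompanying a phantom volume (the test oracle)."""

    labels: LabelVolume
    spec: PhantomSpec
    particles: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    grains: list[tuple[float, float, float]] = field(default_factory=list)
    displacement: np.ndarray | None = None  # (3, nz, ny, nx): (dz, dy, dx), voxels
    surface_height: int | None = None  # material top after compaction (voxels)
    n_turnover_rounds: int = 0

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            labels=LabelVolume(self.labels.labels.copy(), self.labels.voxel_size,
                               self.labels.provenance),
            spec=self.spec,
            particles=list(self.particles),
            grains=list(self.grains),
            displacement=None if self.displacement is None else self.displacement.copy(),
            surface_height=self.surface_height,
            n_turnover_rounds=self.n_turnover_rounds,
        )


def _rng(spec: PhantomSpec, *stage: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, *stage])


def _classify_pores_truth(labels: np.ndarray) -> np.ndarray:
    """Split pore voxels into boundary-connected vs enclosed (26-connectivity)."""
    pore = (labels == ClassCode.PORE_CONNECTED) | (labels == ClassCode.PORE_ENCLOSED)
    lab, n = ndi.label(pore, structure=_STRUCT26)
    if n == 0:
        return labels
    border = np.zeros(lab.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            border[tuple(sl)] = True
    touching = np.unique(lab[border & pore])
    touching = touching[touching > 0]
    conn = np.isin(lab, touching)
    out = labels.copy()
    out[pore & conn] = ClassCode.PORE_CONNECTED
    out[pore & ~conn] = ClassCode.PORE_ENCLOSED
    return out


# ---------------------------------------------------------------------------
# aggregate shapes & ballistic deposition
# ---------------------------------------------------------------------------

def _bumpy_sphere(radius: float, rng: np.random.Generator,
                  eps: float = 0.15, n_lobes: int = 4) -> np.ndarray:
    """Boolean block of a sphere with smooth low-order radial lobes.

    The perturbation keeps the shape convex-ish at ``eps`` ~ 0.15, emulating
    rounded sieved aggregates rather than ideal spheres.
    """
    dirs = rng.normal(size=(n_lobes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(-eps, eps, size=n_lobes) * radius
    m = int(np.ceil(radius * (1 + eps) + 1))
    g = np.mgrid[-m:m + 1, -m:m + 1, -m:m + 1].astype(np.float64)
    dist = np.sqrt((g**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = g / dist
    nhat[:, m, m, m] = 0.0
    rloc = np.full(dist.shape, radius)
    kappa = 4.0
    for v, a in zip(dirs, amps):
        cosang = np.tensordot(v, nhat, axes=(0, 0))
        rloc = rloc + a * np.exp(kappa * (cosang - 1.0))
    return dist <= rloc


def _ball_offsets(radius: float) -> np.ndarray:
    m = int(np.floor(radius))
    g = np.mgrid[-m:m + 1, -m:m + 1, -m:m + 1]
    inside = (g**2).sum(axis=0) <= radius**2
    return np.argwhere(inside) - m


def _deposit(spec: PhantomSpec, overlap_frac: float,
             grain_slots: Sequence[int]) -> tuple[np.ndarray, np.ndarray, list]:
    """Ballistic deposition of bumpy spheres (and grains) onto a height map.

    Each deposit first rests on the highest point of its footprint, then
    sinks until its voxel overlap with the existing bed reaches
    ``overlap_frac`` of its volume (moist aggregates interpenetrate when
    packed); the lateral boundary is periodic so the bed stays uniform.
    Returns (matrix_mask, grain_mask, grain_centroids).
    """
    nz, ny, nx = spec.shape
    rng = _rng(spec, 0)
    solid = np.zeros(spec.shape, dtype=bool)
    grain_mask = np.zeros(spec.shape, dtype=bool)
    height = np.zeros((ny, nx), dtype=np.float64)
    grain_centroids: list[tuple[float, float, float]] = []
    i = 0
    max_deposits = 50 * nz * ny * nx // max(1, int(spec.aggregate_radius_range[0]) ** 3)

    def _overlap(block: np.ndarray, zci: int, yy: np.ndarray, xx: np.ndarray) -> float:
        m = block.shape[0] // 2
        dz = np.arange(-m, m + 1) + zci
        keep = (dz >= 0) & (dz < nz)
        if not keep.any():
            return 1.0
        sub = block[keep]
        hit = (solid[np.ix_(dz[keep], yy, xx)] & sub).sum()
        below = block[~keep].sum()  # voxels clipped by the floor count as overlap
        return (hit + below) / block.sum()

    while height.min() < nz and i < max_deposits:
        is_grain = i in grain_slots
        if is_grain:
            r = rng.uniform(*spec.grain_radius_range)
            block = _bumpy_sphere(r, rng, eps=0.05)
        else:
            r = rng.uniform(*spec.aggregate_radius_range)
            block = _bumpy_sphere(r, rng)
        i += 1
        m = block.shape[0] // 2
        # footprint: per (dy,dx) column, lowest and highest solid offset
        any_col = block.any(axis=0)
        lo = np.where(any_col, block.argmax(axis=0), 0) - m
        hi = np.where(any_col, block.shape[0] - 1 - block[::-1].argmax(axis=0), 0) - m
        y0 = int(rng.integers(0, ny))
        x0 = int(rng.integers(0, nx))
        yy = (np.arange(-m, m + 1) + y0) % ny  # periodic laterally: uniform bed
        xx = (np.arange(-m, m + 1) + x0) % nx
        hcols = height[np.ix_(yy, xx)]
        z_rest = int(round((hcols - lo)[any_col].max()))
        z_floor = int(-lo[any_col].min())
        zci = max(z_rest, z_floor)
        if overlap_frac > 0 and zci > z_floor:
            # sink: lowest z whose bed overlap stays within overlap_frac
            lo_z, hi_z = z_floor, zci
            while lo_z < hi_z:
                mid = (lo_z + hi_z) // 2
                if _overlap(block, mid, yy, xx) <= overlap_frac:
                    hi_z = mid
                else:
                    lo_z = mid + 1
            zci = hi_z
        # stamp (crop to z extent)
        dz = np.arange(-m, m + 1) + zci
        keep = (dz >= 0) & (dz < nz)
        if keep.any():
            sub = block[keep]
            tgt = solid[np.ix_(dz[keep], yy, xx)]
            solid[np.ix_(dz[keep], yy, xx)] = tgt | sub
            if is_grain:
                g = grain_mask[np.ix_(dz[keep], yy, xx)]
                grain_mask[np.ix_(dz[keep], yy, xx)] = g | sub
                grain_centroids.append((float(zci), float(y0), float(x0)))
        newh = np.where(any_col, zci + hi + 1.0, -np.inf)
        height[np.ix_(yy, xx)] = np.maximum(hcols, newh)
    matrix = solid & ~grain_mask
    return matrix, grain_mask, grain_centroids


def generate_packing(spec: PhantomSpec) -> tuple[VolumeGrid, GroundTruth]:
    """Generate a loose aggregate packing at the target porosity.

    Aggregates are dropped sequentially along -z onto the bed; the overlap
    depth is calibrated by bisection (re-running the deterministic deposition)
    until the measured porosity is within +-0.03 of ``target_porosity``.
    Raises :class:`GenerationError` when the target is unreachable.
    """
    if spec.target_porosity >= 1.0:
        labels = np.full(spec.shape, ClassCode.PORE_CONNECTED, dtype=np.uint8)
        truth = GroundTruth(LabelVolume(labels, spec.voxel_size, "phantom: empty packing"), spec)
        return render_grayscale(truth, spec), truth

    grain_slots: set[int] = set()
    if spec.n_grains > 0:
        slot_rng = _rng(spec, 7)
        # spread grains over the early-to-mid deposition sequence
        n_est = max(spec.n_grains + 1,
                    int(np.prod(spec.shape) / (4.2 * spec.aggregate_radius_range[0] ** 3)))
        grain_slots = set(slot_rng.choice(n_est, size=spec.n_grains, replace=False).tolist())

    lo_a, hi_a = 0.0, 0.85  # overlap fraction bracket; porosity decreasing in it
    best = None
    for it in range(10):
        alpha = 0.0 if it == 0 else (lo_a + hi_a) / 2
        matrix, grains, gcent = _deposit(spec, alpha, grain_slots)
        phi = 1.0 - (matrix | grains).mean()
        if best is None or abs(phi - spec.target_porosity) < abs(best[0] - spec.target_porosity):
            best = (phi, matrix, grains, gcent)
        if abs(phi - spec.target_porosity) <= 0.02:
            break
        if it == 0 and phi < spec.target_porosity - 0.03:
            raise GenerationError(
                f"target porosity {spec.target_porosity} unreachable: loosest packing "
                f"already at {phi:.3f}; use smaller aggregates or a higher target")
        if phi > spec.target_porosity:
            lo_a = alpha  # too loose -> allow deeper interpenetration
        else:
            hi_a = alpha
    phi, matrix, grains, gcent = best
    if abs(phi - spec.target_porosity) > 0.03:
        raise GenerationError(
            f"porosity calibration failed: reached {phi:.3f} for target {spec.target_porosity}")

    labels = np.full(spec.shape, ClassCode.PORE_CONNECTED, dtype=np.uint8)
    labels[matrix] = ClassCode.MATRIX
    labels[grains] = ClassCode.GRAIN
    labels = _classify_pores_truth(labels)
    truth = GroundTruth(
        LabelVolume(labels, spec.voxel_size, "phantom: packing"),
        spec, grains=gcent,
    )
    return render_grayscale(truth, spec), truth


# ---------------------------------------------------------------------------
# particle coating
# ---------------------------------------------------------------------------

def coat_with_particles(truth: GroundTruth, spec: PhantomSpec | None = None) -> GroundTruth:
    """Coat aggregate surfaces facing the connected pore space with particles.

    A ``coat_coverage`` fraction of eligible surface voxels seeds particle
    balls (greedy, non-overlapping), each straddling the matrix/pore
    interface so its contact distance to the interaggregate pores is <= 1
    voxel.  A ``detach_fraction`` of the particles is instead dropped free
    into wide pore throats, with no matrix contact (emulating particles shaken
    loose during sample handling).
    """
    spec = spec or truth.spec
    rng = _rng(spec, 1)
    out = truth.copy()
    labels = out.labels.labels
    pore_conn = labels == ClassCode.PORE_CONNECTED
    matrix = labels == ClassCode.MATRIX

    # matrix voxels with a 6-neighbour in the connected pore space
    pore_dil = ndi.binary_dilation(pore_conn, structure=ndi.generate_binary_structure(3, 1))
    surface = matrix & pore_dil
    surf_idx = np.argwhere(surface)
    if surf_idx.size == 0 or spec.coat_coverage == 0:
        return out

    n_target = int(round(spec.coat_coverage * len(surf_idx)))
    if spec.max_particles is not None:
        n_target = min(n_target, spec.max_particles)
    order = rng.permutation(len(surf_idx))

    # free pore locations wide enough for a detached particle
    pore_depth = ndi.distance_transform_edt(pore_conn)

    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    particles: list[tuple[tuple[float, float, float], float]] = []
    shape = np.array(labels.shape)
    n_detach = int(round(spec.detach_fraction * n_target))

    def _try_place(center: np.ndarray, r: float) -> bool:
        if placed_centers:
            d = np.linalg.norm(np.array(placed_centers) - center, axis=1)
            if (d < np.array(placed_radii) + r + 1).any():
                return False
        offs = _ball_offsets(r)
        pts = center.astype(int) + offs
        ok = (pts >= 0).all(axis=1) & (pts < shape).all(axis=1)
        pts = pts[ok]
        vals = labels[pts[:, 0], pts[:, 1], pts[:, 2]]
        if np.isin(vals, (ClassCode.PARTICLE, ClassCode.GRAIN)).any():
            return False
        labels[pts[:, 0], pts[:, 1], pts[:, 2]] = ClassCode.PARTICLE
        placed_centers.append(center.astype(float))
        placed_radii.append(r)
        particles.append((tuple(center.astype(float)), float(r)))
        return True

    # detached particles: centers deep enough in the pore space
    if n_detach > 0:
        for _ in range(n_detach):
            r = rng.uniform(*spec.particle_radius_range)
            cand = np.argwhere(pore_depth > r + 1.5)
            if len(cand) == 0:
                break
            for _attempt in range(50):
                c = cand[rng.integers(len(cand))]
                if _try_place(c.astype(float), r):
                    break

    n_attached = n_target - len(particles)
    struct6 = ndi.generate_binary_structure(3, 1)
    for j in order:
        if len(particles) >= n_detach + n_attached or len(particles) >= n_target:
            break
        s = surf_idx[j].astype(float)
        r = rng.uniform(*spec.particle_radius_range)
        # outward normal: mean direction of connected-pore 6-neighbours
        nvec = np.zeros(3)
        for off in np.argwhere(struct6) - 1:
            p = (s + off).astype(int)
            if (p >= 0).all() and (p < shape).all() and pore_conn[tuple(p)]:
                nvec += off
        norm = np.linalg.norm(nvec)
        if norm == 0:
            continue
        nvec /= norm
        # mostly proud of the surface: tangent-ish contact, pore side
        center = np.round(s + nvec * max(spec.coat_thickness, 0.8 * r))
        if not ((center >= 0).all() and (center < shape).all()):
            continue
        _try_place(center, r)

    out.labels.labels = _classify_pores_truth(labels)
    out.labels.provenance += " + coated"
    out.particles = particles
    return out


# ---------------------------------------------------------------------------
# compaction
# ---------------------------------------------------------------------------

def compact(
    v: VolumeGrid,
    truth: GroundTruth,
    surface_strain: float,
    profile: str = "uniform",
) -> tuple[VolumeGrid, GroundTruth]:
    """Uniaxially compact the phantom by closing pore space column-wise.

    Material voxels are advected along -z; per column, solid voxels keep unit
    spacing while pore voxels shrink by a depth-dependent closure factor, so
    solid mass is conserved by construction and porosity strictly decreases.
    ``profile="uniform"`` applies a uniform strain (displacement linear in
    height, new porosity 1 - (1-phi0)/(1-s) by mass balance);
    ``"linear_with_depth"`` concentrates the strain toward the piston
    (displacement maximal at the top, vanishing at the bottom).  The true
    forward displacement field (reference grid) is stored in the result.
    """
    if not 0 <= surface_strain < 1:
        raise ValueError("surface_strain must be in [0, 1)")
    if profile not in ("uniform", "linear_with_depth"):
        raise ValueError(f"unknown profile {profile!r}")
    out = truth.copy()
    if surface_strain == 0:
        out.displacement = np.zeros((3, *truth.labels.shape), dtype=np.float32)
        return VolumeGrid(v.data.copy(), v.voxel_size), out

    labels = truth.labels.labels
    nz, ny, nx = labels.shape
    solid = np.isin(labels, SOLID_CODES)
    pore = ~solid
    zcol = np.arange(nz, dtype=np.float64)[:, None, None]

    pore_w = pore.astype(np.float64)
    if profile == "uniform":
        pore_total = pore_w.sum(axis=0)  # per column
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(pore_total > 0, surface_strain * nz / pore_total, 0.0)
    else:  # closure grows linearly with height; same total surface displacement
        wsum = (pore_w * zcol).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(wsum > 0, surface_strain * nz * (nz - 1) / wsum, 0.0)
        c = lam[None, :, :] * zcol / (nz - 1)
    c = np.broadcast_to(c, labels.shape) if c.ndim == 3 else np.broadcast_to(c[None], labels.shape)
    c = np.clip(c, 0.0, 1.0)

    inc = np.where(solid, 1.0, 1.0 - c)
    zpos = np.cumsum(inc, axis=0) - inc  # new float position of each voxel
    tgt = np.floor(zpos + 0.5).astype(np.int64)

    spec = truth.spec
    rng = _rng(spec, 2, truth.n_turnover_rounds)
    new_labels = np.full(labels.shape, ClassCode.PORE_CONNECTED, dtype=np.uint8)
    new_gray = np.clip(
        rng.normal(spec.pore_mean, max(spec.noise_sigma, 1e-6), labels.shape), 0, 255
    ).astype(np.float32)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for z in range(nz):
        t = tgt[z]
        new_labels[t, yy, xx] = labels[z]
        new_gray[t, yy, xx] = v.data[z]

    disp = np.zeros((3, nz, ny, nx), dtype=np.float32)
    disp[0] = (zpos - zcol).astype(np.float32)

    new_labels = _classify_pores_truth(new_labels)
    out.labels.labels = new_labels
    out.labels.provenance += f" + compact(s={surface_strain}, {profile})"
    out.displacement = disp
    # mean final column height: porosity below it obeys the mass balance
    out.surface_height = int(min(nz, np.ceil(zpos[-1].mean() + 1)))

    def _advect_point(p: tuple[float, float, float]) -> tuple[float, float, float]:
        z, y, x = p
        zi = int(np.clip(np.floor(z), 0, nz - 2))
        f = z - zi
        yi, xi = int(round(y)) % ny, int(round(x)) % nx
        znew = (1 - f) * zpos[zi, yi, xi] + f * zpos[zi + 1, yi, xi]
        return (float(znew), y, x)

    out.particles = [(_advect_point(cp), r) for cp, r in truth.particles]
    out.grains = [_advect_point(g) for g in truth.grains]
    return VolumeGrid(new_gray, v.voxel_size), out


# ---------------------------------------------------------------------------
# structure turnover
# ---------------------------------------------------------------------------

def apply_turnover(
    v: VolumeGrid,
    truth: GroundTruth,
    intensity: float,
    mix: dict[str, float] | None = None,
    porosity_budget: float = 0.02,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeGrid, GroundTruth]:
    """Apply structure-turnover events: channels, micro-cracks, pore refills.

    ``intensity`` is the expected event count per 10^6 voxels.  Channels are
    random cylinders carved to pore, cracks thin planar slabs carved to pore,
    refills pore neighbourhoods flood-filled back to matrix (earthworm-cast
    analogue).  Tracer particles and grains are never moved or overwritten:
    turnover changes their pore context, not their position.  The cumulative
    porosity change of one call is bounded by ``porosity_budget``.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    mix = mix or {"channel": 0.35, "crack": 0.25, "refill": 0.40}
    wsum = sum(mix.values())
    if not np.isclose(wsum, 1.0):
        raise ValueError("mix weights must sum to 1")
    out = truth.copy()
    out.n_turnover_rounds = truth.n_turnover_rounds + 1
    if intensity == 0:
        return VolumeGrid(v.data.copy(), v.voxel_size), out

    spec = truth.spec
    if rng is None:
        rng = _rng(spec, 3, out.n_turnover_rounds)
    labels = out.labels.labels
    gray = v.data.astype(np.float32).copy()
    nz, ny, nx = labels.shape
    nvox = labels.size
    protected = np.isin(labels, (ClassCode.PARTICLE, ClassCode.GRAIN))
    phi0 = (~np.isin(labels, SOLID_CODES)).mean()

    n_events = int(round(intensity * nvox / 1e6))
    kinds = rng.choice(list(mix), size=n_events, p=list(mix.values()))
    for kind in kinds:
        phi = (~np.isin(labels, SOLID_CODES)).mean()
        if kind in ("channel", "crack") and phi - phi0 >= porosity_budget:
            continue
        if kind == "refill" and phi0 - phi >= porosity_budget:
            continue
        if kind == "channel":
            p0 = rng.uniform(0, [nz, ny, nx])
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            length = rng.uniform(0.3, 0.7) * nz
            radius = rng.uniform(1.5, 3.0)
            ts = np.arange(0, length, 0.5)
            pts = (p0[None] + ts[:, None] * d[None]).round().astype(int)
            ok = ((pts >= 0) & (pts < [nz, ny, nx])).all(axis=1)
            carve = np.zeros(labels.shape, dtype=bool)
            offs = _ball_offsets(radius)
            for p in pts[ok][:: max(1, int(radius))]:
                q = p + offs
                qok = ((q >= 0) & (q < [nz, ny, nx])).all(axis=1)
                q = q[qok]
                carve[q[:, 0], q[:, 1], q[:, 2]] = True
            carve &= ~protected
            labels[carve] = ClassCode.PORE_CONNECTED
            gray[carve] = np.clip(
                rng.normal(spec.pore_mean, max(spec.noise_sigma, 1e-6), int(carve.sum())), 0, 255)
        elif kind == "crack":
            p0 = rng.uniform(0, [nz, ny, nx])
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            rad = rng.uniform(8, 20)
            thick = rng.uniform(0.8, 1.5)
            m = int(np.ceil(rad))
            lo = np.maximum(np.floor(p0 - m).astype(int), 0)
            hi = np.minimum(np.ceil(p0 + m).astype(int) + 1, [nz, ny, nx])
            g = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
            rel = g - p0[:, None, None, None]
            distn = np.abs(np.tensordot(n, rel, axes=(0, 0)))
            inplane = np.sqrt((rel**2).sum(axis=0))
            sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
            carve = (distn <= thick / 2) & (inplane <= rad) & ~protected[sl]
            labels[sl][carve] = ClassCode.PORE_CONNECTED
            gray[sl][carve] = np.clip(
                rng.normal(spec.pore_mean, max(spec.noise_sigma, 1e-6), int(carve.sum())), 0, 255)
        else:  # refill
            pore_idx = np.argwhere(labels == ClassCode.PORE_CONNECTED)
            if len(pore_idx) == 0:
                continue
            c = pore_idx[rng.integers(len(pore_idx))]
            rad = rng.uniform(5, 10)
            offs = _ball_offsets(rad)
            q = c + offs
            qok = ((q >= 0) & (q < [nz, ny, nx])).all(axis=1)
            q = q[qok]
            vals = labels[q[:, 0], q[:, 1], q[:, 2]]
            fill = q[(vals == ClassCode.PORE_CONNECTED) | (vals == ClassCode.PORE_ENCLOSED)]
            labels[fill[:, 0], fill[:, 1], fill[:, 2]] = ClassCode.MATRIX
            gray[fill[:, 0], fill[:, 1], fill[:, 2]] = np.clip(
                rng.normal(spec.matrix_mean, max(spec.noise_sigma, 1e-6), len(fill)), 0, 255)

    out.labels.labels = _classify_pores_truth(labels)
    out.labels.provenance += f" + turnover(intensity={intensity})"
    return VolumeGrid(gray, v.voxel_size), out


# ---------------------------------------------------------------------------
# imaging model
# ---------------------------------------------------------------------------

def render_grayscale(truth: GroundTruth, spec: PhantomSpec | None = None,
                     rng: np.random.Generator | None = None) -> VolumeGrid:
    """Render truth labels to gray data: class means, blur, noise, clip.

    The Gaussian blur creates partial-volume films of intermediate gray around
    bright particles (the main segmentation hazard of the real scans); noise
    is additive Gaussian.
    """
    spec = spec or truth.spec
    if rng is None:
        rng = _rng(spec, 4, truth.n_turnover_rounds)
    lut = np.zeros(len(ClassCode), dtype=np.float64)
    lut[ClassCode.PORE_CONNECTED] = spec.pore_mean
    lut[ClassCode.PORE_ENCLOSED] = spec.pore_mean
    lut[ClassCode.MATRIX] = spec.matrix_mean
    lut[ClassCode.PARTICLE] = spec.particle_mean
    lut[ClassCode.GRAIN] = spec.grain_mean
    lut[ClassCode.UNASSIGNED] = spec.matrix_mean
    gray = lut[truth.labels.labels]
    if spec.blur_sigma > 0:
        gray = ndi.gaussian_filter(gray, spec.blur_sigma)
    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0, spec.noise_sigma, gray.shape)
    return VolumeGrid(np.clip(gray, 0, 255).astype(np.float32), spec.voxel_size)
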