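"""Contact-distance analysis: the structure-turnover metric.

A Euclidean distance transform assigns every non-interaggregate-pore voxel
(matrix, garnet, occluded pores, unassigned) its minimum distance to the
interaggregate pore space — the contact distribution.  Its mean d̄_s
approximates the oxygen diffusion length through the water-filled matrix.
Comparing the mean over tracer-particle voxels d̄_p with d̄_s separates
structure turnover from mere compaction: particles planted on aggregate
surfaces start with d̄_p ≪ d̄_s; compaction grows both means in parallel
(d̄_p stays below the 1:1 line), while turnover — formation and destruction
of pores that rearranges the particles' spatial context — drives
Δ = 1 − d̄_p/d̄_s toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .core_io import ClassCode, LabelVolume

__all__ = [
    "ContactDistanceResult",
    "TurnoverTrajectory",
    "contact_distance_map",
    "particle_vs_bulk",
    "turnover_trajectory",
    "fit_distance_porosity",
    "matric_potential_for_diameter",
    "garnet_lifetime",
]


@dataclass
class ContactDistanceResult:
    """Distance-to-pore field plus bulk and particle histograms and means."""

    distance: np.ndarray           # μm; 0 exactly on PORE_CONNECTED
    voxel_size: float
    bin_edges: np.ndarray          # μm, one-voxel width
    hist_bulk: np.ndarray          # counts, all non-PORE_CONNECTED voxels
    hist_particle: np.ndarray      # counts, PARTICLE voxels
    mean_bulk: float               # d̄_s, μm
    mean_particle: float | None    # d̄_p, μm (None without particles)
    mean_matrix: float             # mean over MATRIX voxels only, μm
    porosity: float                # total resolved pore fraction

    @property
    def divergence(self) -> float | None:
        """Δ = 1 − d̄_p/d̄_s; 0 on the 1:1 line (randomized particles)."""
        if self.mean_particle is None:
            return None
        return 1.0 - self.mean_particle / self.mean_bulk


@dataclass
class TurnoverTrajectory:
    """Ordered (d̄_s, d̄_p, Δ) states of one sample, plus an optional decay rate."""

    states: list[str]
    mean_bulk: np.ndarray
    mean_particle: np.ndarray
    divergence: np.ndarray
    decay_rate: float | None = None   # per state step, from Δ_t ≈ Δ_0 e^{−kt}


def contact_distance_map(l: LabelVolume) -> ContactDistanceResult:
    """Exact Euclidean contact distances to the interaggregate pore space.

    Distances are measured to ``PORE_CONNECTED`` only; enclosed pores count
    as bulk (they are not air-connected).  Histogram bin width is one voxel.
    Raises if the volume has no connected pore space.
    """
    pore = l.labels == ClassCode.PORE_CONNECTED
    if not pore.any():
        raise ValueError("no connected pore space: contact distances undefined")
    dist_vox = ndi.distance_transform_edt(~pore)
    dist = dist_vox * l.voxel_size
    bulk = ~pore
    particles = l.labels == ClassCode.PARTICLE
    matrix = l.labels == ClassCode.MATRIX
    dmax = float(dist[bulk].max()) if bulk.any() else 0.0
    edges = np.arange(0.0, dmax + 2 * l.voxel_size, l.voxel_size)
    hist_bulk, _ = np.histogram(dist[bulk], bins=edges)
    hist_part, _ = np.histogram(dist[particles], bins=edges)
    pore_total = l.pore_mask()
    return ContactDistanceResult(
        distance=dist,
        voxel_size=l.voxel_size,
        bin_edges=edges,
        hist_bulk=hist_bulk,
        hist_particle=hist_part,
        mean_bulk=float(dist[bulk].mean()) if bulk.any() else 0.0,
        mean_particle=float(dist[particles].mean()) if particles.any() else None,
        mean_matrix=float(dist[matrix].mean()) if matrix.any() else float("nan"),
        porosity=float(pore_total.mean()),
    )


def particle_vs_bulk(r: ContactDistanceResult) -> tuple[float, float, float]:
    """(d̄_s, d̄_p, Δ) of one state; raises without particle voxels."""
    if r.mean_particle is None:
        raise ValueError("no particle voxels: particle mean undefined")
    return r.mean_bulk, r.mean_particle, r.divergence


def turnover_trajectory(
    results: list[ContactDistanceResult],
    labels: list[str] | None = None,
    fit_decay: bool = True,
) -> TurnoverTrajectory:
    """Trajectory of (d̄_s, d̄_p, Δ) over ordered states of one sample.

    The rate at which Δ decays toward 0 is the structure-turnover rate; an
    exponential Δ_t = Δ_0 e^{−kt} is fitted in log space when all Δ > 0.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 states for a trajectory")
    if any(r.mean_particle is None for r in results):
        raise ValueError("every state needs particle voxels")
    ds = np.array([r.mean_bulk for r in results])
    dp = np.array([r.mean_particle for r in results], dtype=np.float64)
    delta = 1.0 - dp / ds
    labels = labels or [f"state_{i}" for i in range(len(results))]
    rate = None
    if fit_decay and (delta > 0).all():
        t = np.arange(len(delta), dtype=np.float64)
        slope, _ = np.polyfit(t, np.log(delta), 1)
        rate = float(max(0.0, -slope))
        if np.allclose(delta, delta[0]):
            rate = 0.0
    return TurnoverTrajectory(
        states=list(labels), mean_bulk=ds, mean_particle=dp,
        divergence=delta, decay_rate=rate,
    )


def fit_distance_porosity(points) -> tuple[float, float]:
    """Least-squares fit of d̄_s = a·exp(−b·φ) in log space.

    ``points`` is a sequence of (porosity, mean contact distance) pairs; the
    intercept ``a`` is the vanishing-porosity contact distance, set by the
    aggregate size.  Raises on non-positive distances or constant porosity
    (rank-deficient design).
    """
    pts = np.asarray(list(points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (porosity, distance) points")
    phi, d = pts[:, 0], pts[:, 1]
    if (d <= 0).any():
        raise ValueError("distances must be positive for the log-space fit")
    if np.ptp(phi) == 0:
        raise ValueError("porosity constant across points: fit rank-deficient")
    slope, intercept = np.polyfit(phi, np.log(d), 1)
    return float(np.exp(intercept)), float(-slope)


def matric_potential_for_diameter(
    d_um: float,
    surface_tension: float = 0.075,
    contact_angle_deg: float = 0.0,
) -> float:
    """Matric potential (hPa, negative) draining pores of diameter ``d_um``.

    Young–Laplace with perfect wettability by default:
    ψ_m = −4 σ_w cos(θ) / d.  At d = 8 μm and σ_w = 0.075 N/m this gives
    −375 hPa — the potential at which the resolved pore space is air-filled.
    """
    if d_um <= 0:
        raise ValueError("pore diameter must be positive")
    psi_pa = -4.0 * surface_tension * np.cos(np.deg2rad(contact_angle_deg)) / (d_um * 1e-6)
    return float(psi_pa / 100.0)  # Pa → hPa


def garnet_lifetime(
    d0_um: float,
    d1_um: float,
    rate: float = 5e-7,       # dissolution flux, mg·mm⁻²·a⁻¹
    density: float = 4.3,     # almandine, mg·mm⁻³
) -> float:
    """Years for a spherical garnet grain to shrink from d0 to d1.

    Shrinking-sphere model with a surface-area-proportional dissolution flux:
    the diameter shrinks at the constant rate dd/dt = −2k/ρ, so
    t = ρ (d0 − d1) / (2k).  Field dissolution rates span orders of
    magnitude with pH and stagnant-moisture fraction; both parameters are
    exposed rather than fixed.
    """
    if not d0_um >= d1_um > 0:
        raise ValueError("require d0 >= d1 > 0")
    if rate <= 0 or density <= 0:
        raise ValueError("rate and density must be positive")
    dd_mm = (d0_um - d1_um) * 1e-3
    return float(density * dd_mm / (2.0 * rate))
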