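# Methods

This note documents the models, algorithms and numerical choices behind
`garnettrack`, and what the synthetic phantoms do and do not establish about
real scan data.

## Volumes, classes, conventions

All volumes are isotropic, axis order `(z, y, x)` with z the compaction axis
pointing from the sample bottom toward the piston. Gray data follow the
8-bit convention (values in [0, 255]; 16-bit input is linearly rescaled).
Segmentation distinguishes six classes: `PORE_CONNECTED` (interaggregate
pore space, operationalized as pore components touching the volume or ROI
boundary), `PORE_ENCLOSED` (occluded pores), `MATRIX`, `PARTICLE` (fine
garnet tracer), `GRAIN` (coarse garnet markers) and `UNASSIGNED`
(partial-volume and unconfirmed voxels). On disk, labels are written 8-bit
with visually distinct values (0, 50, 100, 150, 200, 250) so any viewer
shows them sensibly. Pore-phase connectivity is 26-neighbourhood, solid
analyses use 6-neighbourhood — the standard dual pairing that avoids
topological paradoxes.

## Segmentation chain

1. **Denoising** — non-local means (patch radius 1, search radius 3),
   filter strength h = 0.8 × the noise level estimated from the median
   absolute deviation of the 3-D Laplacian response (for i.i.d. Gaussian
   noise the 6-neighbour Laplacian has variance 42 σ²).
2. **Thresholds** — two gray thresholds by three-class multi-level Otsu on
   the (optionally ROI-restricted) histogram; degenerate histograms (< 3
   distinct values) raise with advice to supply thresholds manually.
3. **Tentative classes** — pore / matrix / garnet by simple thresholding.
4. **Partial-volume cleanup** — the matrix class is opened with a ball of
   diameter d_SE = 5 voxels; voxels removed by the opening, and matrix
   objects smaller than 27 voxels (a free parameter), become `UNASSIGNED`.
   This removes the spurious 1–2-voxel matrix films that blur paints around
   bright particles. The operation is idempotent.
5. **Particle detection** — scale-normalized Laplacian of Gaussian:
   response σ²·(−LoG) maximized per voxel over the scale ladder
   σ ∈ {1.5, 2.2, 3.2, 4.6, 6.6} voxels (geometric; covers tracer radii
   r = σ√3 ≈ 2.6–11 voxels, comfortably bracketing the 45–100 μm garnet at
   8 μm/voxel). Hysteresis thresholding (defaults 0.6× / 0.3× of the
   99.9th response percentile, both overridable) segments the blob mask;
   every scale-space local maximum above the high threshold yields one
   detection, so touching particles grown into one hysteresis component are
   still counted separately. Coarse grains — tentative-garnet components
   larger than twice the largest particle volume implied by the scale
   ladder — are masked (dilated by d_SE) during detection, because their
   edges mimic blob responses.
6. **Final assembly** — tentative-garnet components supported by the LoG
   mask keep their full thresholded extent as `PARTICLE` (the threshold,
   not the LoG support region, defines the particle boundary; the LoG mask
   alone systematically under- or over-shoots the rim). Unconfirmed garnet
   becomes `UNASSIGNED`; grains overwrite everything; pores are split into
   connected vs enclosed.

On noiseless, blur-free phantoms the chain reproduces ground truth exactly
outside a 1-voxel interface shell. With realistic imaging (blur σ = 1,
noise σ = 5) particle *interiors* are recovered essentially completely while
the 1-voxel partial-volume shell goes to `UNASSIGNED` by design — the tests
assert interior recovery, since shell voxels are genuinely ambiguous in
gray value.

## Pore metrics

*Porosity profiles* are pore area fractions per xy-plane (connected and
enclosed pores together); empty ROI planes are flagged NaN, never zero.

*Local thickness* implements the maximum-inscribed-sphere construction on
the exact Euclidean distance transform: with R(c) the distance from a pore
voxel c to the solid, the thickness at x is 2·max{R(c) : |x−c| < R(c)} − 1
voxels, so an isolated pore voxel reads 1 voxel. Candidate radii are swept
in descending order, painting the union of inscribed balls per radius (one
EDT per level); levels are thinned to at most 64 (configurable) for large
volumes. A brute-force oracle (exhaustive centres, strict squared-distance
coverage) verifies the implementation on small volumes.

*Γ connectivity* is the second moment of the pore cluster-size
distribution, Γ = Σ nᵢ²/N_v², computed from 26-connected labeling; Γ(d)
curves restrict the pore phase to voxels with local thickness ≥ d (the
construction of the diameter-resolved curve is an interpretation, recorded
here and configurable, since thresholded-thickness subsets and morphological
openings differ slightly).

## Contact distances and the turnover metric

Distances are exact Euclidean, measured **to `PORE_CONNECTED` only**:
enclosed pores are not air-connected and therefore count as bulk.
Histograms use one-voxel bins. Besides the bulk and particle means the
matrix-restricted mean is reported; under uniform random particle placement
in the matrix the expected particle mean equals it (the randomized 1:1
limit). Δ = 1 − d̄_p/d̄_s is dimensionless, 0 at equilibrium; the raw pair
(d̄_s, d̄_p) is reported alongside for 1:1-plane plots. An exponential decay
rate is fitted to Δ(t) in log space when all Δ > 0.

The distance–porosity relation d̄_s = a·exp(−b·φ) is fitted by least squares
in log space; the intercept a is the vanishing-porosity diffusion length,
set by the aggregate size. The Young–Laplace helper converts pore diameter
to the matric potential that drains it (ψ_m = −4σ_w cosθ/d; σ_w = 0.075 N/m
and θ = 0 by default, giving −375 hPa at 8 μm). The garnet-lifetime helper
uses a shrinking-sphere model with surface-proportional dissolution flux,
t = ρ(d₀−d₁)/(2k); density and rate are parameters because field dissolution
rates span orders of magnitude.

## Digital volume correlation

Registration of the coarse-grain matrix is re-implemented self-containedly
rather than delegated to a registration toolkit: volumes are block-mean
downscaled and gray-windowed so only garnet carries signal; each block of
the deformed volume is located in the reference by exhaustive normalized
cross-correlation; the integer peak is refined per axis by 3-point quadratic
interpolation. Matches pinned at the search border away from the zero-shift
position are flagged unreliable (the true shift may be truncated), as are
signal-free blocks; reliable vectors are smoothed with a confidence-weighted
Gaussian (σ = 0.75 control spacings) so in-filled values never contaminate
good ones, and unreliable blocks are in-filled by inverse-distance weighting
of confident neighbours. Displacements are material motion
(deformed − reference) in μm of the original grid. Blocks whose true source
material entered or left the field of view have no in-volume match; profile
evaluations therefore restrict to heights where at least half the blocks are
confident.

## Phantom generator

The generator emulates the laboratory system, not CT physics:

- **Packing** — bumpy spheres (radius field perturbed by ~4 random
  von-Mises–Fisher lobes, ±15 %) ballistically deposited along −z onto a
  laterally periodic bed. Moist aggregates interpenetrate: each deposit
  sinks below its resting point until its voxel overlap with the bed reaches
  a fraction α, and α is calibrated by bisection (re-running the
  deterministic deposition) until porosity hits the target ±0.03. The
  default target is 0.30, the loose-packing porosity of the case study.
- **Coating** — a chosen fraction of matrix surface voxels facing the
  connected pore space seeds particle balls (radii 3–6 voxels ≈ 45–100 μm
  garnet at 8 μm/voxel), placed mostly proud of the surface so each touches
  the pore network; a configurable fraction instead detaches into wide pore
  throats with no matrix contact. Placement is greedy and non-overlapping.
- **Compaction** — per-column pore collapse: solid voxels keep unit spacing
  while pore voxels shrink by a depth-dependent closure factor, then labels
  are re-rasterized ("label advection", no mechanics). Solid mass is
  conserved by construction; `uniform` realizes uniform strain
  (displacement linear in height; porosity obeys the mass balance
  1 − (1−φ₀)/(1−s) below the new surface), `linear_with_depth` concentrates
  strain toward the piston (displacement maximal at top). The true forward
  displacement field and advected particle/grain centroids are stored.
  Because columns compress independently, the compacted surface is rough;
  analyses of compacted states crop to ~80 % of the mean surface height.
- **Turnover** — channels (random cylinders carved to pore), micro-cracks
  (thin planar slabs) and refills (pore neighbourhoods flooded back to
  matrix). Particles and grains are never moved or overwritten — turnover
  changes their context, not their position. Each call bounds its net
  porosity change by a budget (default 0.02).
- **Imaging** — class gray means (40/130/220/235), Gaussian blur (σ = 1
  voxel) producing the partial-volume films around particles, additive
  Gaussian noise (σ = 5), clipped to [0, 255]. No ring or beam-hardening
  artifacts: the workflow removes noise before analysis, and artifact
  realism is out of scope.

All randomness flows from one seed; every stage is deterministic.

## Problem sizes and what the tests show

Tests and the acceptance script use 96³ phantoms (128³ for DVC) with
aggregate radii 7–14 voxels — chosen so the full suite runs in minutes on a
single core while keeping ≥ 6 aggregates per linear dimension. Geometric
similarity to the real system is deliberately sacrificed: real aggregates
are ~60–250 voxels across at 8 μm, so the phantom's particle-to-aggregate
size ratio is ~5× larger than in the experiment. Consequences: the initial
divergence Δ ≈ 0.4 (real pulse labeling would start nearer 1), and absolute
distances are not comparable to the case study. The *qualitative* laws the
suite verifies — monotone porosity and pore-size decline under strain, Γ
near 1 until a critical porosity band around 0.09–0.12 followed by steep
collapse, Δ constant under compaction versus Δ → 0 under turnover, the
exponential distance–porosity relation with radius-controlled intercept —
are scale-free statements and are the ones the phantoms can legitimately
establish. What passing tests do **not** show: robustness to CT artifacts,
to heterogeneous mineralogy (iron-free bright grains), to anisotropic
resolution, or to particle coverage far below the pulse-labeling regime.

The overlapping-sphere model's exponential fit is evaluated over the
experimentally relevant porosity range (φ ≈ 0.04–0.48, overlap sweep
0.50–0.70 of the lattice spacing); at extreme overlaps (φ < 0.02) the decay
steepens beyond a single exponential, which the model reports but the fit
quality claim does not cover.

## Numerical details

- Exact EDT from `scipy.ndimage.distance_transform_edt`; periodic distances
  (sphere model) by 3× tiling and central cropping.
- Otsu thresholds from 256-bin histograms; ties in the inscribed-sphere
  coverage test are broken strictly (|x−c| < R), with squared-integer
  comparisons in the oracle to avoid float ties.
- Compaction rasterization rounds with floor(z+0.5); consecutive solid
  voxels are ≥ 1 apart in the advected map, so solid never collides.
- Report JSON rounds floats to 6 digits and sorts keys, making pipeline
  re-runs byte-identical under a fixed seed.
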