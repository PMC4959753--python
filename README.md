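# garnettrack

Quantifying **soil structure turnover** from 3-D X-ray microtomography of
garnet-labeled aggregate packings.

Soil structure — the arrangement of aggregates and pores — controls where
oxygen, water and nutrients can reach. Pore-space summaries (porosity, pore
sizes, connectivity) describe a single snapshot, but say nothing about how
fast pores are created and destroyed. `garnettrack` implements an
image-analysis workflow for a *structure labeling* experiment: sieved soil
aggregates are coated with fine garnet tracer particles (45–100 μm, bright in
CT because of their iron content), packed into a column, and scanned
repeatedly while the structure evolves. The particles mark the initial
aggregate boundaries; as pores are destroyed and new ones form, the
particles' distance to the nearest air-filled pore drifts from "practically
zero" toward the bulk-soil average — and the speed of that drift is the
structure turnover rate.

The package is aimed at soil physicists and X-ray CT practitioners; it works
on TIFF stacks or MHD/raw volumes at isotropic resolution (the case study
uses 8 μm voxels) and ships a seeded phantom generator so every stage can be
exercised and validated without scan data.

## The metric

For a segmented volume, a Euclidean distance transform assigns every voxel
outside the interaggregate (air-connected) pore network its minimum distance
to that network — the *contact distribution*. With

- d̄_s — mean contact distance over all non-pore voxels (bulk soil),
- d̄_p — mean contact distance over tracer-particle voxels,

the divergence **Δ = 1 − d̄_p / d̄_s** starts close to 1 (particles sit on
aggregate surfaces) and behaves diagnostically:

- **compaction** moves everything collectively — both means grow, Δ stays
  roughly constant (trajectory parallel to the 1:1 line in the d̄_p–d̄_s
  plane);
- **structure turnover** (new biopores, micro-cracks, pore refilling)
  rearranges the particles' spatial context without moving them — Δ decays
  toward 0, the randomized limit.

Supporting statistics: porosity profiles per height, pore-size distributions
by the maximum-inscribed-sphere method, pore connectivity
Γ = Σᵢ nᵢ² / N_v² (second moment of the pore cluster-size distribution:
1 for one percolating cluster, → 0 for fragmented pore space), digital
volume correlation of the coarse-grain matrix between scans, and
Young–Laplace helpers (at 8 μm resolution the resolved pores are exactly
those air-filled at ψ_m = −375 hPa).

## Worked example

```python
import garnettrack as gt

spec = gt.PhantomSpec(shape=(96, 96, 96), aggregate_radius_range=(7, 12),
                      coat_coverage=0.02, max_particles=200, n_grains=0, seed=5)
gray, truth = gt.generate_packing(spec)      # aggregate bed at porosity 0.30
truth = gt.coat_with_particles(truth)        # garnet coat on aggregate surfaces

cd0 = gt.contact_distance_map(truth.labels)
_, compacted = gt.compact(gray, truth, 0.10, "uniform")
cd1 = gt.contact_distance_map(compacted.labels)

vt, tt = gray, truth
for _ in range(16):                          # repeated turnover events
    vt, tt = gt.apply_turnover(vt, tt, intensity=40.0)
cd2 = gt.contact_distance_map(tt.labels)
```

which prints, formatting the three states:

```
fresh coat:  d_s=34.2 um  d_p=19.5 um  Delta=0.431  (phi=0.245)
compacted:   d_s=36.3 um  d_p=20.6 um  Delta=0.434
turned over: d_s=19.5 um  d_p=19.5 um  Delta=0.003
pore connectivity Gamma = 0.997 over 30 clusters
resolution limit: psi_m = -375 hPa at 8 um
```

Freshly coated particles lie at less than half the bulk distance (Δ = 0.43).
A 10 % uniaxial compaction grows both means in lockstep — Δ is unchanged —
while sixteen rounds of channel/crack/refill events at constant porosity
drive Δ to ≈ 0: the particles have lost all memory of the initial structure.

## Command line

```
garnettrack phantom | segment | metrics | distances | deform | trajectory | spheremodel | demo
```

Each subcommand is a thin wrapper over the library: `segment` runs
denoising → multi-Otsu thresholding → partial-volume cleanup → LoG particle
detection → pore classification on one volume; `metrics` and `distances`
write CSV/JSON summaries; `deform` runs block-matching digital volume
correlation between two states; `demo` generates and analyses a complete
synthetic experiment.

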