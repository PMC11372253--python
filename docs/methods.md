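# Methods

## Scope and model

`phantomforge` models the digital half of a fillable three-compartment brain
phantom's life cycle: constructing the compartment geometry from a labeled
tissue volume, exporting printable surfaces, planning radiotracer fills, and
predicting what a PET scanner — and the standard partial-volume-effect (PVE)
corrections applied to its images — would report. The physical steps
(printing, support dissolution, sealing, scanning) are out of scope, as are
sinogram-domain reconstruction, attenuation, scatter and atlas registration.

## Synthetic anatomy

The generator emulates the *topology* an MR-derived digital brain phantom
hands to the construction rules, not its shape realism: a closed GM rind
(nested ellipsoids), a WM core, four striatal bodies strictly inside the
core, spherical deep-nuclei sub-labels, and deliberately disconnected
single-voxel islands. Ellipsoids keep every volume/area oracle analytic;
gyrification would change none of the construction logic, which depends only
on nesting, connectivity and island structure. Consequences for
interpretation: passing tests demonstrate the correctness of the rules and
of the recovery pipeline on piecewise-constant nested compartments; they do
not probe segmentation error, registration error, or cortical-fold geometry
(where thin-structure PVE is more severe than on a smooth rind).

Key parameters (defaults):

| parameter | default | why |
|---|---|---|
| grid / voxel | 160³ at 0.9375 × 0.9375 × 1 mm | the grid convention of MR-derived digital phantoms; 160³ keeps default builds desk-sized |
| brain radii | 60 × 52 × 55 mm | adult-brain-scale ellipsoid that leaves ≥ 10 mm grid margin (≳ 3.7 σ of the PSF), so blur conserves activity |
| GM rind thickness | 6 mm | thick enough that injected WM islands keep the ≥ 2-voxel clearance that guarantees 26-disconnection on the source grid |
| striatal bodies | caudate ≈ 1 mL, putamen ≈ 2 mL per side | small hot structures whose uncorrected means collapse, the phenomenon the striatum compartment exists to exercise |
| n_islands | 4 per tissue | exercises the island-reassignment rule; island sites are seeded RNG draws, the only stochastic element |

A fixed seed yields a bit-identical volume. `AnatomyParams.scaled(f)`
shrinks all mm geometry for coarse-grid runs (the Monte-Carlo experiments
use 96³ grids this way).

## Construction rules

* **Merging**: total lookup-table relabel; unmapped labels are a hard error.
  The default table sends pallidum/dentate/thalamus to GM, substantia
  nigra/red nucleus to WM, caudate/putamen to striatum, CSF/extracranial to
  background.
* **Island reassignment**: island detection uses 26-connectivity (the
  permissive reading of "3-dimensionally disconnected"; parameterized).
  The largest component of each tissue is the main body; every other voxel
  of that tissue takes the majority label among its face-adjacent
  non-background *surrounding* voxels — island voxels do not vote, so thick
  islands erode outside-in over iterations — with ties broken by fixed label
  order (GM < WM < striatum) for determinism. Deep GM nuclei merged into GM
  are 26-disconnected from the rind and are deliberately absorbed into the
  surrounding WM by this rule. Total non-background count is conserved; the
  operation is idempotent.
* **Cylinders**: pipes and connectors are rasterized as
  distance-to-segment ≤ lumen/2 on voxel centers. Each cylinder carries an
  `allowed_crossings` label set: crossing an allowed label relabels the
  voxels (recorded in pipe/connector provenance masks); any other label
  aborts, keeping compartments disjoint unless the crossing is deliberate.
  Defaults follow the nesting order (GM pipes may cross only background, WM
  pipes background+GM, striatum pipes background+GM+WM, connectors WM only).
  Fill pipes are z-aligned, placed bilaterally at the column with the
  highest apical surface per hemisphere, and penetrate 3 mm below the apical
  surface, halving the penetration when a thin curved wall would otherwise
  be punched through. Crumbs stranded by pipe carving are absorbed by a
  second island-reassignment pass. Threaded joints are metadata only.
* **Supersampling**: nearest-neighbor (label-preserving) onto the same world
  extent; an output voxel takes the label of the input voxel containing its
  center. Integer ratios reduce to exact block replication.

## Meshing and printability

Surfaces come from marching cubes at iso-level 0.5 on the binary compartment
mask, padded by one background voxel so surfaces always close; vertices are
mapped to world mm. The one-voxel interface shell (voxels with a 26-neighbor
outside the compartment) is available separately and is idempotent on thin
sets. Noise shells — small disconnected mesh components from surface
extraction — are dropped below a 50 mm² area threshold (a few voxel faces;
the threshold is a package decision, exposed as a parameter, and the largest
component is always kept). Validation reports watertightness (every edge
shared by exactly two faces), component count, Euler characteristic, area,
divergence-theorem volume, and minimum wall thickness measured as the
minimum voxel-grid Euclidean distance between different compartments —
cheaper and deterministic versus mesh-to-mesh proximity queries; adjacent
compartments at 0.75 mm pitch report 0.75 mm. STL is written binary
(80-byte header, uint32 count, 50-byte triangle records).

## Fill planning

Volumes are voxel counts × voxel volume (mL). Given a WM scan-time
concentration and target ratios, every compartment's scan-time concentration
is ratio × WM, and the injected dose inverts radioactive decay:
`dose = conc × volume × 2^(+Δt/T½)` with T½ = 109.77 min (¹⁸F). Each
compartment has its own injection-to-scan interval — compartments are filled
sequentially in practice, so a shared Δt is never assumed. The plan/decay
round trip is exact to machine precision by construction.

## PET simulation

Activity maps are piecewise constant (compartments fill uniformly). The PSF
is a separable Gaussian, σ = FWHM/(2√(2 ln 2)), FWHM 6.36 mm isotropic by
default — the uniform effective resolution assumed for processing; spatially
varying resolution is out of scope. Boundary handling is zero padding (the
phantom sits in inactive surroundings), and with the default ≥ 10 mm margins
total activity is conserved to ≲ 0.05%. PET-grid resampling is
volume-weighted block averaging for integer spacing ratios (conserving) and
trilinear with a warning otherwise. Noise is a voxelwise Poisson surrogate,
`v → Poisson(v·s)/s` — mean-preserving and seeded, a deliberate
simplification that does not reproduce the spatial covariance of
reconstructed PET noise.

## PVE correction

Formulas follow the classic method definitions (Rousset 1998; Müller-Gärtner
1992; Meltzer 1990); see the module docstring for the exact expressions.
Numerical choices:

* GTM is solved directly (`numpy.linalg.solve`, least squares for
  overdetermined ROI sets); condition numbers above 1e8 are an error
  advising coarser regions; the relative residual is checked at 1e-8.
  Background carries zero activity and therefore needs no column; ω rows may
  sum below 1. The ω-assembly blur is the same operator applied to the data;
  callers that resample the PET grid pass the composed operator so ω stays
  consistent.
* Müller-Gärtner needs WM and striatum concentration estimates: WM either
  from a deep-WM ROI on the uncorrected image (the centrum-semiovale analog,
  implemented as WM-mask erosion to 6 mm depth) or from the GTM solution;
  striatum always from GTM, since two-tissue MG has no native estimator for
  a third hot compartment. The GM denominator threshold defaults to 0.3 to
  avoid edge blow-up; corrected GM statistics are taken over
  threshold-valid GM voxels.
* Meltzer divides by the blurred whole-brain mask above the same threshold.
* The synthetic GM parcellation (angular wedges × axial slabs, 8×2 default)
  stands in for an anatomical atlas; parcels partition the GM mask exactly.
  Reported GM values are volume-weighted means with the across-parcel sample
  SD; per-parcel GTM (each parcel its own ROI alongside WM and striatum)
  supplies the corrected-GM dispersion.

For noiseless piecewise-constant activity GTM is exact up to solver
round-off, so recovery experiments test the whole chain (geometry, blur,
masks, assembly) rather than a tolerance of the method itself.

## Problem sizes and determinism

Default experiments run on the 160³ source grid (≈ 200×200×213 after
supersampling to 0.75 mm); Monte-Carlo noise experiments use a 0.7-scaled
anatomy on a 96³ 1-mm grid with 100 seeds. Every artifact is reproducible
from configuration plus seed; the pipeline writes a manifest with the config
hash and package versions.

## Known limitations

* No gyrification: cortical thin-fold PVE is underrepresented relative to a
  real brain; recovery numbers here characterize the methods under ideal
  nested-compartment geometry.
* No reconstruction physics: noise is voxelwise and post-blur; resolution is
  stationary and Gaussian.
* The wall between compartments is not modeled as a separate material — wall
  thickness is a printability report on the voxel grid, not a simulated
  cold layer in the PET image.
* The Alfano (PVEOUT) voxel method is not implemented (its algorithm is not
  publicly specified in a reproducible form); the recovery tables carry the
  four implemented columns.
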