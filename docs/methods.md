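# Methods

This note documents the models and design choices behind `csiplan`: what is
computed, which defaults matter, what the synthetic phantoms do and do not
emulate, and where the design was genuinely open.

## Geometry conventions

All volumes live on a regular voxel grid in an LPS patient frame (x →
patient left, y → posterior, z → superior), head-first supine, superior =
increasing slice index. World coordinates are millimetres; planning rules and
beam parameters are expressed in centimetres. Beam angles follow IEC 61217
with the couch fixed at 0° (the half-beam block exists precisely to avoid
couch rotations): gantry 90° enters from the patient's left, 180° is the
posterior spine field. Beam's-eye-view (BEV) coordinates are measured on the
isocenter plane; BEV +y is patient-superior at collimator 0°, so the y2 jaw
is the superior jaw.

## Anatomical pre-checks

Three measurements drive plan admissibility, all reduced to slice-index
arithmetic so they are invariant to grid translation:

* **canal length** — the superior-inferior extent of the spinal-canal mask
  (occupied-slice count × slice thickness). A curved-centerline arc length
  would differ on a kyphotic spine; the z-extent is used because field
  lengths are set along z.
* **brain-to-mandible distance** — |z(brain top) − z(mandible bottom)|. The
  half-beam block on the brain field caps this at 20 cm (rejection is
  strictly `> 20`).
* **feathering space** — the clearance between mandible bottom and shoulder
  top, clamped at 0. Feathering shifts the junction twice by the spacing
  `s`, spanning `2s`, so ≥ 2 cm of space supports `s = 1 cm`, [1, 2) cm
  supports `s = 0.5 cm`, and < 1 cm (strict) is rejected.

The spine field configuration is chosen from the canal length `L`:
`L ≤ 36 cm` → SINGLE, `36 < L ≤ 36·(120/100) = 43.2 cm` → EXTENDED,
otherwise MULTIPLE. The 36 cm maximum field length at isocenter, 100 cm SAD,
and 120 cm extended SSD are machine parameters (`MachineLimits`) and
configurable; the SINGLE/EXTENDED cut-offs scale with them.

## Field construction

* The cranio-spinal junction starts at the midpoint of the feathering
  interval minus one junction spacing, so the {0, +s, +2s} superior shifts
  all stay inside the measured space.
* The brain isocenter lies on the junction plane; the inferior jaw closes at
  exactly 0.0 (half-beam block), making the junction edge non-divergent.
  The brain isocenter's y coordinate follows the spine-field axis so the
  divergence-matched edges share a single junction line.
* Brain MLC apertures conform to a 1 cm isotropic expansion of the brain
  (Euclidean distance transform in mm space, boundary ties included); spine
  apertures conform to a 1 cm left-right-only dilation of the spinal canal.
  Leaf pairs take the min/max footprint extent in their 0.5 cm track;
  tracks without footprint are parked closed at the x1 jaw.
* BEV footprints are rasterized at 1 mm by projecting all eight corners of
  every mask voxel through the source and filling the projected bounding
  boxes (difference-array accumulation), so a fitted aperture covers the
  whole voxel, not just its center.
* Brain-field collimators rotate by θ = atan(L_sup / SSD_spine), where
  L_sup is the spine field's superior half-length, so the brain inferior
  edge parallels the diverging spine edge (sign mirrored between gantry 90°
  and 270°). The rotation is isolated in `match_divergence` and can be
  disabled by constructing beams directly.
* For MULTIPLE configurations the two spine fields' facing jaw edges are
  constructed as exact rays through the match point, placed 0.5 cm anterior
  to the canal's anterior surface at the mid-canal plane. The resulting
  skin gap follows the classical formula G = (d/2)(L1/SSD1 + L2/SSD2); the
  edges abut at the match depth and deliberately leave a sub-centimetre
  converging gap at the canal itself, keeping the overlap (hot) region
  anterior of the cord.

## Dose model

Dose to voxel v from one field is

    D(v) = w · ((SAD + d_max)/r(v))² · PDD(d_eff(v)) · F(v)

with `r` the distance to the source, `PDD` rising linearly from 0 to 1 over
the build-up depth `d_max` = 1.5 cm and falling as `exp(−μ (d − d_max))`
beyond it (μ = 0.05 cm⁻¹), and `F` the aperture fluence: a 1 mm jaw+MLC
openness map blurred with a Gaussian of σ = 0.3 cm (error-function penumbra,
50% at the projected geometric edge), sampled at each voxel's BEV
coordinates, with 2% leaf transmission outside the opening. The reference
output is 1 Gy per unit weight at `d_max` on axis at SSD 100; extended-SSD
fields keep that reference, so their output drops by inverse square exactly
as the setup implies.

`d_eff` is the radiological depth: the density line integral accumulated by
cumulative sum along the beam-axis direction (parallel rays). All CSI fields
here are axis-aligned laterals or posterior fields, and divergence is
retained where it matters for the planning logic — inverse square and the
fluence projection — so the parallel-depth approximation only softens
oblique-incidence depths far off-axis. Air (ρ=0) contributes nothing, so
the body surface needs no explicit handling. This is a broad-beam model: no
lateral scatter kernels, no electron transport, no interface effects, and
no MU calibration; absolute doses are meaningful only relative to the
normalization rules.

Edge tie-breaking: aperture-map pixels exactly on a jaw/leaf edge count as
open (a 1e-9 cm tolerance), which keeps opposed-lateral dose distributions
mirror-symmetric to ≤ 1e-6 on symmetric phantoms.

## Plan assembly

* **Subfields.** For each spine field, the canal-midline (per-slice centroid)
  dose of the parent field is sampled; leaf tracks covering segments whose
  midline dose exceeds the field's median are closed. SINGLE/EXTENDED plans
  get one subfield per spine field; MULTIPLE plans get two (median and 75th
  percentile thresholds), matching the subfield counts of the technique.
  The exact subfield shapes and objective are a declared stand-in (the
  clinical procedure is not specified to that level) and are isolated in
  `make_subfields` / `optimize_spine_weights`.
* **Weighting.** Subfield weights minimize the relative spread
  (max − min)/mean of the combined midline profile, restricted to points
  ≥ 1 cm inside both the jaws and the aperture's longitudinal extent (the
  penumbra at the field ends is not something a subfield can fix). The
  optimizer is a deterministic bounded coordinate descent (per-coordinate
  scan on a 0.002 grid over [0, 1.5], ≤ 50 sweeps, stop when a sweep
  improves the spread by < 1e-3); weights start at 0, so the optimized
  spread never exceeds the parent-only spread. Weights are fitted once on
  the unshifted plan and reused by the feathered copies.
* **Feathering.** Three sub-plans are built with every junction translated
  superiorly by {0, s, 2s}; each sub-plan is fully rebuilt (isocenters,
  half-beam jaws, MLC fits) so abutment holds at its shifted junction.
* **Normalization.** Within each sub-plan the brain-field group and the
  spine-field group (parent + subfields) receive separate scalars: the
  smallest scalar giving 95%-of-prescription coverage to 100% of the brain,
  and to ≥ 95% of the canal, found by monotone bisection (relative
  tolerance 1e-4, the covering bracket end is returned). The solves are
  interleaved (spine → brain → spine) because each group contributes a small
  transmission background to the other's target. A final settle pass
  applies the same solve to the fraction-weighted composite (scalars
  clamped ≥ 1 so per-sub-plan guarantees are never undone): mixing three
  near-identical patterns can otherwise land a binding voxel fractionally
  below threshold. Composite dose = Σ (f_i/13) · D_i with f = (5, 5, 3).

## Synthetic phantoms

Phantoms are stylized geometric primitives — the planner consumes only
contours and densities, so image texture is irrelevant. Densities: soft
tissue 1.0 g/cc, lung 0.26, bone (vertebral column, mandible) 1.6, air 0;
the contrast flag adds +0.08 g/cc to the kidneys only. Key constructions:

* The mandible's inferior edge is a flat cross-section placed exactly on a
  voxel center, and the shoulder top and canal extent are one-sided with
  respect to the grid, so the pre-check measurements recover the spec
  parameters within one slice thickness.
* The brain-to-mandible distance is 13.5 cm + 0.25 cm per degree of chin
  tuck, so the cohort tilt range (0–15°) stays plannable while strong tilts
  cross the 20 cm rejection boundary.
* The brain sits ≥ ~1.2 cm beneath the scalp everywhere so that no brain
  voxel lies in the lateral fields' build-up region (a grazing surface
  voxel would otherwise dominate the 100%-coverage normalization).
* The spinal canal's superior end is placed ~1 cm caudal to the lowest
  feathered junction. With apertures conformed strictly to the brain and
  canal expansions, target tissue inside the junction corridor could never
  satisfy the coverage rules, so the corridor is kept target-free. Two
  consequences are documented rather than hidden: neck structures
  (thyroid) receive less dose than in real plans, and the cranio-spinal
  abutment is demonstrated dosimetrically with open jaw-defined fields
  while the conformal plan exercises it geometrically.
* Cohort sampling draws canal length 25–60 cm, tilt 0–15°, gap 1–4 cm and
  slice thickness 1–3 mm uniformly; these emulate the anatomical spread of
  a pediatric CSI population, including sub-1-cm gaps that the pre-check
  should reject. No age/size distribution is modeled.

What passing tests on these phantoms show: the planning *logic* — rules,
geometry, weighting, feathering, normalization, metrics — behaves as
specified on anatomies spanning the clinical parameter range. What they do
not show: dosimetric accuracy on real CT data, robustness to contouring
noise, curved or scoliotic spines, or TPS-grade dose computation.

## Numerical choices

* Margin expansions include boundary ties (distance ≤ margin + 1e-6 mm).
* Radiological depth uses a half-voxel self-contribution, making `d_eff`
  exactly consistent with a surface on a voxel boundary.
* V95 thresholds are inclusive (≥), so "100% of the brain" is exactly
  attainable; Dmax is the point maximum over mask voxels (no 0.03 cc
  smoothing convention).
* DVHs are cumulative with 0.1 Gy bins, volume-weighted by voxel volume.
* The dose engine works in float64 end to end; the full pipeline is a pure
  function of (phantom spec, prescription, limits, model parameters) and is
  bit-reproducible, which the suite checks by hashing the composite dose.

## Problem sizes

The default study phantom uses a 3 mm grid (≈ 1.6 M voxels, ~115×77×185);
a single-field plan (12 beam-dose evaluations plus normalization solves)
completes in a few seconds, and the full test suite — including two complete
plans and the property suites — in well under a minute. Coarser 5 mm grids
are used where only pipeline mechanics are under test.

## Known limitations

* The broad-beam dose model overstates entry (skin) dose for the PA spine
  field relative to a clinical TPS, so the 107% hotspot volume is larger
  than clinical plans would show; it is reported, not normalized against.
* Field-length limits are not enforced as hard constraints during
  construction; anatomies near the configuration cut-offs may produce jaws
  slightly beyond the nominal 36 cm aperture.
* Brain subfields (hotspot reduction) and physician-preference MLC edits
  (cribriform/lens trade-off) are out of scope, as is DICOM-RT export.
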