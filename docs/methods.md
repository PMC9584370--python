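# Methods

This note records the models, conventions and numerical choices behind
`blebquant`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and assumptions

The pipeline starts from *labelled segmentations* (or closed component
surfaces) of the glaucoma-implant complex: globe, plate, inner bleb,
outer bleb. It does not segment images; MR acquisition, intensity
modelling and manual delineation are upstream of this package. All
units are mm / mm³; world coordinates follow the voxel-center
convention `world = origin + index · spacing`.

## Surface extraction and the smoothing stand-in

Component surfaces are the 0.5-level marching-cubes iso-surfaces of the
binary masks, padded by one background voxel so masks touching the grid
boundary still close. The original analysis pipeline fitted subdivision
surfaces to manual segmentations with proprietary software; that step
is replaced here by a documented stand-in with a testable contract:
Taubin λ|μ smoothing (uniform Laplacian weights, λ = `strength` = 0.5,
μ = −(strength + 0.03), 10 iterations by default), whose enclosed
volume change is asserted to stay below 1% at default settings. The
stand-in reproduces the *function* of the original step (a smooth,
watertight boundary at sub-voxel fidelity), not its exact output, which
cannot be verified against the unpublished algorithm.

A degenerate but exact consequence of the 0.5-level convention: a
single isolated voxel meshes to the octahedron spanning its face
midpoints, volume h³/6. This is asserted as such in the tests.

## Voxelization

Closed surfaces are rasterized by parity ray-casting along z: the
crossing parities of each grid column classify voxel centers as
inside/outside, an unbiased volume estimator for closed surfaces
(inside iff the voxel *center* is inside; no partial-volume weighting).
The grid origin carries a deterministic sub-voxel offset so that rays
avoid lattice-aligned mesh vertices; if a ray still grazes an edge
(odd crossing count), the surface is nudged by 10⁻⁵ voxel and the fill
repeated, up to three times, before failing loudly. The default
analysis resolution is 0.1 mm voxel edge (10⁻³ mm³ per voxel),
configurable via `MeasureConfig.resolution`.

When several components are voxelized onto the shared analysis grid,
voxels claimed by two smoothed surfaces lie on a contested interface
band; they are set to background and resolved by the distance rule of
the gap-closure stage. A fixed-priority rule was tried first and
systematically inflated the thin plate by ~1% (the plate sits between
both blebs and won every interface tie).

## Gap closure

Adjacent hand- or pipeline-derived segmentations leave hairline gaps.
`close_gaps` fills a background voxel iff the gap it sits in — the sum
of its surface distances to the two nearest distinct components — is at
most `max_gap` wide, assigning it to the nearest component, ties to the
lower label id (globe < plate < inner < outer). Distances are
center-to-center Euclidean distance transforms minus half a voxel per
side (implemented as `d1 + d2 ≤ max_gap + spacing`). Labelled voxels
are never reassigned, so the operation is idempotent.

The default `max_gap` is 0.2 mm (two analysis voxels). A 0.3 mm reach
was evaluated and rejected: at that reach the fill annexes the seam
wedges that smoothing opens around the plate rim, biasing the plate
volume by up to +1.3% on recovery phantoms, while 0.2 mm closes the
actual inter-component gaps (sub-voxel to two voxels wide) and keeps
every compartment within ±1% of ground truth.

## Plate plane and complex height

"Perpendicular to the plate" is formalized as one global direction: the
minor principal axis of the plate voxel cloud (eigenvector of the
smallest covariance eigenvalue), sign-oriented from the globe center
toward the plate centroid. The fit refuses point clouds with fewer
than 10 voxels or with no unique minor axis (relative eigengap
< 10⁻⁶). For a curved plate this is a convention — the plate has no
single normal — but it is reproducible and matches the notion of one
measurement direction for the whole complex.

Height is a *through-thickness* maximum, not a global extreme
difference: bleb voxels are binned into columns one voxel wide in the
plane frame, and only columns containing both an inner- and an
outer-bleb voxel contribute a span, `max_n(outer) − min_n(inner) + h`.
The `+ h` corrects for voxel centers sitting half a voxel inside each
outer surface. When a segmentation has a single bleb label (merged
capsule), that label plays both roles. Column-wise matching prevents
pairing laterally distant surface points, which a global max-minus-min
would do.

## Merged and large-bleb classification

Fibrotic strands grow through the four plate fenestrations by design,
so inner/outer contact near a fenestration axis does not constitute
merged blebs. `detect_merged` flags face-adjacent inner/outer voxel
pairs farther than one fenestration radius + 2 voxels from every
fenestration axis (half-lines from the globe center). Without
fenestration geometry the rule degrades to any-contact and the
measurement provenance records the fallback.

The large-bleb rule is a strict threshold: total complex volume
(inner + outer + plate) > 1100 mm³.

## Clinical classifiers

Visual-field severity follows the Hodapp-Parrish-Anderson bands of the
perimetric mean deviation: mild (MD > −6 dB), moderate
(−12 < MD ≤ −6), severe (MD ≤ −12). The band definitions use strict
inequalities on both sides, leaving the edges −6 and −12 dB undefined;
this implementation assigns edge values to the worse category.

A duction is restricted when reference − measured ≥ 10°, the threshold
reflecting Goldmann-perimeter repeatability and age-related decline;
all restricted directions are reported. The normative excursions ship
as an editable CSV (`data/normative_ductions.csv`; elevation 43°,
depression 57°, adduction 45°, abduction 46°, oblique directions
40–53°) — conventional values standing in for the external normative
source, not measured cohort properties. The scalar "total motility
restriction" used in correlations is the sum of degrees lost over
*flagged* directions, keeping sub-threshold noise out of the total;
this is a convention, as no numerical definition is published.

## Cohort statistics

The variable→test mapping is fixed: unpaired t-test (age, IOP at four
timepoints, time since surgery; pooled variance by default, Welch by
flag), Fisher's exact test (all counts), Mann-Whitney (visual-field MD,
volumes, height), Spearman rank correlations (diplopia coded 1 vs
morphometry, total restriction vs volume, morphometry vs each IOP
timepoint). No multiplicity adjustment is applied (each variable is
tested separately, α = 0.05). Policies that vary across software are
pinned here:

* quartiles: inclusive linear interpolation between order statistics
  (numpy's default), recorded so spreadsheet-derived IQRs can be
  reconciled against other quartile rules;
* Mann-Whitney: exact enumeration for combined n ≤ 20 without ties,
  otherwise normal approximation with tie and continuity corrections —
  a 12 vs 18 comparison therefore uses the approximation;
* Spearman: average ranks for ties, exact permutation p for n ≤ 9
  (vectorized over all n! rank permutations), t-approximation above;
  with a binary variable it stays ranks-on-ranks (no point-biserial
  substitution);
* Fisher: two-sided p sums all hypergeometric tables with probability
  ≤ the observed table's.

scipy.stats provides the numerics behind this interface; brute-force
enumeration oracles in the test suite verify every policy on all
instances small enough to enumerate. The Fisher test's type-I error at
n = 12 vs 18 is intrinsically below the nominal 5% (discreteness); the
continuous-outcome tests calibrate to 5% ± 1.5 pp over 2000 null
simulations.

## Synthetic phantoms

A phantom is an analytic label map: spherical globe (default radius
11.5 mm); plate as a spherical-shell patch concentric with the globe
(it conforms to the sclera), default 18 × 18 × 1 mm, with four
fenestration cylinders of radius 0.6 mm along radial axes; inner and
outer bleb shells (defaults 2.5 and 1.5 mm thick) sharing the plate's
angular extent. Inner-bleb material fills the fenestrations (strands),
so the blebs touch there *by design*. With `merged=True` the bleb
patches extend 25% past the plate rim and meet around it. Default
generation spacing is 0.4 mm (a typical reconstruction resolution for
high-field orbital MRI); defaults produce compartment volumes
456/413/226 mm³ — inside the ranges reported for real cohorts.

Ground-truth volumes are generated-voxel counts × voxel volume (exact
by construction, additive by definition). Ground-truth height is the
*analytic maximum* span of the construction along the patch axis,
evaluated on a fine (d, φ) grid from the closed-form sphere/cone
boundaries. The naive "sum of thicknesses" holds only at the apex
column (exposed as `height_apex`): on a curved plate the span grows
off-apex, e.g. 5.73 vs 5.00 mm at defaults — a geometric fact, not an
estimator artifact.

What a green recovery test establishes — and what it does not: the
phantoms share the concentric-shell idealization, so recovery to 1%
demonstrates the correctness of the surface/voxelization/gap/height
chain, not robustness to real anatomy (asymmetric blebs, globe
deformation, segmentation error). Phantoms are label maps; no MR
intensities, noise or artifacts are simulated. Recovery studies
generate phantoms at the analysis resolution (0.1 mm): at 0.4 mm
generation the discrete construction itself quantizes surfaces by
±0.2 mm, which dominates any estimator at a 0.2 mm height tolerance.

## Cohort simulator

Total complex volume per group is log-normal — positive and
right-skewed like the reported distributions — parameterized from the
group median m and interquartile range (q₁, q₃): μ = ln m,
σ = ln(q₃/q₁)/(2z₀.₇₅). This matches the median exactly and the
interquartile *ratio*; a two-parameter family cannot also match both
quartile locations independently. Default medians/IQRs are
1023.3 (875.7–1750.5) mm³ for the diplopia group and
804.6 (755.1–923.4) mm³ for controls (group sizes 12 and 18). The
plate volume is drawn near-constant (280 ± 25 mm³ — one device model),
the remainder split between inner and outer bleb by a Beta-distributed
fraction. Height follows the cube-root link h = c·V^{1/3} + ε,
ε ~ N(0, 0.3 mm), with c calibrated per group so the median volume
maps to the median height (5.3 / 4.6 mm) — dimensional consistency is
the rationale; no published link exists. Clinical covariates (age,
IOPs, MD, duction restriction probabilities 10/12 and 6/18, sex, eye,
surgical technique, strand visibility, extra peribleb fluid) are drawn
per group from the baseline-table summaries. One seeded generator
drives everything; identical seeds give identical tables.

## Known limitations

* The subdivision-fitting stand-in matches the original step's contract
  (smooth watertight boundary, volume-preserving), not its output.
* The plate plane is a global convention; for strongly curved or folded
  plates a local-normal height definition could differ.
* The merged-height convention (single label in both roles) is a
  choice; how the original analysis handled merged capsules is not
  published.
* The simulator reproduces group-level summaries, not inter-variable
  correlation structure beyond the height–volume link; it cannot stand
  in for the deposited per-patient data when testing correlations
  against published values.
* Normative duction values are editable configuration, not a validated
  normative dataset.
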