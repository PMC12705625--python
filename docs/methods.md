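# Methods

## Problem and pipeline

The posterior limb of the internal capsule (pLIC) carries motor and sensory
projection fibers in a somatotopically ordered arrangement; on mean
diffusion-weighted images a hyperintense subregion (PICS) marks the
corticospinal territory and sits directly lateral to the Vim, making it a
candidate landmark for thalamic surgical targeting. The pipeline implemented
here takes a diffusion acquisition, computes the DiMANI contrast, fits a
tensor model, tracks fibers deterministically and probabilistically,
parcellates the capsule by cortical territory, summarizes each territory as
a per-slice center-of-mass skeleton, orders territories
anterior-to-posterior, and ranks stimulation sites by distance to those
skeletons.

Because no patient data ship with the package, every stage is exercised on
a synthetic phantom whose somatotopy is known exactly; the tests and the
acceptance analyses are parameter-recovery experiments against that ground
truth.

## Coordinate conventions

Voxel indices are 0-based; world space is RAS in mm ( +x lateral/right,
+y anterior, +z superior); an "axial slice" is a fixed index along the third
axis; anterior–posterior position means world y. bvec sign conventions are
taken from file as-is — phantom writer and pipeline reader share one
convention, so no flipping heuristics are applied.

## Synthetic phantom

Geometry: a 48×48×48 grid at 1.25 mm isotropic (the acquisition resolution
of the motivating protocol). Five bundles — tongue/larynx, head/face,
upper limb, trunk, lower limb — run inferior→superior as tubes of radius
2.5 mm at x = 12 mm (one "hemisphere"), crossing a capsule slab
(z ∈ [−10, 10] mm, x ∈ [8, 16] mm) at anterior–posterior offsets
+15, +7.5, 0, −7.5, −15 mm. Rank 1 = anteriormost is the ground truth the
parcellation must recover; the anterior placement of the oral territories
and posterior placement of limb/trunk follows the homuncular arrangement
reported for the capsule. Each tube ends in a cortical label disc (the seed
ROI for probabilistic tracking, ~13 voxels). Tubes may optionally bend
toward a displaced cortical position; the default phantom keeps them
vertical so tracking is well-posed.

Signal: single diffusion tensor per voxel. Inside bundles the tensor is
axially symmetric about the local direction with λ∥ = 1.7×10⁻³ and
λ⊥ = 0.3×10⁻³ mm²/s (typical healthy white matter, FA 0.799); outside,
isotropic λ = 0.8×10⁻³ mm²/s. Acquisition: 5 b=0 volumes plus directions at
b = 1500 s/mm² (50 by default; 30 in the test-scale experiments) spread by
electrostatic repulsion of antipodal pairs, deterministic per seed. Rician
noise is applied as S' = √((S+n₁)² + n₂²) with n ~ N(0, S0/SNR) when SNR is
finite.

PICS analog: the limb/trunk (corticospinal) bundles' capsule segments form
the PICS mask, inside which all diffusivities are scaled by
`pics_lambda_scale` = 0.7. Reduced diffusivity raises every b>0 signal, so
the mean-DW (DiMANI) image is hyperintense there — the mechanism is a
modeling choice; only the hyperintensity itself, not its biophysical cause,
is established for the real landmark, and no intensity ratio is reported
for it, so 0.7 is a free parameter chosen to give a clearly visible
(~1.3×) contrast, not a fit.

Stimulation sites: two, placed 4 mm medial to the capsule slab at the
head/face bundle's y offset, 3.7 mm and 2.3 mm above the target-depth plane
(z = 0) — the geometry of the motivating case study, where stimulation at
those depths elicited tongue/face contractions.

What the phantom does **not** emulate: crossing fibers, gyrified cortex,
partial-volume gradients, distortion/motion artifacts, or anatomical
variability. Passing the recovery experiments therefore shows the pipeline
is correct and stable under its own assumptions (single-tensor voxels,
well-separated bundles), not that tractography resolves real capsule
somatotopy; the crossing-fiber regime is a known failure mode of
single-tensor tracking.

## DiMANI

Voxelwise arithmetic mean over exactly the volumes with b > 100 s/mm²
(threshold inclusive-exclusive as stated: "b > 100"). The complementary
b ≤ 100 mean gives the b0 image. Adaptive equalization is 3-D tiled
CLAHE (scikit-image backend, default 8×8×8 tiles, clip 0.01) with trilinear
tile-CDF blending; it exists solely for display — every quantitative
operation (contrast ratio included) uses raw intensities. Note one
consequence of blending: output is monotone in input within tile interiors
but not across blend zones between tiles with different histograms.

## Tensor model

Weighted log-linear least squares per voxel (weights S², the standard
first-order noise correction in log space), requiring ≥ 6 distinct DW
directions plus a b0; nonpositive signals are excluded per voxel and voxels
with fewer than 7 usable measurements are flagged degenerate (zero tensor,
FA 0). Negative eigenvalues are clamped to zero after the fit. Nonlinear
fitting was deliberately not used: at phantom SNR the weighted LLS solution
is accurate (noiseless recovery to <1e-6 relative; median eigenvalue error
<10% at SNR 20) and exactly reproducible.

Otsu threshold: 256 equal bins on [0, max], between-class variance computed
from bin counts and centers via cumulative sums, argmax taken at the first
maximizing bin edge. Empty bins between well-separated classes make the
objective exactly flat over a plateau; first-edge tie-breaking makes the
randomized threshold range (0.5–0.7 × Otsu) reproducible. The test oracle
recomputes the exhaustive search in exact rational arithmetic.

## Deterministic tracker

Streamlines launch from uniformly jittered sub-voxel positions in seed
voxels and propagate both ways along the trilinearly interpolated
principal-direction field. Interpolating axial (sign-free) data requires
aligning the eight corner vectors to the previous direction before
weighting. Per streamline, the FA threshold is drawn once from
U(0.5, 0.7)×Otsu(FA) and the angle threshold from U(45°, 90°); termination
on sub-threshold FA, super-threshold turning angle, leaving the volume, or
the step cap. The step equals the voxel spacing by default, so consecutive
points are exactly one step apart (the final point is the last in-volume
point — no partial step is taken). A pathway entering an exclusion region
is discarded whole. If the FA map is constant (synthetic fixtures), the
Otsu scale falls back to that constant. The midline exclusion wall is one
voxel thick at world x ≈ 0 from the top of the volume down to just above a
configurable z level, leaving the inferior crossing open.

## Probabilistic tracker

Contract-level emulation of an FSL probtrackx run: per seed voxel,
`n_samples` samples propagate both directions at 0.5 mm steps; both halves
are concatenated before evaluation; a sample touching any avoidance mask is
discarded; a sample counts only if it intersects the waypoint; the map
records, per voxel, the number of counted samples that visited it (each
sample contributes a voxel at most once).

Orientation uncertainty is parametric rather than bootstrap-posterior-based
(the single-tensor phantom has no crossing fibers to justify the latter): a
Watson-type axial distribution about the local principal direction, sampled
as a tangent-plane Gaussian with variance 1/(2κ), matching the Watson
small-angle behavior, with κ = κ₀·FA/(1−FA+1e-6). κ₀ defaults to 30 —
at bundle FA 0.8 that gives ≈ 3.5° angular SD per step, enough dispersion
to spread counts across the bundle cross-section without leaking through
the isotropic background (whose FA floor, 0.01, is the single-fiber mapping
of the "subsidiary fiber volume threshold"). κ₀ = ∞ degenerates exactly to
the mean direction, which pins the equivalence oracle against the
deterministic tracker. A draw whose cosine against the previous direction
falls below 0.2 (≈ 78.5° max turn, the named tool's documented default
meaning) terminates the sample without resampling. Loop checking records
the sequence of distinct voxels entered and terminates a sample re-entering
a voxel it previously left; consecutive steps inside one voxel do not
trigger it. Counts are kept raw (unnormalized); the 80% parcel rule is
scale-invariant either way.

## Parcellation

Parcels: keep in-capsule voxels with counts ≥ 0.8 × the in-capsule maximum
(strict ≥; out-of-capsule peaks are ignored). The frac = 0 edge keeps the
whole capsule, since every count is ≥ 0. Skeletons are computed from the
**unthresholded** in-capsule distribution — one count-weighted centroid per
axial slice with nonzero counts — reading the thresholded parcels and the
skeletons as two renderings of the same data rather than chaining them.
Ordering scores each territory by the weighted mean world-y of its skeleton
points, anteriormost (largest y) first; exact ties are broken
lexicographically and flagged. Overlap is quantified as pairwise Dice (any
monotone overlap measure would do).

## Clinical mapping

Mask volumes are voxel count × |det| of the affine's 3×3 block. Cohort
summaries use the arithmetic mean and sample SD (n−1); the within-patient
left−right difference is reported descriptively only. The packaged cohort
table keeps disease durations as free text because two entries are ranges.
Site-to-territory distances are point-to-point-set minima against skeleton
points (deterministic and rigid-invariant), ranked ascending with exact
ties flagged; a mesh-to-mesh distance would only matter for claims finer
than nearest-region, which is all that is made.

## Reproducibility and problem sizes

A single global seed fans out to named substreams (CRC-derived
SeedSequence, all below 2³¹), one per module and per experiment repeat;
fixed seeds reproduce every stage bit-for-bit and the run manifest records
SHA-256 checksums to prove it. The recovery experiment uses 20 phantoms ×
(noiseless, SNR 20), 30 directions, 500 samples per seed voxel, and
~13-voxel cortical seed discs — sizes chosen so the full experiment runs in
a few minutes on one CPU while keeping per-map convergence high (two
independent-seed maps correlate > 0.95 in-capsule). Randomized per-streamline
threshold draws are summarized (min/mean/max) in the run log for audit.

## Known limitations

* Single-tensor model throughout: no crossing-fiber ODFs, no multi-shell
  support, no free-water compartment.
* The probabilistic sampler models dispersion parametrically; it is not a
  reimplementation of bedpostx/probtrackx posteriors, and κ₀ has no direct
  counterpart in those tools.
* Euler integration for both trackers (step ≤ voxel size); curved-field
  accuracy is first-order.
* The phantom's capsule is a box and its cortex a disc; registration,
  template building, and cross-subject statistics are out of scope.
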