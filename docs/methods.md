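# Methods

`stptquant` re-creates, at desk scale, the analysis chain used to quantify
fluorescent signal across the whole mouse brain from serial two-photon
tomography (STPT) data: preprocessing of raw coronal mosaics, supervised
pixel classification, registration into a labeled reference atlas,
region-wise aggregation, and voxel-level validation. This note records the
models, parameter choices and numerical conventions the package is built on,
and what its synthetic phantoms do and do not demonstrate.

## Acquisition model and preprocessing (`volio`)

STPT is block-face imaging: a few optical planes are acquired just below the
freshly cut tissue surface, then a vibratome removes the imaged slab. The
`OpticalSchedule` captures this geometry — by default three optical planes at
25/50/75 µm below the surface, a 75 µm cut, 0.875 µm/px laterally — so that
`plan_acquisition` can state exactly how many 2-D images a brain produces
(e.g. 190 physical sections × 3 planes = 570 images).

Conventions, fixed once and shared by every module:

* axis order `(section, row, col)` = (anterior→posterior, dorsal→ventral,
  left→right); 0-based indices; voxel center at `index × spacing`;
* raw channels 16-bit, probability maps 8-bit; out-of-range values are
  clipped, never wrapped;
* rounding of float intensities to integer storage is round-half-away-from-
  zero (so 127.5 → 128).

Flat-field correction divides by the unit-mean illumination profile, making
a uniform profile a no-op. The mosaic stitcher places tile (r, c) at offset
`(r·(h−ov), c·(w−ov))` and resolves overlaps first-writer-wins in row-major
order — a deliberate simplification of the vendor stitcher that is
deterministic and exactly invertible on sliced test images; it performs no
sub-pixel tile registration. The MIP collapses each physical section's
optical planes by per-pixel maximum; the stored axial spacing of a MIP stack
is the cut thickness (the finer pre-MIP sampling survives as schedule
metadata). Downsampling (e.g. 0.875 → 1.5 µm/px) uses area interpolation —
each output pixel averages its exact source footprint — because it preserves
summed signal, the quantity the pipeline ultimately reports; a constant image
is preserved bit-exactly.

## Pixel classification (`classify`)

A random forest is trained on sparse pixel annotations over a multi-scale 2-D
feature bank computed per section and per channel: raw intensity plus, at
each scale σ ∈ {1, 2.5, 5} px (configurable), Gaussian smoothing, Gaussian
gradient magnitude, Laplacian of Gaussian, both Hessian eigenvalues and both
structure-tensor eigenvalues — 22 features per channel at three scales, the
standard interactive-segmentation bank. Forest defaults: 100 trees,
unbounded depth, bootstrap resampling, √d feature subsampling, fixed seed
recorded on the model; training is exactly reproducible. One model serves a
whole cohort of brains and the model object carries its cohort binding.

Class probabilities are exported per label as 8-bit maps: stored value
`round(p·255)` (half away from zero), so 0 ↔ 0 %, 255 ↔ 100 %, and the
quantization error is at most 0.5/255 per voxel. Any argmax-style summary
breaks ties toward the lowest label index; quantification itself never uses
argmax.

## Registration (`register`)

The atlas template is the fixed image and the sample's red (tissue
autofluorescence) channel the moving image; the fitted chain therefore maps
atlas coordinates to sample coordinates, which is simultaneously the
"register the sample into the atlas" orientation and the resampling
transform that pulls sample-space probability maps onto the atlas grid.

Three stages run in a fixed order, each initialized from the previous:
rigid (6 DOF), affine (12 DOF, initialized from the rigid pose and therefore
subsuming it in the final composition), and a cubic b-spline refinement
composed with the affine. Every stage maximizes Mattes mutual information
(32 histogram bins) estimated from randomly sampled coordinates (2,048 per
level by default, seeded) over a multi-resolution pyramid — 6 levels by
default for full-size data, automatically reduced so no level drops below 8
voxels (64-section toys get 4). The optimizer is regular-step gradient
descent with parameter scales normalized to physical shift: the learning
rate is an initial step of 0.05 mm, halved on oscillation. Restricting
sampling to sub-regions of 2 × 2 × 4 mm is realized as a union of randomly
placed boxes applied as the metric's fixed-image mask per stage; volumes no
larger than one region (all toys) are unrestricted. The b-spline control
grid is 0.5 mm per axis, capped at a quarter of the volume extent so toy
volumes get a meaningful grid.

**A metric artifact worth knowing about.** On images with strong iid voxel
noise, linear interpolation at half-voxel offsets averages the noise and
sharpens the joint histogram, so sampled mutual information *genuinely
prefers* ~0.5-voxel misalignments; a flexible transform will chase this
everywhere and can end up less accurate than the affine it started from.
The b-spline stage therefore runs only on the two finest pyramid levels with
a small step (0.01 mm), a 4× denser coordinate sample and an extra 0.5 voxel
of pyramid smoothing. This mattered at phantom scale, where noise is a
larger fraction of tissue contrast than in real 16-bit acquisitions; it is a
property of the metric, not of any particular library.

Lesioned tissue is not masked during registration (matching practice; an
optional exclusion mask exists, default off). The chain serializes to a
plain-text parameter file (stage name, transform class, fixed parameters,
parameters) readable without the package. Warping uses linear interpolation
for probability maps and intensity volumes and nearest-neighbor for integer
masks; out-of-field voxels are 0.

## Quantification (`quantify`)

On the atlas grid, each region's signal is reported two ways, and both are
carried through every table because real pipelines are ambiguous about which
they report: the **summed probability mass** (Σ v/255 over member voxels)
and the **thresholded voxel count** (voxels with v/255 ≥ threshold; default
threshold 5 % of the 8-bit range). Each is normalized per region volume into
a density (per mm³); region volume comes from the atlas label volume itself
(voxel count × voxel volume), never a published table. Background (ID 0) is
reported as its own row so total-mass conservation is checkable; hierarchy
roll-up adds each region's direct voxels to the sum over all descendants;
hemispheres are split at the atlas midline with voxels exactly on the
midline assigned left. Heat-map tables are dense samples × regions matrices
(missing combinations are 0, not NaN) rendered with matplotlib.

A caution on the two readouts: after any non-identity resampling, linear
interpolation surrounds each near-binary object with a partial-volume shell.
At a low threshold such as 5 %, that shell inflates the *count* readout by
roughly the objects' surface-to-volume ratio, independent of registration
quality; the *mass* readout is conserved by interpolation and is the
unbiased estimator of object volume across a warp. Consequently the
end-to-end recovery checks compare mass, while thresholded-count recovery is
validated on maps that have not been resampled.

## Validation (`validate`)

Observer-style binary masks are compared voxel-wise against probability maps
across a strictly increasing threshold sweep. Per threshold: TP/FP/FN/TN,
the four canonical rates (TPR, FNR = 1−TPR, FPR with reference-negative
denominator, TNR), precision, F1 = 2TP/(2TP+FP+FN) and the Matthews
correlation coefficient. Zero-denominator conventions: F1 is NA when
TP+FP+FN = 0; MCC is 0 when any confusion-matrix marginal is 0. Raw counts
are always emitted so any alternative rate convention can be recovered. The
operating point is evaluated at the 5 % threshold whether or not it is in
the sweep. Subregion sampling is a seeded random-crop utility (default 8
crops of ~1 Mpx, clipped to the section size); crops without any
reference-positive voxel are retained deliberately — negative-control
subregions are informative — and per-crop metrics are summarized as
mean ± SEM. Automated-versus-manual count comparison is ordinary least
squares with intercept (slope p-value two-sided; a constant response is
R² = 0 by convention).

## The phantom (`phantom`) — what it emulates and what it does not

The toy atlas tiles each hemisphere into AP slabs of deliberately unequal
width (widths ∝ k+2) mirrored about the sagittal midline, under a two-level
ontology (root → hemisphere groups → leaves). Unequal widths plus smooth
dorsoventral and mediolateral intensity gradients make the template's MI
landscape unimodal in translation — equal slabs were shift-ambiguous because
mutual information is blind to which intensity maps to which.

The rendered stack has two channels at 10 µm isotropic (default
64 × 96 × 96): a red tissue channel (autofluorescence modulated by the
template at 4× the baseline level, so anatomy sits well above the noise
floor, as in real autofluorescence imaging) and a green signal channel with
hard-sphere cell bodies (default radius 20 µm, 25 per leaf), 1-voxel-radius
random-walk processes on a subset of cells at intermediate intensity, an
optional bright ellipsoidal stroke patch that suppresses cell placement
around it, and additive Gaussian noise (σ = 1000 counts against a 17,000-
count cell-to-tissue contrast). A requested deformation acts on geometry —
cell positions and the label field are displaced by a smooth, boundary-
tapered random field and objects are re-rendered crisply — because real
tissue deforms under sharp optics; resampling a rendered image would
introduce interpolation halos no microscope produces.

Annotations emulate a brush-wielding annotator plus the iterative
retrain-until-clean loop of interactive classification: 2,000 seeded pixels
per label by default, spread over ≥3 sections, with half of the tissue
(autofluorescence) picks drawn from the 2-voxel rim around objects. Those
rim "hard negatives" are what makes the trained forest conservative at the
5 % threshold; with 10× fewer annotations the same forest over-segments a
halo around every cell (~40 % count inflation at 200 pixels/label vs ~8 % at
2,000).

What passing phantom tests show: the arithmetic of every kernel, exact
conservation and hierarchy identities, recovery of known rigid/affine/
nonrigid geometry under realistic noise, and end-to-end per-region recovery
within 10 % with correct ranking. What they do not show: performance under
real tissue heterogeneity (vessels, meninges, ventricles — known confounds
deliberately not modeled), real annotation noise and inter-observer
disagreement, stroke-distorted anatomy beyond a bright ellipsoid, or the
paper-scale data volumes. The validation-rate magnitudes on phantoms
(F1 ≈ 0.97 at the operating point) are far above what heterogeneous real
data yields and must not be read as expected real-world performance.

## Problem sizes and runtime

Default test and acceptance problem sizes: 64 × 96 × 96 voxel phantoms
(~0.6 M voxels) for classification, registration and end-to-end recovery;
32 × 48 × 48 for the double pipeline-determinism run; 100-instance oracle
sweeps on ≤ 10 × 10 grids; 1,000-instance MCC chance-level sweeps at 32 × 32.
These sizes keep the full suite in a few CPU-minutes while leaving every
stage non-trivial (hundreds of cells, 4-level pyramids, ~4³ b-spline grids).

## Orchestration and provenance (`pipeline`)

A single YAML config names samples (each bound to a cohort), the per-cohort
model or training annotations, the atlas and the output directory. Runs are
auditable: the manifest records tool version, config hash, all seeds and a
SHA-256 for every artifact; re-runs skip stages whose input hashes and
output checksums are unchanged; a failing sample is recorded and does not
stop the others. Two provenance rules are enforced in code: a cohort's model
is applied unchanged to every stack in the cohort, and the transform chain
fitted on the red channel is the one applied to every label's probability
map. With fixed seeds the quantification CSV is byte-identical across runs.

## Known limitations

* The stitcher is a simplified grid stitcher (stated blend rule, no sub-pixel
  alignment) standing in for the vendor tool.
* SimpleITK draws metric samples once per pyramid level rather than per
  iteration; the per-iteration "random coordinate" behaviour of elastix is
  approximated, and sample-region restriction is per-stage, not per-iteration.
* Thresholded voxel counts are not comparable across a resampling step (see
  the quantification caution above); compare masses, or threshold before
  warping.
* The phantom's stroke is a bright ellipsoid, not a texture model of infarcted
  tissue; registration across severely distorted anatomy is untested.
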