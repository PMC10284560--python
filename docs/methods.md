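# Methods

`aztomo` quantifies presynaptic architecture in cryo-electron tomograms: it
detects the pleomorphic density bridges that link synaptic vesicles (SVs) to
the active-zone (AZ) membrane (*tethers*) or to each other (*connectors*),
measures vesicle distances and bridge lengths, classifies vesicles into
tethering states, and compares experimental conditions with planned
nonparametric statistics. This note records the models, conventions, and
numerical choices behind each stage, and what the bundled synthetic phantoms
do and do not establish.

## Coordinate and contrast conventions

Volumes are voxel-indexed, 0-based, in `(z, y, x)` order; nm appear only in
reported quantities. Reconstructed cryo-ET density is *structure-low*:
protein and membrane are darker (lower values) than background, so
segmentation thresholds from below (`density <= t`). The
`DensityVolume.structure_low` flag records this convention explicitly.

At the ~1.4-1.8 nm voxel sizes of 4x-binned tomograms, no sub-voxel
refinement is attempted anywhere; every distance and length carries an
uncertainty of about one voxel, and interval tests use one voxel diagonal
(`voxel * sqrt(3)`) as their slack.

## Hierarchical connectivity segmentation

A bridge is a connected cluster of dark voxels linking two boundaries.
Because any single threshold is arbitrary, components are computed at an
increasing threshold series; each bridge is reported as the component at the
*lowest* threshold at which its boundary contacts form a valid signature
(the bridge "core"). Components at higher thresholds that contain an
already-reported core are that core's dilations and are skipped, so reported
segments are mutually disjoint.

- Contact signatures: exactly {one SV, AZ membrane} is a tether; exactly
  {two SVs, no membrane} is a connector; anything else (three or more
  boundaries, a single boundary, SV plus non-AZ membrane) is rejected rather
  than split — splitting multi-way junctions would require a watershed-style
  decision the data do not constrain.
- Connectivity is 26-neighbor for components and for boundary contacts: the
  permissive choice that preserves thin diagonal bridges at these voxel
  sizes.
- Analysis region: presynaptic non-boundary voxels within 250 nm of the AZ
  membrane, restricted to the presynaptic connected compartment (identified
  by the vesicles it contains, by a reference point, or by AZ adjacency), so
  the synaptic cleft and postsynaptic side never contribute.
- Threshold schedule (not constrained by any published value; exposed in
  config): 24 evenly spaced quantiles of the region density between q=0.02
  and q=0.5. A quantile ladder is invariant to affine contrast changes; the
  q=0.5 cap keeps the top threshold at the median, above which foreground
  percolates and components lose valid signatures anyway. On near-binary
  volumes (noiseless phantoms) the ladder collapses and an evenly spaced
  ladder over the density range is used instead; a constant-density region
  yields zero segments.

The implementation is validated voxel-for-voxel (components, validity
thresholds, kinds, contact sets) against an exhaustive per-threshold
brute-force oracle on randomized small grids.

## Morphometry

**Distances.** The SV-to-AZ distance `d` is the shortest edge-to-edge
distance between the vesicle and AZ voxel sets: the minimum center-to-center
distance minus one voxel, clamped at zero, so adjacent or overlapping
objects are at `d = 0`. Computed from a single Euclidean distance transform
of the AZ label.

**Bridge lengths.** The length `L` of a tether or connector is the minimal
geodesic path through the segment's own voxels — 26-neighbor steps weighted
1/sqrt2/sqrt3 voxels — between its two boundary-contact voxel sets. This
makes curvature contribute to length, unlike a chord; `L` for a straight
rod approximates its span, and `L >= d` (up to discretization) for every
tether. Exact agreement with a networkx Dijkstra oracle is tested. Two
caveats are inherent to the definition: contact regions have voxel-level
extent, so `L` measures the *minimal* span of a bridge (a bridge hugging a
boundary contacts it early and measures short), and a strongly bent tube
loses about `rod_radius x turn angle` to corner cutting.

**Classification.** All interval bins are left-closed/right-open, applied
uniformly: tether length classes short [0,6), intermediate [6,12), long
[12,24) nm, with >= 24 nm retained as "extra"; tethering states by AZ
distance SNAP25-dependent [0,5), intermediate [5,10), Munc13-independent
[10,inf) nm; cytoplasmic zones proximal [0,45), intermediate [45,75),
distal [75,250) nm. Counts: each tether increments exactly one vesicle,
each connector exactly two; "tethered" means >= 1 tether and "multiply
tethered" >= 3.

**Layers and AZ area.** The presynaptic cytoplasm *including* SV voxels is
partitioned into 1-voxel-thick layers by distance to the AZ membrane (layer
k covers (k-1, k] voxels), and the per-layer SV-occupied fraction is
reported; the partition makes voxel conservation exact by construction. AZ
surface area defaults to the marching-cubes mesh of the cytosol-membrane
interface restricted to AZ-adjacent triangles (accurate for oblique and
curved membranes); voxel-face counting with the stereological 2/3
correction is available as a fallback. Surface concentration is proximal
SVs per um^2 of AZ area.

**Vesicle spheres.** Vesicles traced as a maximum-diameter contour are
extended to spheres by a least-squares (Kasa) circle fit; the radius is to
the traced membrane midline (inner/outer leaflet is not distinguished at
this voxel size). In phantom pipelines the sphere-equivalent radius is
recovered from the labeled voxel count.

**Model span screen.** For candidate bridging proteins, `model_span`
measures the minimal inter-atom distance between two residue selections of
an atomic model (e.g. the C2B domain and the MUN C-terminal end of the
Munc13 C1C2BMUN fragment, PDB 5ue8; default residue ranges 678-820 and
1725-1735 follow the model's annotated domains and are configurable).
`tether_accommodates` then asks whether any geodesic between a tether's
contact sets is at least that span — a purely geometric screen that a
curved tether can pass even when its chord is shorter than the span; it
does not replace rigid-body density fitting. The deposited coordinates are
downloaded on demand (`aztomo.structures.fetch_munc13_model`); a clearly
labelled synthetic rod-plus-domain stand-in with an analytically known span
exercises the measurement machinery where the download is unavailable.

## Statistics

Per-structure variables (distances, lengths, per-vesicle counts) are pooled
across synapses within a condition; fraction variables are computed per
synapse and summarized by the SEM between synapse means (undefined, not
zero, for a single synapse). Comparisons are restricted to a configured
list of planned, orthogonal pairs — never expanded all-vs-all, which is
also why no multiple-testing correction is applied. Test choice by variable
kind: Student's t (equal variances; Welch by flag) for approximately normal
continuous values, Kruskal-Wallis for per-vesicle counts (retained even for
two groups), Pearson's chi-squared without continuity correction for
frequencies (flagged when an expected cell is < 5, degenerate all-zero
columns report p=1), and Pearson correlation for associations; all
two-tailed. Each statistic is tested against its textbook closed form to
1e-10, and the chi-squared fraction test is calibrated: under a shared
distance distribution its type-I error is 0.05 within binomial error over
500 replicates.

**CDF inflection points** are the midpoints of maximal contiguous regions
where the derivative of the smoothed empirical CDF (moving average, default
bandwidth 1 nm, configurable) exceeds half its maximum; samples whose steep
region spans most of the range (near-uniform) report no inflection rather
than an arbitrary midpoint, and multimodal samples report one midpoint per
region.

**Orientation equalization.** To balance missing-wedge orientation effects
between conditions, synapses are removed one at a time — the synapse whose
angle is most extreme relative to the grand mean, never emptying a group —
until all pairwise group-mean differences are within tolerance (default 5
degrees; the published procedure states no tolerance). Removals are logged,
deterministic, order-invariant, and applied only to tether/connector
analyses, not to distance or layer analyses.

## Synthetic phantoms

The phantom generator emulates exactly the structures the pipeline
measures: a plasma-membrane slab with a square AZ patch, spherical vesicles
at prescribed surface-to-surface distances, and bridges rasterized as tubes
(spherical brush of >= 1 voxel radius) swept along polylines, so every
planted arc length is well-defined. Labels carry boundaries only; bridges
exist only as grayscale density, as in real data. Optional degradations:
additive Gaussian noise (the default sigma = 0.25 against a contrast of 1,
an SNR of 4, is a generator choice — tomogram SNR is not published — and is
exposed in config) and a Fourier missing-wedge mask for a +-halfangle tilt
range. Everything is seeded and bit-reproducible.

The reference validation phantom (128^3 voxels at 1.4 nm) plants six
vesicles spanning all three tethering states (3.6-17.4 nm), eight tethers
including a bent one whose geodesic strictly exceeds its end-to-end chord,
and four connectors, with membrane and sphere surfaces placed between voxel
centers to keep voxelization bias near half a voxel. Condition-level
simulations sample SV distances directly from truncated Gaussian mixtures
(peaks near 6 nm for a tethering-competent condition and 16 nm for a
tethering-deficient one, sd 2 nm) without rasterizing volumes.

What phantom tests show: exactness of the segmentation selection rule,
recovery of planted geometry within discretization limits, conservation
properties, and statistical calibration. What they do not show: performance
under real tomogram artifacts (CTF, reconstruction noise correlations,
membrane crowding, manual-segmentation error); the Gaussian-noise SNR sweep
bounds robustness only to uncorrelated noise.

## Problem sizes in the validation suite

The bundled checks run on one CPU in minutes: 50 random 10^3 grids for the
oracle equivalence, one noiseless and ~20 noisy 128^3 phantoms for recovery
and consistency, and 500 replicates of n=300-per-condition distance samples
for the calibration and discrimination checks. These sizes were chosen so
the whole suite stays desk-scale while every estimate's sampling error is
far below its test tolerance.

## Known limitations

- Lengths are minimal-span measurements: extended protein-lipid contact
  regions shorten `L` by up to ~2 voxels, and sharply bent bridges lose
  ~rod_radius x turn angle to corner cutting.
- Multi-boundary density junctions are rejected, not split; bridge counts
  are therefore conservative where bridges genuinely branch.
- The accommodation screen is geometric only and one-sided relative to full
  rigid-body fitting.
- The AZ membrane, vesicle traces, and compartment labels are taken as
  given (manual segmentation upstream); label errors propagate directly
  into distances and signatures.
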