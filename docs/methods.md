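# Methods

This note documents the models, algorithms and design choices behind
`cortiquant`, in the order the pipeline runs them.

## Coordinate conventions

Volumes are `(z, y, x)` with `z` the proximodistal slice index and
isotropic voxels (anisotropic headers are rejected). Physical coordinates
are µm from the voxel center of index 0. The anatomical **anterior**
direction is `+x` by default (configurable); polar angles θ are measured in
the slice plane from anterior, positive toward `+y`, reported in
(−180°, 180°]. *Posterior* means |θ| > 90°, with the boundary |θ| = 90°
counted as anterior (strict inequality). Anatomical direction labels on a
CT grid are ultimately a registration choice; the pipeline only assumes
they are fixed and consistent per study.

## Phantom generator

The generator emulates a nano-CT acquisition of a juvenile mouse fibula
diaphysis: voxel size defaults to 1.27 µm; the cortex is a hollow elliptic
cylinder (default outer semi-axes 105 × 90 µm, inner 65 × 55 µm) whose
center may drift linearly across slices (a tilted shaft). Carved into the
wall are:

- **canals** — straight circular tubes, one per `(θ, z_frac, diameter,
  inclination)` spec, spanning the wall from just inside the endosteal to
  just outside the periosteal surface. Straight tubes are a deliberate
  idealization: real canals are irregular, but straight geometry makes
  every downstream quantity analytically checkable;
- **osteocyte lacunae** — axis-aligned ellipsoids (default semi-axes
  5 × 3 × 3 µm, ≈190 µm³) rejection-sampled strictly inside the wall,
  clear of every tube and of each other;
- optionally one **nutrient foramen** — a wider tube (default 60 µm).

Carving is pure masking (a voxel is void if any structure covers it), so
the volume is invariant to the order of canal specs. After carving, the
two-level image (bone 200, background 50) receives a Gaussian partial-
volume blur (default 0.5 voxel; physically detailed intensity formation of
a real scanner is out of scope) and optional additive Gaussian noise. The
seed is a required field; identical specs are bit-reproducible. If two
structures merge into one connected component the generator raises instead
of returning an ambiguous truth ledger.

Shell geometry, closing radius and foramen size are coupled: the ball
closing (below) must have radius ≥ the foramen radius (to seal it) and
≤ the minimum radius of curvature of the endosteal ellipse, b²/a (or the
closing would clip the marrow cavity at its pointed ends). The defaults
(closing 40 µm, foramen 60 µm, inner 65 × 55 µm ⇒ b²/a ≈ 46.5 µm) satisfy
both with margin.

The random-spec builder places tubes at jittered even angular spacing with
a guaranteed pairwise 3D clearance between tube axes, spreads z-levels so
angular neighbours are offset proximodistally, and keeps every canal ≥ 3°
away from the ±90° boundary so the truth posterior classification can
never be flipped by sub-voxel centroid rounding. The paired-contrast
builder (`posterior_contrast_spec`) places an exact number of posterior
canals with an 8° boundary margin, giving specimens with posterior
fractions near 8% (1/12-like) and 35% (5/14-like) — the contrast between
normally loaded and unloaded bones.

**What the phantom does not emulate:** canal tortuosity and branching,
phase-contrast fringe artifacts, ring artifacts, detector response, and
beam hardening. Passing recovery tests on phantoms therefore demonstrates
the correctness of the geometry/statistics chain, not robustness to every
real-scanner artifact.

## Segmentation

1. **Bone threshold.** Global threshold, `values ≥ t`. The automatic
   method minimizes intra-class intensity variance over the grey-level
   histogram (Otsu's criterion, via scikit-image); a fixed threshold can be
   supplied instead. Constant volumes are rejected; the threshold used is
   logged and stored in the mask metadata. Note the minimizer is not
   unique when the histogram has an empty gap between modes; any threshold
   inside the gap yields the same segmentation.
2. **Cortex region.** Morphological closing of the bone mask with a
   Euclidean ball (default radius 40 µm), implemented with two exact
   distance transforms rather than an explicit structuring element. The
   working array is padded: laterally with background (air), along z by
   edge replication, because the diaphysis continues beyond the scanned
   stack. The closed region is the shell with canals, lacunae and the
   foramen sealed.
3. **Marrow.** The largest connected non-region component not touching the
   lateral grid faces. It must be extracted from the *closed* mask: on the
   raw bone mask the cavity is connected to the exterior through every
   trans-cortical canal. Ties between equal-size interior cavities are an
   error, as is their absence.
4. **Void components.** 26-connected components of
   `cortex_region ∧ ¬bone ∧ ¬marrow` (26-connectivity merges diagonal void
   chains, matching visual canal continuity; bone is treated
   6-connected). Discrete closing leaves a sub-voxel film of "void" along
   the smooth segmented surfaces; a one-voxel morphological opening strips
   it, and a residual depth filter (a real void must reach > 1.8 voxels
   into the region) removes any isolated leftovers. Surface contact flags
   use 2-voxel adjacency: *periosteal* = adjacent to the exterior space,
   *endosteal* = adjacent to the marrow.
5. **Classification.** *Trans-cortical* components (both contacts) are
   **foramen** if diameter ≥ 50 µm (inclusive), **canal** if additionally
   volume > 2000 µm³, otherwise lacuna. Non-trans-cortical components are
   **lacuna** when ≤ 2000 µm³ and **partial** otherwise; partials are
   reported but never counted as canals. Both cutoffs are config-exposed:
   2000 µm³ is a generous upper bound for an osteocyte lacuna, 50 µm a
   conservative lower bound for a nutrient foramen in juvenile mouse
   fibulae.

## Canal geometry

- **Marrow axis:** the line through the marrow area centroids of the first
  and last slices; per-slice centroids are kept for diagnostics only. The
  per-z reference point for orientation is taken on this two-point *line*,
  not on the per-slice centroid.
- **Diameter:** the canal axis is estimated from the second central
  moments of the component's voxels. Every eigenvector is tried as a
  candidate axis — for a short wide tube (the foramen) the largest moment
  lies *across* the tube, so picking the top eigenvector blindly cuts the
  tube lengthwise — and the candidate whose perpendicular cross-section is
  most circular wins. The cross-section is the slab of voxels within
  ±2.5 voxels of the centroid plane perpendicular to the axis (thick
  enough to average lattice aliasing, thin enough to stay clear of the
  beveled ends where the tube meets the curved surfaces); the diameter is
  the minor axis `4·sqrt(λ_min)` of its moment-matched ellipse. Degenerate
  components fall back to the equivalent-circle diameter of their largest
  single-slice section, flagged. Cross-sections are canal-perpendicular,
  not z-slices; the choice is recorded in output metadata.
- **Orientation:** θ = signed angle between the anterior direction and the
  centroid's offset from the axis point at the same z-level. Centroids on
  the axis are an error.
- **Density:** canals per mm² of endocortical surface. The reference area
  is the per-slice marrow contour arc length (marching squares on a
  Gaussian-smoothed slice — raw binary contours overestimate smooth
  boundaries by several percent through staircase excess) restricted to
  the angular sector, × slice thickness, summed. Endosteal surface is the
  normalizer because canals are read off the endocortical panorama.
- **Posterior fraction:** share of canals with |θ| > 90°, reported with
  counts.

## Panoramic unwrapping

Rays are cast outward from the marrow axis perpendicular to z (cylindrical
projection — analytic and testable; perspective shading of commercial
renderers is out of scope). The bone mask is sampled trilinearly and the
0.5 iso-crossing located by linear interpolation, so the depth map (first
bone contact radius = endosteal surface radius) is sub-voxel accurate.
Rays that exit the grid without contact are *gap* pixels — canal openings —
not errors. Two modes:

- **stitch**: one view per `theta_step` (18 at the default 20°), each
  spanning `theta_step / crop_fraction` of arc, cropped to its central
  `crop_fraction` (default 0.25, the quarter-width crop of the original
  workflow) and tiled in angle order;
- **resample**: direct (θ, z) sampling, strictly linear in θ.

Both modes locate phantom canal openings at the same positions; the
resample map's physical width (Σ r·Δθ averaged over rows) reproduces the
analytic ellipse perimeter to < 1% on noise-free phantoms. Panoramas are
written as 16-bit TIFF at 0.1 µm per grey level with a JSON calibration
sidecar.

## Periosteal thickness

At `n_samples` points uniformly spaced by arc length along the inner
contour, the outward normal is cast to its first crossing of the outer
contour (normal-based rather than nearest-point distance: it matches the
paired-edge semantics of inter-edge measurement macros, and is the
definition under which a profile-offset fixture has its analytic mean).
Samples inside user-supplied angular exclusion arcs (the interosseous-
membrane analogue; excluded manually in histological practice) are
dropped before summarizing; a sample whose normal never crosses the outer
contour is dropped with a warning, and losing more than half of the
retained samples is an error. Note the nearest-point distance is a lower
bound on the normal distance; for the sinusoidal fixture 5 + 2 sin 2θ on a
10 µm circle the two differ by ≈2.7%.

## Statistics

- **Mann–Whitney U** (independent groups): exact two-sided p by full
  enumeration when n₁ + n₂ ≤ 12 with no ties (enumeration stays
  sub-second), otherwise the normal approximation with midrank
  tie-corrected variance and continuity correction; the method used is
  recorded. All observations identical is reported as U = n₁n₂/2, p = 1.
  Implementation delegates to scipy; tests cross-check against an
  independent brute-force enumeration. The discrete null makes rejection
  at α = 0.05 slightly conservative (Monte-Carlo type-I error ≈ 0.045 at
  n = 10 per group).
- **Paired t-test** (within-animal left/right contrasts): t = mean(d) /
  (sd(d)/√n) with the n−1 sd denominator and n−1 degrees of freedom,
  two-sided. All-zero differences are a degeneracy error. Applied to
  per-specimen posterior fractions in the group contrast.
- **Polar histogram:** right-closed bins over (−180°, 180°], default 15°
  width (config-exposed; a narrower choice only refines the display, not
  the anterior/posterior split), with anterior/posterior percentage
  annotations on the rendered figure.
- Two-sided p-values throughout; no multiple-testing correction is applied
  (none is performed in the workflows this mirrors).

## Problem sizes and numerical defaults

Validation studies use phantoms of ≈ 4–5 Mvoxels (e.g. 96 × 176 × 176 at
1.27 µm) — large enough for ≈16–30 µm canals to span ≥ 12 voxels across —
with 3–8 canals plus lacunae and foramen per specimen; 20 random specimens
for parameter recovery and 2 × 4 for the paired contrast. Unit tests use
coarser 2 µm phantoms (with proportionally larger lacunae, since 3 µm
semi-axes fall at that sampling's resolution limit). Recovery on
noise-free phantoms is exact in count and classification, ≤ 0.2° in angle
and ≤ 0.3 voxel in diameter.

## Known limitations

- Canal counting is per connected component; a branching network would
  count once. Curved or branching canals are out of scope.
- Classification thresholds (2000 µm³, 50 µm) are biological conventions,
  not estimated quantities; they are exposed in `RunConfig`.
- The density normalizer (endosteal sector area) differs from alternatives
  (periosteal area, mid-wall area) by the shell's radius ratio; comparisons
  across studies must use the same convention.
- On noisy volumes the one-voxel opening doubles as denoising, but no
  claim is made beyond the noise levels exercised in the tests.
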