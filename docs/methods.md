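# Methods

This note documents the models, algorithms and numerical choices behind
`aneuwall`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Coordinate conventions

Meshes live in millimetres. Images are row-major with the origin at the
top-left pixel; a 2D point is `(x, y) = (column, row)`, 0-based. Voxel
grids declare an origin (the center of voxel `(0,0,0)`), a spacing and
a shape, all in mm. Slide thicknesses are given in micrometres and
converted to mm at the API boundary.

## Inner/outer classification (3D)

A resected dome is a bowl: one side of the shell faced the lumen. The
classifier labels vertex `v_i` inner (0) iff the open segment from the
mesh center `C` (arithmetic vertex mean — deliberately not an
area-weighted centroid) to `v_i` contains no interior point of the
watertight shell. Implementation: all ray–triangle intersections of
the segment are found (Möller–Trumbore, vectorized in numpy), the
segment is cut into sub-intervals at the hit parameters, and each
sub-interval midpoint is tested for containment by even–odd ray
crossing. A vertex is outer as soon as any sub-interval lies in the
tissue. Two guards matter:

* the segment is shrunk by `eps = 1e-6` of its length at the vertex end
  so the vertex's own incident faces never occlude it (a literal
  reading of the interior test is always true at the surface);
* testing interval midpoints rather than counting crossings keeps the
  degenerate zero-thickness shell (empty interior) all-inner, and a
  center that lies inside the solid (e.g. a closed sphere) all-outer.

The containment ray direction is slightly off-axis so regular grids and
symmetric phantoms do not graze triangle edges. Non-watertight input is
a hard error; the message lists offending boundary edges.

Refinement replaces each label by the strict majority of its
edge-neighbors' labels, sequentially in vertex-index order, iterated to
a fixed point with a 100-pass cap (a single-pass mode exists). Ties and
isolated vertices keep their label. Majority smoothing never increases
the number of label-discordant edges, which the tests assert.

## Virtual inflation

Per iteration, each inner vertex moves `step_fraction` of the way
toward the centroid of its `k_target` nearest target (lumen) vertices;
each outer vertex moves by the mean displacement of its `k_inner`
nearest inner vertices, so local wall thickness is carried along, and
outer vertices move every iteration to keep intermediate meshes valid.
Defaults: `k_target = k_inner = 5` (a small neighborhood keeps the
mapping local while averaging out target discretization),
`step_fraction = 0.5` (damped steps avoid oscillation around the
target), `max_iterations = 200`, `convergence_tol = 1e-3 mm` (largest
inner displacement per step). Nearest neighbors are Euclidean distances
to target *vertices*, not closest points on triangles — the mapping is
vertex-to-vertex by design. The scheme is purely geometric: no elastic
energy, no self-intersection handling, no material parameters.

On the dome phantom the iteration contracts monotonically (each default
step halves the remaining distance) and converges in ~10 iterations;
the enclosed shell volume changes by ≈3.3% and the mean wall thickness
by ≈1%.

## Histology segmentation

Both thresholds come from a 3-class multi-Otsu on grayscale luminance:
the lower separates the near-black scanner padding, the upper separates
tissue from the light slide background. The padding is then identified
as the dark structure *connected to the image border*, so equally dark
texture inside the tissue (nuclei, lipid droplets) is not punched out
of the mask. Half a histogram bin of slack absorbs thresholds that
land on the bin edge right below a discrete gray level (relevant for
rendered masks); images with fewer than three gray levels fall back to
a single Otsu split. All four stains share this path: every stain is
darker than the slide background, differing only in how much.

Components smaller than `min_object_area` (default 0.1% of the image)
are removed before and after refinement by morphological geodesic
active contours (`gac_iterations = 100`, balloon 0). The edge map is
`inverse_gaussian_gradient(alpha=1000, sigma=1)`: a steep response to
weak gradients so that the faint tissue/background edge of pale stains
(ORO, aSMA) still stops the contour, with `smoothing=2` to keep it off
small internal texture. Slides larger than 4096 px on a side are
segmented on a proportionally downsampled proxy and the mask is
upsampled nearest-neighbor — at such sizes the tissue boundary is many
pixels wide, so proxy segmentation loses little.

## Stain classification

The stain label is a property of global color distribution, so the
classifier is multinomial logistic regression on per-channel 8-bin
histograms plus channel means and standard deviations. Pixels are
subsampled by striding (never interpolated), making the features
independent of patch resolution. Trained on 70 labeled patches it
separates the four synthetic palettes perfectly; this replaces a deep
CNN because the contract is the 4-way label, not the architecture.
Real slides with stain variability would need richer features or more
training data.

## Contour split and sections (2D)

The tissue contour (largest component, counter-clockwise, arc-length
resampled to ≤4000 points) is split by the 2D analogue of the
visibility test: a point is inner iff the segment from the contour-
point centroid to it (shrunk at the point end) crosses no polygon edge.
The centroid may lie outside the polygon — u-shapes do that — and the
test is unchanged. Edges use a half-open rule so a crossing through a
shared polygon vertex is counted once.

Sectioning extracts the longest circular run of each label as the inner
and outer chains, co-orients them to start at the same tissue tip
(minimum inner-to-outer distance ties the two chain ends together),
resamples both uniformly in arc length to `n_sections = 5000`
positions, and pairs inner sample *i* with a sliding window of
`outer_per_section = 50` outer samples centered at *i* (clipped at the
ends). Sections therefore overlap, and sections 1 and n sit at the two
u-tips.

## Value mapping

For each matched segment pair the number of samples is
`max(len_a, len_b)` (≈1 per target pixel); reads are bilinear, writes
go to the nearest target pixel, restricted to the target mask.
Contributions per pixel are counted in processing order (section,
segment, sample) and capped at `update_cap = 5`; counted contributions
are averaged. The printed form of the transfer scales *values* by the
segment length ratio; this implementation reads it as an arc-length
*coordinate* rescaling — equivalent to sampling both segments at the
same normalized parameter — because value scaling would recolor the
output while the mapping is expected to preserve dominant colors, and
the two readings agree exactly in the self-mapping case.

When a source mask is supplied, source pixels outside it are replaced
by their nearest tissue pixel before interpolation. Segment endpoints
lie on the mask's 0.5-isoline, so unmasked bilinear reads there would
mix ~50% slide background into every boundary pixel; tissue-only reads
remove that artifact. The mapping-fidelity statistic is the Pearson
correlation of luminance over mask pixels (the channel handling is this
package's choice).

Self-mapping fidelity is resolution-dependent: at 2000 px the phantom
maps onto itself with correlation ≥0.997; at 512 px ≈0.989, because
boundary pixels are a larger fraction of the band. The dilation
experiment (map into a disk-dilated mask, correlate against the
original over the mapped region) decays much faster on the phantom than
it would on a full-resolution slide — the band is only ~90 px wide at
512 px, so a 5 px dilation is already a large relative shape change;
only the monotone decay is scale-independent.

## Slide stack and cross-sections

Stack length is the thickness sum including placeholders; slide
positions use a mid-slice convention (cumulative thickness of earlier
slides plus half its own). The missing-slide estimate is the length
discrepancy divided by the median slide thickness, rounded; a negative
discrepancy raises a shrinkage flag (fixation shrinks tissue, so a
stack longer than the measured sample is plausible). Cross-sections
rasterize pixel-center containment on a plane (default 20 px/mm), with
the cutting axis user-supplied.

## ICP and voxel transfer

Point-to-point ICP on vertex sets: nearest-neighbor matching (k-d
tree) alternating with the Kabsch least-squares rigid update, stopping
when the RMS improvement drops below `tol`. Initialization tries the
plain centroid shift plus principal-axes alignments with all four
proper sign flips and keeps the best start — ICP is local, and the
scanner pose of the ex vivo sample is arbitrary. If the RMS ever
exceeds its initial value a warning is issued and the best transform
seen is returned. Registration is only unique for shapes without
rotational symmetry; the tests use a bulged ellipsoid for that reason.

Voxel transfer is deliberately nearest-vertex (no interpolation): each
voxel center takes the field value of its closest mesh vertex, exact
ties resolving to the lowest index, so the output range is a subset of
the input values. Planar overlays resample the volume with
nearest-voxel lookup.

## Synthetic phantoms

The dome phantom is a watertight bowl — outer hemisphere, inner
hemisphere on the same angular grid (so radially aligned vertex pairs
are exactly one wall thickness apart), flat rim — with default 5 mm
outer radius and 0.5 mm wall, matching the mm scale of clinical lumen
models; the micro-CT stack generator defaults to tens of px/mm against
a 10 µm-class acquisition. Deflation is a volume-preserving squash:
axial compression by the deflation factor with lateral dilation by its
inverse square root, plus 0.01 mm seeded jitter to break symmetry.
Collapsed tissue flattens and spreads but is nearly incompressible, so
its wall volume is conserved — this is what makes "inflation changes
the volume only a little" a meaningful statement; a naive uniform
radial scaling would conflate deflation with mass loss and force any
thickness-preserving inflation to change the volume by ~f⁻³.

Histology phantoms are u-shaped annulus bands (mid radius 0.30, half
width 0.085, 100° opening as fractions of the image) on a light slide
background inside a dark padding frame, with fixed per-stain palettes
(base + accent color) chosen to mimic each stain's gross appearance and
to be linearly separable. Texture is accent-colored blobs plus
low-pass color modulation, both scaling with image size — the phantom
is "the same tissue" at any scan resolution, and mapping fidelity is
then measured on resolvable structure rather than on pixel noise,
which no resampling could reproduce. WSS surrogates are smooth positive
fields (axial gradient or Gaussian spot, ~1–5 Pa). All generators are
deterministic under a fixed seed.

What the phantoms do *not* emulate: real stain variability (batch
effects, fading), folding and tearing artifacts, multi-component
slices, anisotropic collapse, micro-CT noise and partial-volume
effects, and real CFD-derived WSS patterns. Passing tests demonstrate
the correctness of the geometry and transfer machinery under clean
conditions, not clinical robustness.

## Problem sizes

The test-suite and acceptance defaults — 2000 px for the full-scale
mapping check, 512 px elsewhere, ~1600-vertex domes, 20³–64³ voxel
grids, 5 classifier seeds — were chosen so the full pipeline exercises
every code path in minutes on a single core while keeping each check
well-conditioned (e.g. the mapping band is ≥80 px wide at 512 px).

## Known limitations

* Inflation has no tissue model; large or non-convex deflations can
  fold the mesh (no self-intersection checks).
* The contour machinery assumes one simply-connected u-shaped band per
  slice; closed rings (two boundary contours) and fragmented slices are
  out of scope.
* Correspondence between slices relies on consistent contour
  orientation and the u-tip anchoring; there is no elastic matching.
* The stain classifier is a palette classifier; it is not expected to
  transfer to scanners/stains outside its training distribution.
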