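# Methods

`chromatrack` quantifies the activity of cephalopod chromatophores —
dermal pigment organs expanded by radial muscles under direct motor-neuron
control — from video of behaving animals. Because each organ's projected
area is a readout of the motor neurons driving it, the pipeline turns raw
footage into per-organ area series, per-sector ("slice") expansion series,
and finally putative motor units inferred from the covariation of those
slices. This note documents the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic test bed does
and does not establish.

## Coordinate and map conventions

All coordinates are `(row, col)`, 0-based, with pixel centers at integer
positions; frame intervals are half-open `[start, end)`. Every dense map
is a *pull* field: a warp samples the source image at the coordinates the
field stores, so composing two warps is composing two lookups
(`compose_fields`). Label images (segmentation masks, the cleanqueen) are
always resampled with nearest-neighbor interpolation; intensity images
bilinearly. Angles are measured as `atan2(Δrow, Δcol)`, consistently in
the shape model, the slice geometry and the orientation stabilization.

## Pipeline stages

### Chunking

Each frame is scored with the mean absolute difference-of-Gaussians
(DoG) response, a band-pass centered on chromatophore edges. The two
sigmas default to `d/6` and `d/2` where `d` is the configured expected
chromatophore diameter (default 24 px). Frames passing both a focus and
a brightness threshold form maximal runs; runs of at least
`min_chunk_length` (default 20) frames become *chunks*, the unit of all
later processing. The focus threshold is relative by default — half the
median score of the sharpest decile — so recordings with different
lighting need no retuning; an absolute override exists. A single
threshold without hysteresis is used; degraded episodes in practice
depress the score far below the pass band, so chatter at the boundary
has not been an issue (boundaries on synthetic ground truth are
recovered within ±2 frames).

### Segmentation

Two classifiers ship behind one `PixelClassifier` interface. The color
lookup table pre-classifies every quantized RGB color by its nearest
training sample in a selectable color space (RGB/HSV/Lab, Euclidean
metric, exact ties to the lowest label id), making prediction a
pointwise, order-invariant table lookup. The random forest uses
per-pixel features (raw channels, Gaussian-smoothed channels at scales
1/2/4 px, and consecutive-scale DoG responses) with a fixed seed, so
refits are bit-reproducible. Several classifiers can be fused by
per-pixel majority vote, ties going to background. Heavier learned
models can implement the same interface; none are shipped, keeping the
package free of GPU dependencies. Downstream identity tracking is
binary; color classes are kept as per-territory metadata, because organs
darken over development and a color change must not break identity.

### Registration

Within a chunk, motion is estimated from sparse landmarks: centroids of
shape-filtered connected components of the first frame's mask (area in
range, eccentricity ≤ 0.95, solidity ≥ 0.7 — note a digitized disk of
radius 3 has solidity ≈ 0.78, so a higher floor would reject exactly the
small round organs that track best), thinned to a few points per grid
cell and kept away from the borders. A uniform-random fallback covers
masks with too few candidates. Points are tracked frame-to-frame (not
first-to-current; the solver assumes small motion) by a pyramidal
Lucas–Kanade solver written in-package: 3 levels, 21 px window, up to 10
fixed-point iterations per level. A point is killed — permanently —
when its single-step displacement exceeds `0.5·d`, when it leaves the
frame, or when its window loses texture; tracking aborts and the chunk
is flagged unusable when fewer than half the points survive.

A tracked point is only a *skin* fiducial while the pigment under it
holds still. The tracker therefore records the area of the mask
component under each point and clears a sticky `stable` flag the first
time that area leaves the band `[1/1.2, 1.2]×` its initial value:
expansion or contraction drags the point with the pigment edge, and the
drift does not revert when the area does. The band tolerates
segmentation flicker on small organs (area CV of a few percent) but
catches the ~1 px edge motion a 10% radius change produces. Unstable
points remain alive (they are tracked fine) but are excluded from map
estimation. This filter reduced worst-case anchor residuals from ~5 px
to < 1 px on the full-size synthetic scene.

Dense maps come from affine moving least squares (MLS) over the stable
control points: for every output position an affine map is fitted under
inverse-distance-squared weights (`α = 1`), evaluated on a coarse grid
(step 8 px) and bilinearly upsampled. Affine MLS reproduces any global
affine field exactly and interpolates the controls; degenerate
(collinear) configurations fall back per-point to a closed-form
similarity fit. Inverse maps are built by MLS with source and target
swapped — exact for affine fields and far cheaper than numeric field
inversion — because every frame needs an inverse map for cleanqueen
back-projection.

### Stitching

Each chunk is condensed to a masterframe (pixelwise mean of its
registered grayscale frames). Consecutive masterframes are aligned in
three steps. (1) Coarse: moment-based ellipse fit of the body silhouette
when one is available (the 180° ambiguity resolved by post-transform
image correlation), manual correspondences otherwise, or the identity
when the expected offset is within one patch of capture range. (2)
Refinement: grid points (spacing 16 px) matched by phase correlation of
surrounding patches — 64 px patches, then a second round at 32 px. The
correlation is the inverse transform of the normalized cross-power
spectrum with a relative regularizer; the integer peak is refined per
axis by a three-point parabolic fit, and the peak height gates matches
(default 0.05; matching patches of time-averaged content measure
0.07–0.65, featureless patches < 0.01). Hann windowing was evaluated
and rejected: on band-limited skin texture it smeared and biased the
peak. Two outlier stages follow: a median/MAD displacement gate, then a
leave-one-out MLS consistency trim (1.5 px) that removes
correspondences the rest of the field cannot predict — typically
patches dominated by a blob whose average expansion state differs
between the two chunks. (3) The surviving correspondences are
interpolated to dense maps with the same MLS code.

After the main rounds a *border pass* adds support near the frame
edge: grid points in the band the full-size patches cannot reach are
matched with fully interior half-size patches seeded from the MLS
prediction of the interior correspondences, then jointly re-trimmed —
without it the dense map extrapolates in the outer band and drifts off
the local warp there. Patches whose time-averaged background fraction
falls below 55% in either chunk are skipped up front (pigment does not
carry skin motion).

Quality control is the reprojection error: mean Euclidean distance
between evaluation points and their forward-then-backward images;
pairs above 2 px are rejected, and rejected chunks are excluded from
identity tracking. Chunks are chained (1→2→3…) and maps composed
frame → chunk reference → global reference, the global reference being
the first accepted chunk's first frame.

### Territories and areas

The *cleanqueen* assigns each global-reference pixel to one territory:
the occupancy image (fraction of valid frames a pixel is classified
chromatophore) is thresholded at 0.02, connected components are
labelled, and components containing several occupancy maxima (minimum
peak separation `d/2`) are split by marker-based watershed on the
inverted smoothed occupancy — territories are disjoint and connected by
construction. Physically overlapping organs cannot be separated by this
construction; the generator warns when a scene contains overlap at
maximal extent.

Per-frame areas are measured in the *unregistered* frames: the
cleanqueen is pulled through the composed inverse maps
(nearest-neighbor), and a chromatophore's area is the pixel count of
the largest 8-connected component of segmented pixels inside its
territory. Frames outside accepted chunks carry NaN, never 0.

### Anisotropy

Slice decomposition needs a deformation-proof anchor. Chromatophores
that stay small and constant (mean area below a cutoff, coefficient of
variation ≤ 0.1; the size cutoff defaults to the 25th percentile of
mean areas) serve as motion markers. Each organ's *epicenter* — its
center of mass at its most contracted valid frame (ties to the earliest)
— is stored as barycentric coordinates in its enclosing Delaunay
triangle of markers (hull-exterior epicenters use the triangle with the
least-negative extrapolated weights) and reconstructed per frame as
`c = λ₁a₁ + λ₂a₂ + λ₃a₃`; barycentric weights are invariant under the
locally affine skin deformation. The angular origin of the slices is
pinned per frame by the rigid (rotation-only, 3-point Procrustes)
transform of the marker triangle, so slice identity survives rotations.

Slice areas use `area = π·r̄²/n` with `r̄` the mean epicenter-to-border
distance of the slice (36 slices by default — comfortably above the
Nyquist rate for the 10–15 radial muscles of these organs). The border
is the *subpixel* outer contour: the half-level contour of the largest
component, resampled at 0.25 px of arc and smoothed with a 1 px
periodic Gaussian. Raw boundary-pixel centers sit about half a pixel
inside the true edge and bias slice areas 10–15% low; the subpixel
contour keeps every slice of a rasterized radius-10 disk within 5% of
`π·100/36`. Interior holes are ignored — the radius measures the
expansion front.

### Long-term alignment

Across days or weeks, growth and new organs defeat automated stitching,
so the user supplies landmark pairs (CSV). Warp maps come from
thin-plate splines (exact at landmarks, affine data gives zero bending
energy) or from the registration MLS. Identity transfers by greedy
one-to-one maximal-Jaccard matching (minimum 0.3); after prealignment
the overlap matrix is near-diagonal, where greedy matches the optimal
assignment (verified against a Hungarian oracle in tests). Unmatched
territories of the later session are flagged `new`, of the earlier one
`lost`.

### Motor units

Per chromatophore, the slice-area matrix is z-scored per slice (slice
areas scale with organ size) and the number of motor sources is set by
the elbow of the cumulative explained variance. The elbow is
operationalized as the point of maximum distance to the chord from the
*origin* (0, 0) to (n, 1); anchoring at the origin is essential — a
chord from the first curve point can never select k = 1 and returns
k ≈ 13 on rank-1 data. A curve whose maximum chord distance stays below
0.2 is treated as elbow-free (isotropic spectra reach ≈ 0.15) and k = 1
is returned with a warning. FastICA (fixed seed, tol 1e-3) extracts k
activation series, sign-fixed to non-negative skewness (expansion
bursts point up) and ordered by explained variance; if FastICA fails to
converge at the requested k, the pipeline retries with k−1 rather than
dropping the organ.

ICs are clustered across chromatophores by the sign-invariant
similarity |Pearson r| (ICA signs are arbitrary). Affinity propagation
(preference = median similarity, damping 0.7, one damping retry) is the
default and recovers the synthetic wiring essentially perfectly.
HDBSCAN (precomputed distance 1−|r|, minimum cluster size 2) is also
available; at this minimum cluster size it tends to fragment tight
correlation blocks, which a cluster-level merge (mean cross-similarity
≥ 0.6) only partly repairs — expect lower adjusted Rand indices than
affinity propagation on small scenes.

## The synthetic test bed

The generator renders what the pipeline assumes about real footage: (1)
organs as star-convex shapes whose boundary radius interpolates
linearly *in polar angle* between per-muscle vertex radii — constant
radii therefore give an exact disk, and each inter-muscle sector has
closed-form area `(Δθ/6)(r₀² + r₀r₁ + r₁²)`; (2) anchors fixed in the
skin, with motor sources in [0, 1] wired to contiguous muscle arcs; (3)
skin deformation defined directly as the smooth frame-to-reference
field ψ_t (drift + radial breathing + a smooth random local warp, all
vanishing at t = 0), which is exactly what registration must recover;
(4) mottled multi-scale background texture, normalized by band standard
deviation so sharpness — not chromatophore expansion state — dominates
the focus score, as it does on real skin; (5) episodic blur and
brightness dropouts (half-open intervals) plus sensor noise. Ground
truth is exact: rendered per-frame pixel areas, analytic sector areas,
per-frame anchor positions, the dense deformation field (evaluated
lazily), sharp-frame indicators and the motor wiring.

Default scene: 512×512 px, 200 frames, 20 driven chromatophores
(maximal radius 9–13 px, contracted 2.5 px, 12 muscles, up to 3 sources
each) plus 5 constant markers of radius 5 px — the marker diameter
honours the ≥ 10 px resolution floor below which segmentation of real
organs becomes unreliable. Breathing amplitude 1.5 px (period 40
frames), drift (0.02, 0.03) px/frame, local warp 0.8 px at 64 px
correlation length, sensor noise σ = 2.

What the synthetic bed does *not* emulate: occlusion by the animal's
own body, iridophores/leucophores, 3D skin bending, photometric
heterogeneity across the mantle, and physically overlapping
chromatophores. Passing tests therefore demonstrate the correctness of
the algorithms under the stated model, not performance on an arbitrary
recording; in particular segmentation of real footage will need
training samples, and marker density on real animals is set by biology,
not by the generator.

## Problem sizes

The shipped test suite and the reproduction script run the full
pipeline at 512×512 × 200 frames (the default scene), a two-chunk
256×256 × 120-frame drift scene, a 30-organ × 300-frame slice scene for
motor-unit inference, and several smaller unit scenes; these sizes were
chosen so a complete run takes a few minutes on one CPU core while
every stage still operates far from degenerate regimes.

## Known limitations

- Overlapping chromatophores share pixels the territory model cannot
  split; the generator records a warning and results for those organs
  are unreliable.
- The area-band stability filter assumes the first frame of a chunk
  shows each tracking-point organ near a representative state; an organ
  caught mid-expansion on frame one contributes nothing to the map
  (it is filtered) but costs a control point.
- Greedy territory matching is an approximation to optimal assignment;
  it is exact only when the overlap matrix is near-diagonal, i.e. after
  a successful prealignment.
- HDBSCAN's fragmentation at small minimum cluster size (above).
- The CLI reads MP4/AVI only when an imageio video plugin is installed;
  PNG frame directories and `.npy` stacks always work.
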