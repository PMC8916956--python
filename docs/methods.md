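# Methods

This note documents the models and procedures implemented in `mcmini`, the
parameters that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Synthetic data model

The generator (`synthgen`) is the package's ground-truth source, and its
defaults define the benchmark conditions used throughout the tests.

**Tissue.** Nuclei are non-overlapping disks placed by rejection sampling
(minimum edge-to-edge separation 2 px, radii uniform in 5–9 px by default).
Each cell carries a type label; each type has a distinct mean intensity
vector over the markers (`DNA`, `CD45`, `CK`, `Ki67` by default, with the
nuclear stain bright in every cell at ~500 intensity units over a
configurable constant background). Intensity is uniform within a cell by
default (zero within-cell variance), so per-cell mean-intensity checks have
exact expected values; lognormal per-cell scatter is available via
`intensity_cv`. Disks are hard-edged when `rim_blur_px=0` (used wherever a
test asserts exact pixel sums or means) and get a 1-px Gaussian rim by
default for realistic gradients. Per-cell expected intensities are stored at
float32 precision, matching the raster dtype, so "exact" means bit-exact.

**Acquisition.** A tile grid is derived from the frame size, grid shape and
overlap fraction (tile size `ceil(H / (n − (n−1)·overlap))`, step rounded up
so the grid covers the frame). Each tile is cropped at
`nominal origin + integer per-tile jitter (N(0, jitter_sd), rounded) +
cycle · cycle_offset`, multiplied by a per-channel mean-1 illumination
field, with additive Gaussian noise clipped at zero (Poisson noise is
deliberately omitted to keep exactness tests tractable). Every cycle
re-images the nuclear channel; remaining markers are split round-robin
across cycles. True origins, illumination fields and noise levels are
recorded. Pixel convention everywhere: origin top-left, (row=y, col=x),
0-based, half-open windows.

**TMA.** Cores are disks of cell-populated tissue on a grid; a dropout
fraction removes cores, a fragment fraction keeps only 2–3 angular sectors
(~60% of the disk area), and `clump_pairs` pulls horizontally adjacent pairs
to 0.9× spacing to emulate merged cores.

**What the generator does not emulate:** irregular nucleus shapes and
chromatin texture, cell crowding with contact deformation, staining
chemistry and cycle-dependent signal decay, autofluorescence structure,
focus variation, and rotational/non-rigid stage error. Passing the benchmark
therefore demonstrates correctness of the algorithms under their geometric
and photometric assumptions, not segmentation accuracy on real tissue —
which is the role of learned probability-map providers that can replace the
classical one behind the same interface.

## Illumination correction

The flat-field is the per-pixel median (optionally 10% trimmed mean) across
the tile stack, Gaussian-smoothed and normalised to mean 1; the optional
dark-field is the smoothed per-pixel minimum (off by default, zeros).
Correction is `(tile − dark) / flat`, clipped at 0, in floating point.

- `smoothing_scale` defaults to tile width / 20.
- Plain Gaussian smoothing biases a curved field by more than 1% near tile
  borders (any boundary mode); one van Cittert deconvolution step
  (`2·S − S²`) cancels the first-order bias and brings the estimator within
  the 1% idempotence contract.
- The estimator needs signal at every pixel: on tissue whose background is
  exactly zero, the stack median carries no shading information in empty
  regions. The benchmark therefore uses a nonzero background baseline
  (autofluorescence-like, 10–20 units), which is also the realistic case.
- Estimation is per cycle and per channel.

## Stitching and registration

Three steps: (1) cycle-1 tiles are aligned edge-to-edge with their
4-neighbours by phase correlation of the nuclear channel over the shared
nominal overlap region; (2) corrections propagate from the anchor tile
(grid (0,0)) along the maximum-confidence spanning tree, which keeps
alignment errors from compounding across the grid; tiles left disconnected
after discarding low-confidence edges fall back to nominal offsets from a
placed neighbour and are flagged; (3) each later-cycle tile is registered
to the cycle-1 tile of greatest overlap, with a median-shift fallback for
low-confidence tiles, and all channels are assembled on one canvas.

Numerical decisions:

- **Phase correlation** uses the whitened cross-power spectrum with no
  apodization window and no padding. A fixed window over moving content
  biases large shifts toward zero, and zero-padding creates a spurious
  zero-shift peak from the shared rectangular support once the spectrum is
  whitened; the circular formulation with a confidence filter proved
  strictly more accurate in both regimes. Wrapped-content ambiguity on
  narrow strips is a low-confidence situation by construction and is
  handled by the threshold, not by windowing.
- **Confidence** is the ratio of the correlation peak to the second-highest
  peak outside its 3×3 neighbourhood; ~1 for unrelated windows. The default
  threshold is calibrated at runtime as the 99th percentile of confidence
  over pixel-shuffled overlap strips (seeded). The confidence statistic has
  a heavy tail under pure noise, so isolated just-above-threshold estimates
  on textureless windows can still be wrong; the spanning-tree solver and
  the registration median-fallback are the second line of defence.
- **Subpixel** refinement is a 3-point parabola per axis, clamped to ±0.5.
- **Placement** rounds to integer pixels (no interpolation), so mosaic
  intensities remain exact for quantification. Overlap policy is
  last-write-wins by default (exact, used in tests) with linear
  distance-to-edge feathering available for display.
- Solved positions are defined up to a global translation (the anchor
  tile's own jitter); accuracy statements are gauge-removed. Benchmarks use
  an 800-px frame (≈286-px tiles, ≈29-px strips at 10% overlap) so stage
  jitter stays small relative to the strip, as in real scans.

## TMA dearraying

The core-probability map is the block-averaged (default 2×), Gaussian-
smoothed (σ ≈ diameter/4) nuclear channel rescaled to [0,1] — a classical,
monotone-in-tissue-density stand-in for a learned core/background
classifier, interchangeable behind the same interface. The median core
diameter is the median equivalent-circle diameter of Otsu-thresholded
connected components. Centers are local maxima of the scale-normalised LoG
response at σ = d/(2√2) (the blob scale at which a disk of diameter d peaks)
with minimum separation 0.7·d — retaining clumped neighbours — and a 10%
relative response floor; integer peaks are refined by the local center of
mass of the response and mapped back with the block-center offset
((downsample−1)/2). Crops are square windows of side (1+pad_frac)·d, clipped
honestly at mosaic borders, written one multi-page TIFF per core plus a CSV
index.

## Pixel classification

The classical three-class generator scores, after robust [1st, 99th]
percentile normalisation (making the maps invariant to affine intensity
rescaling): *center* = positive part of the inverted LoG at σ = d/(2√2);
*contour* = Gaussian gradient magnitude (σ = 1) multiplied by the
normalised intensity — the gating keeps contour evidence on the nucleus
side of the edge, since raw gradient magnitude is symmetric about it and
would pull a background halo into the nucleus mask; *background* = positive
part of (Otsu threshold − intensity). Scores are rescaled to [0,1] and
normalised per pixel to sum to 1; pixels with no evidence default to
background, and constant images are all-background. The crop sampler keeps
uniform-random ROIs whose fraction of pixels above the global Otsu threshold
meets `min_tissue_fraction`, reporting attempts and warning on budget
exhaustion.

## Segmentation

Seeds are LoG maxima of the center map (σ = d/(2√2), minimum separation =
`maxima_compression`·d with default 0.5 — "compression" is interpreted as a
separation distance — and a 10% relative response floor). The watershed
relief is `(1 − center + contour)/2`, flooded from the seeds with
4-connectivity, restricted to pixels with background probability < 0.5.
False positives are removed by comparing each region's mean in the raw
image or the center probability map against the Otsu threshold computed
over that image's pixels (a threshold over per-region means would bisect a
clean all-true-positive segmentation). Labels are renumbered 1..N by each
region's first pixel in raster-scan order, making masks bit-reproducible.

Cytoplasm methods share one exactness guarantee: ring and EDT use exact
Euclidean nearest-label expansion (`distance_transform_edt` feature
transform), the EDT variant intersected with the Otsu tissue mask of a
user channel. The grayscale-weighted distance transform uses the relief
`α·(normalised distance) + β·(1 − normalised intensity)` flooded by
marker-controlled watershed within distance ≤ max_distance and tissue; for
β = 0 the relief is a strictly monotone transform of the distance field,
whose watershed partition *is* the Euclidean nearest-label assignment, so
that exact closed form is used instead of discrete flooding (which differs
only by tie artifacts). Defaults α = β = 1, both terms normalised to [0,1].
Whole-cell masks are nucleus ∪ cytoplasm per label. Puncta are LoG maxima
at a small σ with relative thresholding. Masks export as uint32 TIFFs plus
two-page outline/raw overlays.

## Quantification

Per-cell means are computed per compartment with `scipy.ndimage.mean` per
label; morphology (area, centroid, eccentricity, solidity, extent,
orientation, equivalent diameter) comes from `regionprops` on the primary
compartment (default nucleus). Column dialect:
`CellID, <marker>_<nucleus|cyto|cell>..., <morphology>`. CSVs are written at
10 significant digits so values round-trip to better than 1e-9 relative.
Conservation (Σ area·mean = Σ labelled intensities) holds to float32
precision (≲1e-6 relative).

## Spatial analysis

Features are z-scored before clustering (scale invariance). K-means is
seeded with `n_init=10`; the kNN-graph route (k = 30 capped at n−1,
Euclidean) uses Leiden modularity (Louvain available). Modularity on a kNN
graph may split a well-separated phenotype into pure sub-communities; the
perfect-ARI guarantee is made for k-means only. Neighborhood composition is
the fraction of each type among neighbours within a radius (default 3× the
median nearest-neighbour distance) or among k nearest; isolated cells under
radius mode get a zero vector and a flag. Recurrent neighborhoods are
k-means clusters of the composition vectors.

## Pipeline

A single-process sequential executor with pre-flight config validation
(modes `wsi`/`tma`, stage coherence). TMA mode renders/accepts a
pre-assembled mosaic, dearrays it, and applies segmentation, quantification
and spatial analysis per core; `segment` and `quantify` each appear once in
the manifest regardless of core count. The provenance manifest records
module, package version, full parameters, derived per-stage seed, SHA-256
digests of inputs/outputs, timestamps and wall-clock seconds — enough to
re-execute the run; identical config + seed reproduce byte-identical
tables. Peak memory is taken from `getrusage` where the platform provides
it, reported as `n/a` otherwise.

## Benchmark problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in well under a minute of compute: 800×800 frames (3×3 tiles) for
stitching, 700×700 (5×5, 25 tiles) for flat-field recovery, 100 nuclei on
512×512 for segmentation, 4×5 TMAs with 60-px cores over 20 seeded
replicates for dearraying, and 200-cell tables for clustering. Accuracy at
these sizes transfers to larger frames for the geometric stages (stitching
error depends on strip content, not slide size), but wall-clock and memory
do not: the package holds mosaics in memory and is not tiled/pyramidal.

## Known limitations

- Rigid translation only; no rotation, scaling or non-rigid registration.
- The classical probability-map generator assumes blob-like nuclei; it is a
  stand-in for learned providers, not a competitor on real tissue.
- Global least-squares position solving is a documented extension point;
  the spanning tree is optimal for the tested error model but ignores
  redundant edges.
- No pyramidal/tiled output; canvas size is guarded by a pixel budget.
- Spatial analysis offers no AnnData export or figure generation.
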