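# Methods

This note documents the models, parameters and numerical choices behind
`spheroscreen`, and what the synthetic benchmarks do and do not demonstrate.

## Imaging model and pre-processing

Inputs are multi-page TIFF stacks (pages = z-planes, optionally RGB per
page), or pre-projected 2D TIFF/PNG/JPEG images; 2D inputs are treated as
depth-1 stacks.  Channel roles follow the staining convention of live/dead
double-stained 3D cultures: the green/viability channel defines structures,
the red channel carries the apoptotic-dot signal.  Because the sandwich
culture format confines spheroids to a narrow focal plane, all quantitative
analysis is 2D: stacks are reduced by average-intensity projection (AIP) per
channel; maximum projection is available as an option.  Grayscale conversion
is a weighted channel sum with equal weights by default (no basis for
unequal weights; configurable).

Percentile normalization clips at the 5th/95th percentiles and rescales
linearly to [0, 255].  When the foreground occupies less than 5 % of the
field the whole foreground saturates into the top bin; the thresholder is
designed to survive this (below).  Optional denoising: Gaussian, median, or
unsharp ("edge enhancement") filtering.  Phase-contrast images are flattened
by subtracting a large-window median background before thresholding; the
median is computed on a 4× downsampled copy and upsampled back, a close
approximation that avoids the quadratic cost of a full-size large median
window.

## Histogram-valley thresholding

The 256-bin histogram over the image's intensity range is smoothed with a
Gaussian of σ = 3 bins.  Candidate modes are local maxima (endpoints
included) thinned so that no two lie within 30 bins — nearer maxima, such as
a clipping spike beside the background hump, belong to the same mode.  The
background mode is the candidate holding the most local histogram mass
(±30 bins); the foreground mode is the highest candidate at least 30 bins
brighter.  This bright-side rule encodes the domain assumption that
fluorescent structures are brighter than background and occupy less than
half the image.  The cut is the minimum of the smoothed histogram between
the two modes; a flat valley resolves to its midpoint, which keeps the cut
stable when the inter-mode region is empty.  The integer `threshold` knob
(levels 1–5) adds (level − 1) × 2 % of the dynamic range to the cut, so
higher levels give a strictly smaller foreground.  Unimodal histograms fall
back to Otsu with a warning; constant images produce an empty mask.

Gap filling closes 4-connected background components that are fully enclosed
by foreground (8-connected) and strictly smaller than 1000 px — a hole of
exactly 1000 px is kept.  This cutoff is what turns a dim spheroid lumen
into structure interior rather than background.

## Structure labeling

A singular opening (disk, radius 3 px) suppresses thin appendages and
speckle before seed detection.  Seeds are regional maxima of the opened
mask's Euclidean distance transform, subject to a depth floor of
√(min_size/π) ≈ 5.6 px — a seed must be at least as deep as the radius of
the smallest acceptable structure (min_size = 100 px), which stops appendage
tips and ripple bumps from seeding.  Maxima are merged greedily: sorted by
depth, a maximum is kept only if no kept seed lies within `sensitivity`
pixels (default 20).  Each 8-connected component of the *un-opened* mask is
then partitioned among its own seeds by nearest-seed (Voronoi) assignment
with ties to the lower seed — the discrete watershed of the distance
transform, splitting touching structures along the ridge equidistant from
their seeds.  Flooding the un-opened mask keeps appendages attached to their
structures.  A component with no seed receives one at its distance-map
argmax, so every foreground pixel in a surviving component is labeled and
label areas are conserved.  Labels are contiguous 1..N in raster order; the
whole chain is deterministic, so re-runs are bit-identical.

Nearest-seed assignment of highly non-convex components can in principle
produce a disconnected label; this does not occur for the blob-plus-neck
geometries the pipeline targets and is checked by the connectivity tests.

For stacks, each structure's focus plane is the z-plane maximising the
intensity variance over the structure's pixels; the valley threshold is
recomputed on that plane restricted to the structure's bounding box and the
structure's pixels re-evaluated inside its own label region, so focus
refinement can reshape structures but never changes their number.

## Substructures, body and appendages

Cell extraction inside a structure thresholds the channel intensities of the
structure's own pixels with Otsu (256 bins).  Two guards make this safe on
empty channels: a structure with no intensity spread yields zero cells, and
the two Otsu classes must differ by at least 30 gray levels
(`min_cell_contrast`) — otherwise the threshold would split pure noise and
fabricate cells.  An adaptive opening (disk radius = `adaptive_kernel_scale`
× structure equivalent diameter; default scale 0.05, floor 3 px) defines
reliable watershed seeds; EDT maxima are merged within 6 px
(`cell_merge_distance`) and the nearest-seed partition floods the
*un-opened* Otsu foreground, so cell areas equal the thresholded areas and
specks disconnected from every seed stay unlabeled.  Cells under 4 px are
dropped.

Two scale choices deserve justification.  The kernel scale is 0.05 of the
equivalent diameter because the opening must simultaneously remove thin
protrusions (width ≲ 6 px) and preserve compact nuclei/dots of radius
3–4 px for typical structure diameters of 30–80 px; a scale of 0.1 erases
the dots.  The floor is 3 px because smaller disk footprints extend less
than 2 px along diagonals and slip through diagonal strands, leaving the
body/appendage split vacuous for small structures; a radius-3 opening still
preserves blobs of radius ≥ 3.

The body is the adaptive opening of the structure mask; boundary ripple
shallower than the kernel is absorbed into the body ("outline variance
removed").  Candidate appendages are 8-connected components of the residual
(mask − body) lying more than 2.5 px from the body — this disconnects
protrusions whose bases are bridged by ripple arcs — and count as appendages
when they cover ≥ 5 px and extend ≥ 6 px from the body.  Remaining residual
pixels attach to their nearest counted appendage within the same residual
component.  If the opening empties the mask (thin, all-appendage
structures) the whole mask is used as the body and flagged.

## Parameter catalogue

The 19 named parameters and their definitions, built on the edge-distance
set D (Euclidean distances from the centre of mass to every boundary pixel
with a 4-connected background neighbour):

| class | parameters |
|---|---|
| general | Area (px), Closest (centre-to-centre px; −1 when alone), Neighbors, SharedBound (px), CellRatio (% of field area covered) |
| morphological | Roundness, FiltRound, RoundDiff, Roughness (%), AppIndex, MaxApp, MedApp (px), AppNumber |
| functional (per channel R, G) | Density (gray/px), AreaRatio (%), Hollowness (%), CellNumber, AveArea (px) |

plus Deviation (sd of structure-channel intensity, reported unitless).  The
centre of mass and the radius — the m-quantile of sorted D, m = 0.25 by
default — are internal and not written to the result file.  Roundness is the
coefficient-of-variation form 100·max(0, 1 − σ(D)/μ(D)); the isoperimetric
alternative 4πA/P² is available (`roundness_isoperimetric`).  Roughness
compares D with a circular moving average (window 15 samples) over boundary
pixels ordered by polar angle, capturing small surface features distinct
from appendages.  Hollowness contrasts core against rim intensity,
100·max(0, 1 − μ_core/μ_rim), with the core at half the quantile radius —
chosen so a half-radius lumen scores high and a filled disk scores ≈ 0.
Appendage length is the maximum distance of appendage pixels from the body,
i.e. the protrusion's reach beyond the smooth outline.  With R/G
duplication the catalogue yields 24 feature columns per structure; output
coordinates are 0-based (x = column, y = row).

## Screen statistics

The heatmap computes d(t, f) = median_t(f) − median_control(f) and divides
each feature column by its sample standard deviation across treatments, the
only reading of "unit variance" that makes colours comparable across
features of different units.  Standardization happens before significance
masking.  Mann-Whitney U p-values are exact for group sizes ≤ 8 without
ties and use the tie-corrected normal approximation otherwise; Bonferroni
correction multiplies by the number of treatments T and caps at 1;
the mask threshold is corrected p < 0.05.  Zero-variance feature columns
standardize to 0 and are flagged.  Spearman correlation uses average ranks;
constant features are recorded as 0 with a unit diagonal.  Clustering is
complete-linkage on Euclidean distances with scipy's deterministic
tie-breaking.

Variance components come from a REML linear mixed model with a random well
intercept and a position variance component nested in wells (positions are
physically fields of a well, so nesting is the appropriate structure).
REML keeps the estimates non-negative.  Preconditions: ≥ 3 wells, ≥ 2
positions per well, ≥ 2 observations per position.

## Synthetic fields

The generator renders what a 5× spinning-disk field of a sandwich 3D
culture looks like at 672 × 512 px: 25 structures by default (≈ 8 %
foreground, matching fields with a few hundred structures per well spread
over four positions), radii ~N(18, 3²) clipped at 10 px, low-frequency
radial deformation (harmonics 2–4, amplitude 8 %), high-frequency surface
ripple (2 %), Poisson(1.5) invasive appendages of length 12–28 px and
half-width 1.6 px, 20 % hollow structures with cores dimmed to 25 % of the
rim level, Poisson(2) red dots of radius 3 px inside the body, flat
intensity levels (background 20, rim 200, dots 220) and additive Gaussian
noise (σ = 5).  Optional z-stacks blur each structure by σ = 1.5 px per
plane of defocus away from its per-structure focus plane.  Bodies are
packed so their envelopes never touch and appendage directions are chosen
to keep clear of every other structure, so each planted structure is
recoverable independently of the watershed-splitting path (which is
exercised separately on constructed touching-disk fixtures).  Every draw
comes from one seeded generator: the same seed gives bit-identical stacks.

Deliberately not modelled: PSF optics, shot noise, intensity gradients,
out-of-focus light from neighbouring structures, debris, and touching
structures.  Recovery rates measured on these fields therefore demonstrate
the correctness and calibration of the algorithms under clean, known
conditions — not expected accuracy on real microscope data, where threshold
and sensitivity typically need per-experiment adjustment.

A screen generator lays fields over treatments × wells × positions (default
triplicate wells, four positions per well), applies per-treatment
multiplicative effects to phenotype parameters (e.g. dot rate ×3 for a
cytotoxic compound; appendage rate ×0.15 for an anti-invasive one) and
draws log-scale well/position size offsets for variance-component checks.

## Benchmark problem sizes

The self-validation benchmarks use 50 default fields for ground-truth
recovery, 50 noise seeds for the shape-ordering checks, 10 fields for the
knob-monotonicity checks, 500 replicates of a 19-treatment global null
(n = 100 per group) for the type-I error rate, and 10 seeds of a 20-well ×
4-position × 25-observation design (σ_well = 2, σ_position = 1,
σ_residual = 1) for variance-component recovery, reporting the median.

## Known limitations

- The valley thresholder assumes bright structures on a darker, more
  abundant background; inverted-contrast images need pre-inversion.
- Appendages thinner than ~3 px or shorter than 6 px are absorbed as
  outline variance by design.
- Focus refinement forbids topology changes, so a structure that is
  genuinely two structures at its focus plane stays one.
- Time-lapse tracking and 3D (volumetric) segmentation are out of scope.
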