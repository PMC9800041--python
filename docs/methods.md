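# Methods

This note records the models and procedures the package implements, the
conventions and numerical choices they depend on, and what the synthetic
test data does and does not establish about behavior on real images.

## Conventions

Pixel coordinates are (row, col), 0-based. All rectangular regions — crops,
tiles — are half-open, `[r0, r1) × [c0, c1)`. Background is label 0 in both
semantic masks (value = class index) and instance masks (value = positive
instance id, not necessarily contiguous). Masks are persisted as
single-channel 16-bit PNG; labels above 65535 require TIFF (stored 32-bit).
An image's identity is its filename stem; its content identity is the
SHA-256 of the raw file bytes, which also keys the feature cache and the
version-control blob store.

## Sample selection

Sequential ordering sorts by filename, case-sensitive byte order. Random
ordering draws a uniform permutation from a seeded PCG64 generator applied
to the canonical (sequential) order, so it is independent of input record
order. Cherry-picking places user-chosen ids first, in the given order, and
falls back to sequential for the rest.

Heterogeneity sampling is greedy farthest-point (k-center) selection: each
pick maximizes its minimum dissimilarity to the union of already-annotated
and already-ordered images. This greedy rule *is* the specified algorithm —
exact subset optimization (NP-hard for k-center) is deliberately out of
scope. Two decisions were genuinely open and are fixed as follows: when
nothing is annotated, the sequence is seeded with the lexicographically
smallest id (any fixed rule works; this one is reproducible without
randomness), and all ties break lexicographically, which makes the ordering
invariant to input shuffling. Dissimilarity, not similarity, is the internal
currency: cosine similarity s enters as 1 − s; zero vectors are rejected
under cosine because the angle is undefined.

The default feature extractor — 8×8 block-mean downsample, min-max
normalized, concatenated with a 32-bin L1-normalized histogram (d = 96) —
was chosen to be deterministic and dependency-free. It captures coarse
layout and intensity distribution, which is enough for the generated test
data; for real data a pretrained-CNN embedding plugged in behind the same
contract (deterministic image → fixed-d vector) will separate content far
better. The cache stores base-10 floats in JSON keyed by content hash:
renames keep entries, any byte change invalidates one entry, and a cache
built under a different extractor or metric is reported stale wholesale.

## Pre-processing

Normalization maps to [0, 1]: min-max, or percentile-clipped min-max with
percentiles under the linear-interpolation definition (the numpy default;
fixed so replays are exact). A constant image maps to all zeros by
convention. Multi-channel images are normalized per channel. Filters use
reflect padding; the median window must be odd. Masks are never normalized
or denoised, and are resampled nearest-only (enforced), so no interpolated
pseudo-labels can appear. Every applied pipeline is recorded with input and
output array hashes (SHA-256 over shape, dtype, bytes); replaying a record
must reproduce the output hash exactly or it raises.

## Pre-annotation

Otsu's threshold is computed over the distinct intensity levels of the
image (not a fixed 256-bin grid), maximizing ω₀ω₁(μ₀ − μ₁)² for the split
x ≤ t | x > t. Three conventions, all fixed because any choice works but
only one can be replayed: foreground is *strictly* greater than the
threshold; ties take the smallest maximizing level; bright-on-dark is
assumed, with an invert flag for the opposite polarity. The percentile
method thresholds at the q-th percentile with the same >-side rule. A
constant image yields an empty foreground with a logged warning rather than
an error — it is a degenerate input, not a caller mistake.

Connected components are 8-connected by default (diagonal contact joins;
matches how annotators perceive blobs), configurable to 4. Seed points are
component centroids rounded half-up. Previous-image propagation deep-copies
the prior annotation and refuses to run under any selector other than
sequential, because "the previous image" is only meaningful in natural
order. External predictors (e.g. pretrained networks) enter through
`PredictorContract`; their output is validated against the task before use
and their name/version is recorded in provenance. No network weights ship
with the package.

## Post-annotation processing

Holes are background regions not 4-connected to the image border, under the
standard complementary pairing (foreground 8-connected, background
4-connected). Instance masks are processed one instance at a time against
background: a hole takes the label of its enclosing instance, morphology
cannot merge neighboring instances, and pixels gained by closing only ever
claim true background. The structuring element is a rasterized disk
including pixels within Euclidean distance radius + 0.5 of the center, so
radius 1 includes the diagonal neighbors and a radius-1 opening removes
single-pixel spurs attached to block edges.

Every step's effect is captured in a diff that carries both summary counts
(pixels changed, per-label added/removed, segments added/removed) and the
full sparse patch of (row, col, old, new) — the processed mask is exactly
reconstructible from the raw mask plus the diff, which is what makes the
accept/reject review trustworthy. Fuzzify produces a two-class mixture
{label: 1−w, secondary: w}; the weight has no canonical value and is the
annotator's judgment of ambiguity.

## Inspection

Criteria use standard region-property definitions: eccentricity of the
ellipse with matching second-order central moments (0 = circle, → 1 =
line), convexity as solidity (area / convex-hull area). Bounds are
inclusive; a missing bound is unbounded on that side. Segment count and
mean segment area are per-image measurements ("mean" is per-image, not a
dataset-level running mean — a config point if prior knowledge is
dataset-wide); area, eccentricity, and convexity are per-segment. Warnings
never block; `resolve` applies the annotator's keep/reannotate decision. A
model-based inspector with the same name and version as the active
pre-annotator is refused outright: a model cannot meaningfully audit its
own proposals.

## Version control

Commits are manifests (path → SHA-256, size) over every data file in the
dataset directory (the `.annotassist/` metadata itself is excluded), stored
in an append-only JSONL log with blob contents deduplicated by hash. This
self-contained store was chosen over delegating to an installed Git: it
needs no external binary, and the meta-file log remains human-diffable. A
commit id hashes the manifest, parent id, message, and timestamp, so
re-committing an identical tree yields a new commit but zero new blobs.
Checkout verifies every needed blob's integrity *before* touching the
working tree, auto-commits the current state as a safety snapshot, restores
byte-exactly, and re-snapshots to verify. Remote sync, merging, and delta
compression are out of scope.

## Tiling

Tiles are placed at stride (tile − overlap); the last row/column is shifted
inward to end exactly at the image border. This no-padding policy means
every fragment is full-size and contains only real pixels, at the cost of
extra overlap near the far borders — preferable for annotation, where
padded fake pixels would be misleading. Fragment names encode the tile
origin (`{id}__r{r0}_c{c0}`), making local→global mapping lossless. Seeds
falling in overlap bands are duplicated into every containing tile.
Instances crossing tile borders keep their id per fragment; re-merging
split instances at stitch time is not attempted.

## Synthetic data

The generators define the package's test conditions. Blob images are
rasterized disks (radius 5–9 px by default) at intensity 180 on background
40 with Gaussian noise σ = 8 — a 17.5σ contrast, comfortably above the 5σ
separability the recovery checks assume — with centers at least
2·r_max + 2 apart, guaranteeing disjoint instances; ground truth (instance
mask, semantic mask, true centers) is exact by construction. Disks were
chosen so area, eccentricity, and convexity have near-closed-form
expectations. Classification sets encode class in mean intensity (evenly
spaced over [40, 215], texture σ = 10). Sequences translate one blob scene
by a fixed per-frame drift, with blob placement shrunk by the total drift
so no object ever leaves the frame, and frame names that sort temporally.

What passing on this data shows: the algorithms implement their definitions
exactly (the oracle tests are exhaustive, not sampled tolerances) and the
pipeline is deterministic end to end. What it does not show: performance on
real micrographs — touching cells, uneven illumination, texture-defined
classes, and non-convex objects are all absent by design. Threshold-based
pre-annotation in particular assumes a bimodal histogram; on real data it
is a starting point for correction, not a segmenter.

## Problem sizes

The bundled checks use the sizes they state: 200 random feature sets
(n ≤ 8, d ≤ 4) for the ordering oracle, 100 random 8-bit images for the
Otsu oracle, 50 blob replicates (1–10 blobs, 160×160) for recovery, 200
random 15×15 masks for post-processing invariants, 20-step edit sequences
for versioning, 100 random grid configurations for tiling, and 4-image
projects for the determinism runs. These sizes give exhaustive or
near-exhaustive coverage of the small-instance space where the oracles are
tractable; the algorithms themselves are dimension- and size-agnostic.
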