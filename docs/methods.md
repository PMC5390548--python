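# Methods

`tonguecbir` implements content-based retrieval of tongue images for
traditional-Chinese-medicine-style inspection workflows: given a query
image, rank a database of tongue photographs by a fused color + texture
similarity, so that images of the same clinical appearance class (pink,
pale, purple, purple-red, yellow-coating, white-coating tongues; normal,
teeth-printed, thick-coating, exfoliative, fissured texture) surface
first. This note records the model, its assumptions, the parameters that
matter, and the choices made where the design was genuinely open.

## Dominant-color descriptor

Color is represented as a small palette `F = {(c_i, μ_i)}` of HSV
cluster centers `c_i` with coverage fractions `μ_i = n_i/(M·N)` summing
to 1. Extraction is a seeded generalized-Lloyd (LBG) vector
quantization:

1. **Seeding.** The image is converted to HSV by the hexcone formula and
   every pixel is assigned to one of nine coarse regions: black
   (v ≤ 0.2), gray (s ≤ 0.1, v ≤ 0.9), white (s ≤ 0.1, v > 0.9), and six
   hue bands — red [315°,360°)∪[0°,20°), yellow [20°,75°), green
   [75°,155°), cyan [155°,190°), blue [190°,260°), purple [260°,315°).
   Every region holding more than `area_threshold` (default **15 %**) of
   the pixels nominates one initial cluster whose center is the
   circular-mean color of its pixels; if no region qualifies, the most
   populated one is used alone. This replaces random initialization,
   which is unreliable on tongue images whose color classes are subtle.
2. **Lloyd refinement.** Assignment (nearest center under the weighted
   squared HSV distance) alternates with centroid update until the
   largest center movement drops below `tol = 1e-6` (normalized units)
   or `max_iter = 100` iterations.
3. **Split / merge.** After convergence, any cluster whose within-error
   (weighted mean squared deviation) exceeds `split_threshold`
   (**T1 = 0.01**) is replaced by two centers offset ± half the member
   standard deviation along the coordinate of largest weighted variance
   (standard LBG splitting); then any center pair closer than
   `merge_threshold` (**T2 = 0.1**) is pooled into its count-weighted
   mean. Each structural change is followed by re-convergence; the outer
   loop ends when a round fires neither operation (at most
   `outer_rounds = 10` rounds, guaranteeing termination).

The distance metric normalizes hue to [0, 1) and differences it
circularly (`min(|Δ|, 1−|Δ|)`); the component weights default to
**ω = (2, 1, 1)**, emphasizing hue because hue carries most of the
separation between tongue color classes. T1, T2 and ω are tuning knobs
(no canonical values exist); the defaults were chosen so that planted
palettes with separation well above T2 and noise well below it are
recovered exactly, which the test suite asserts over 20 seeds.

Centroid hue uses a vector circular mean refined by unwrapping the
members around it and averaging arithmetically — the exact minimizer of
the summed squared circular distance whenever a cluster spans less than
half the hue circle, which keeps the Lloyd objective monotonically
non-increasing (asserted per iteration in the tests). Empty clusters
are dropped; assignment ties go to the lowest cluster index for
determinism.

**Descriptor distance.** The field-standard quadratic matching form is
used: `D² = Σμ1ᵢ² + Σμ2ⱼ² − 2ΣΣ aᵢⱼ μ1ᵢ μ2ⱼ` with center similarity
`aᵢⱼ = 1 − min(dist(c1ᵢ,c2ⱼ)/d_max, 1)` and fixed normalizer
`d_max = 0.5`: centers at least 0.5 apart (weighted, hue-normalized
units — e.g. opposite hues at full saturation) contribute nothing.
`D` is a symmetric premetric bounded by √2. A plain Euclidean distance
between the two nine-region histograms is available as an alternative
color metric (`color_metric="areas"`), since variable-length palette
matching and fixed-length histogram distance are both defensible
readings of "Euclidean similarity" for this descriptor.

**Traditional baseline.** The pre-clustering baseline keeps every
coarse region covering ≥ 5 % of the pixels, with per-region mean colors
and renormalized fractions; it is implemented so the improved and
traditional descriptors can be compared under the identical distance.

## Edge-histogram descriptor

Texture is the MPEG-7-style edge histogram computed on the luminance
image `g = 0.299·r + 0.587·g + 0.114·b` (the 0.114 blue weight is the
standard BT.601 value; a variant with 0.144 — whose coefficients sum to
1.030 — is selectable via `gray_coeffs="variant"` for compatibility,
with the output clipped to [0, 255]).

* The image is divided into a 4×4 grid of subimages (floor division,
  remainder pixels attached to the last row/column), each covered by a
  16×16 grid of **256 blocks** whose side is the largest even number
  ≤ dim/16 (trailing pixels dropped; blocks below 2×2 raise an error, so
  the defaults need ≥ 128×128 images — smaller images work with a
  reduced `blocks_per_subimage`).
* Each block's four macroblock mean grays `(a_TL, a_TR, a_BL, a_BR)`
  are filtered by the five standard MPEG-7 operators — vertical
  (1,−1,1,−1), horizontal (1,1,−1,−1), 45° (√2,0,0,−√2), 135°
  (0,√2,−√2,0), nondirectional (2,−2,−2,2) — taking absolute responses.
  The strongest response classifies the block if it **strictly exceeds
  the threshold (default 20)**; ties resolve in the fixed filter order.
  Applying the threshold to absolute rather than signed responses is
  this package's choice (the sign only encodes polarity).
* The **local** histogram is the per-subimage edge-type frequency
  (counts / 256 — normalization happens before any quantization), 16×5
  = 80 bins; the **global** histogram is the mean of the 16 local rows
  (5 bins; the mean rather than the raw sum keeps it on the local-bin
  scale so the fusion weight below is meaningful); the **semiglobal**
  histogram averages the 13 standard subimage groups — 4 columns, 4
  rows, 4 corner 2×2 quadrants, and the center 2×2 quadrant — giving
  13×5 = 65 bins. This is the only 13-group layout consistent with a
  65-bin histogram.
* An optional uniform 3-bit quantizer (`code = min(⌊8v⌋, 7)`, midpoint
  dequantization) encodes the 80 local bins; similarity always uses raw
  bins — quantization is an encoding concern, not part of the metric.

## Similarity and fusion

The texture distance is the weighted L1 sum
`Σ|EH_q−EH_t| + 5·Σ|GH_q−GH_t| + Σ|SGH_q−SGH_t|` (80 + 5 + 65 terms,
the global term weighted ×5 to amplify whole-image edge statistics);
it is a true metric bounded by 170 for bins in [0, 1]. Each feature
distance is mapped to a similarity `(d_max − d)/d_max ∈ [0, 1]` and the
two are fused convexly with default weights **0.6 : 0.4** in favor of
color. `d_max` defaults to the per-query empirical maximum over the
indexed collection (so the farthest entry scores exactly 0); fixed
theoretical bounds (√2 and 170) are available when scores must be
comparable across queries. Whether the normalizers are per-query or
database-wide constants is an open design point; the per-query choice
needs no invented constants and leaves rankings invariant under any
common rescaling of both `d_max` values (asserted in the tests).

## Retrieval and evaluation

The index stores both descriptors (plus the coarse nine-region
histogram) per image as JSON lines. A query ranks all entries by fused
similarity, ties broken lexicographically by image id; self-queries
rank first with similarity exactly 1. Evaluation uses precision = M/L
and recall = M/D at a cutoff (default top-9, the number of results the
original protocol displays), with relevance meaning a shared class
label and the query counted among its own relevant set.

## Synthetic phantoms: what they emulate, and what not

No tongue-image collection is publicly deposited, so all experiments
run on generated phantoms that carry exactly the signal the
descriptors measure: a 1–3 color HSV palette realized as contiguous
runs with exact pixel fractions, an oriented gray-level pattern
(vertical/horizontal/diagonal stripes, checkerboard, or random-walk
"cracks"), per-channel Gaussian noise, and optionally an elliptical
tongue-shaped mask. Defaults: 256×256 pixels, noise σ = 4 gray levels,
texture contrast 120, stripe half-period 4 px phase-shifted so stripe
boundaries fall mid-block. The 256×256 size is deliberate: it yields
4×4-pixel blocks with 2×2-pixel macroblocks, the smallest geometry at
which diagonal edges are distinguishable from nondirectional ones (at
2×2 blocks every diagonal boundary degenerates to a corner pattern that
fires the nondirectional filter).

Template sets mirror the study design at desk scale: six tongue-like
color classes (hue centers 345°, 15°, 50°, 80°, 290°, 315° with
saturations/values ordered like the clinical classes), five texture
classes (the four stripe orientations plus a checkerboard as the clean
nondirectional class — random-walk cracks produce mixed orientations
and are provided as an option rather than a default class), and six
combined classes drawing three colors and three textures with
deliberate collisions so that color alone confuses two class pairs,
texture alone confuses three pairs, and only the fusion separates all
six. Databases use 9 images per class so that a perfect top-9
retrieval exists; experiments average over 20 seeded databases. Hues
are jittered ±5° per image and noise is resampled, all derived from a
single seed.

Passing these experiments shows that the pipeline recovers exactly the
structure it models — planted palettes, oriented edges, and their
conjunction — under moderate noise. It does **not** show robustness to
properties of real tongue photographs the phantoms lack: illumination
and white-balance variation, specular highlights, soft class
boundaries, spatially varying coatings, segmentation errors, or
correlated (non-Gaussian) sensor noise.

## Numerical choices and degenerate inputs

* Hexcone singularities: S = 0 when V = 0; H = 0 for achromatic pixels.
* Hue intervals are half-open; s/v cutoffs closed on the printed ≤; the
  gray band is extended to v ≤ 0.9 to close the gap an s ≤ 0.1,
  0.8 < v ≤ 0.9 pixel would otherwise fall into (minimal, monotone
  extension; the quantizer is total and exactly nine-valued over the
  domain).
* All floating-point serialization is full-precision (`repr`
  round-trip), so a reloaded index compares equal to the original.
* Retrieval rankings, phantom generation, and experiment seeding are
  fully deterministic given the seed; no global random state is used.

## Known limitations

* T1, T2 and ω have no principled defaults; badly scaled values can
  over-split or collapse palettes. They are surfaced in `GlaParams`.
* The empirical `d_max` makes similarity scores query-relative; use the
  fixed mode for cross-query score comparison.
* Edge classification needs even block sides ≥ 2; very elongated or
  tiny images require adjusting `blocks_per_subimage`.
* The quadratic color distance with `d_max = 0.5` saturates for very
  dissimilar palettes — all "far" pairs look equally far.
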