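# Methods

This note documents the model behind `graincount`, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not establish.

## Problem setting and assumptions

The input is a single photograph of crop grains scattered on white paper,
taken roughly perpendicular to the paper. The method assumes:

* grains are darker than the paper (any seed-coat colour works as long as
  its gray level is separated from near-white by a global threshold);
* grains are convex or nearly convex silhouettes — ellipse-like, wedge-like
  (corn), or round;
* grains lie in a single layer: clusters are touching/overlapping
  neighbours, not piles;
* the background is featureless white paper with at most mild illumination
  gradients.

## Pipeline

### Preprocessing

Photographs are downscaled so the long side is at most 1920 px
(area-averaging resampling; never upscaled — upscaling adds no information
and would change the pixel scale of the short axis). Grayscale conversion
uses Rec. 601 luminance weights. A 5×5 Gaussian (sigma auto-derived from
the kernel) precedes a global Otsu threshold. Otsu returns two classes
without naming them; the class occupying the smaller fraction of the image
border is taken as foreground, since on white-paper scenes the background
touches the border almost everywhere. This makes binarization agnostic to
polarity-inverted fixtures. Components under 9 px² are dropped as sensor
noise; at the 1920-px working scale this is far below any grain, including
rapeseed. A nearly uniform image (gray-level spread below 25) is treated
as an empty sheet: empty mask plus a warning, not an exception.

### Short axis and adaptive erosion

Each 8-connected region is thinned to a one-pixel-wide medial skeleton
(topology-preserving thinning as implemented by scikit-image). At every
skeleton pixel the local grain width is twice the Euclidean distance to
the nearest background pixel; the short axis **X** is the maximum width
over the skeleton. Full width (2× distance) rather than the half-width is
used so X matches the grain's physical minor-axis diameter — for a filled
circle of radius 15 px, X = 30.

The erosion extent is **e = round(w·X)**, floored at 1, with **w = 0.4**.
The structuring element is a disk and **e acts as its radius**: the
erosion removes w·X of material from each side of the region. This
reading is deliberate and load-bearing:

* a single grain's core survives exactly while w·X < X/2, i.e. for
  w < 0.5 — so grains begin to disappear once the coefficient passes 0.5,
  which reproduces the documented failure mode of excessive corrosion and
  makes the sweep over w ∈ {0.1, …, 0.9} peak near 0.4 (measured on the
  package's adhesion benchmark: w = 0.4 ranks first);
* at w = 0.4 the removal (0.4·X per side) is deep enough to cut the
  contact necks of tangentially touching grains, whose half-width grows
  like √(R·d) for contact depth d and boundary curvature radius R.

Under the alternative reading (e as the disk *diameter*, removing only
0.2·X per side) no grain can ever vanish for any w < 1, the isolation
score rises monotonically with w, and the sweep has no interior optimum —
empirically w = 0.4 ranked fifth of nine. That reading was therefore
rejected.

Erosion is applied **per region**, each with its own X, so mixed scenes
erode proportionately; a global X would over-erode small regions. A vanish
guard halves the extent of any region whose erosion output is empty until
at least one pixel survives (falling back to the un-eroded region), so
separation never deletes a region outright. Individual fragments that fall
below the noise floor after erosion are still dropped — this is the
mechanism that penalises excessive coefficients in the sweep.

### Fragment re-grouping and counting units

Erosion destroys the concavity geometry the corner formula depends on, so
corners and holes are always measured on original (pre-erosion) shapes.
When a region splits into k ≥ 2 fragments, the original silhouette is
partitioned among the fragments by marker-based watershed on the negated
distance transform; each reconstructed piece becomes one counting unit.
Un-split regions are counted whole. A unit carved out of a split parent
loses the shared concavity to the cut, and its windowed foreground
fraction (which counts only the unit's own pixels) drops to ≈0.5 there, so
clean splits do not fabricate corners.

### Corner detection

For every boundary pixel of a unit (a foreground pixel with a 4-connected
background neighbour *inside* the image — the photo edge is not outline),
the fraction of the unit's pixels inside the centred 13×13 window is
computed via an integral image. Windows are clipped at the image borders
and normalised by the visible area. Candidates exceed 0.66 strictly;
non-maximum suppression keeps candidates that are local maxima among
candidates within a 13-px Chebyshev radius, ties broken by scan order
(top-to-bottom, left-to-right) for determinism. Convex or straight
boundary sits near 0.5 and yields no corners; each junction between two
adhered convex grains yields up to two.

The 13×13 window and the 0.66 threshold are the operating point of the
corner detector; both are exposed in `PipelineConfig` (`corner_window`,
`corner_fraction`).

### Per-unit classification

With C detected corners and H enclosed holes (4-connected background
components not reaching the region border), the raw estimate is
C/2 − H + 1. Units are classified:

1. C = 0, H = 0, not linear-adhesion → a single grain (count 1);
2. linear adhesion → average-area count;
3. otherwise → corner formula, rounded half-up and floored at 1.

Rounding half up is deliberate: a half-integer raw value means an odd
corner count, i.e. one junction lost a corner to occlusion, which is an
undercount.

**Linear adhesion** is a long, nearly straight unit: skeleton length
strictly greater than 1.5× the image-mean skeleton length, and the
included angle at the midpoint of the longest skeleton path within
160–200°. The angle is measured between least-squares line fits to the
two halves of the path (180° = straight); the band is checked in both
rotation senses. The longest path comes from a double-Dijkstra diameter
sweep over the skeleton's pixel graph (exact on trees, which skeletons of
hole-free blobs are).

**Average-area counts** divide the unit's area by the mean single-grain
area, estimated from units that are plainly single (un-split, no corners,
no holes). If fewer than three such units exist the estimate falls back to
the median unit area divided by the median raw count, with a warning —
this keeps dense all-adhering scenes defined.

### Annotation and totals

Every unit gets a red dot at its centroid; units counted ≥ 2 get a yellow
number at the dot's upper right. The image total equals the number of
plain dots plus the sum of the yellow numbers — the identity
`total_from_annotation(build_annotation(result)) == result.total` holds by
construction and is property-tested.

## Evaluation metrics

CR = (1 − |N₁ − N₂|/N₁)·100 and ER = 100 − CR. The absolute value is
used so overcounting cannot produce CR > 100. The volatility statistic is
the *population* variance (divisor n) of a series of per-scene accuracies,
with the mean M. The benchmark harness tabulates CR per scene and method
and records backend failures as missing values rather than aborting.

## Synthetic scenes

The generator emulates the photographic setting: dark anti-aliased
silhouettes on background N(245, 4) with an optional linear illumination
gradient (default amplitude 8 gray levels) and per-grain intensity drawn
from N(preset mean, 8). The six presets carry the crops' length × width
proportions (wheat 7.2×3.4 mm ellipse, corn 11.8×8.8 mm wedge, mung bean
5.5×3.9, soybean 11.1×6.9, peanut 13×8, rapeseed 2.1 mm round) and gray
levels chosen per seed-coat colour. The wedge is an ellipse clipped by a
chord at 70% of the major axis — one flat end with two convex corners,
the geometry that makes corn prone to false corners. Grain sizes get 4%
lognormal-ish jitter (clipped Gaussian).

Adhesion is explicit: a requested fraction of grains is placed in touching
pairs/triples whose members overlap radially by 5% of the grain width
(at least 1.5 px) along the line of centres; chains bend by at most ±57°.
The default pixel scale is 10 px/mm; `auto_px_per_mm` emulates framing
(more grains → camera further back) by keeping total grain area near 12%
of the canvas. Scenes carry exact truth: per-grain geometry, a truth label
map, cluster bookkeeping, and N₁.

The occluded-pair fixture places two identical 60×24 px ellipses with
centres offset 0.7 of a major axis apart along the axis, 0.3 minor-axis
widths laterally, and a 14° relative tilt. This geometry reliably renders
as one region with exactly one detectable concave corner (the upper
junction corner is swallowed by the overlap) across render seeds, giving
the canonical raw value 1.5 for a true count of 2.

**What the synthetic benchmark does not show.** Rendered silhouettes are
cleaner than photographs: no shadows, specular highlights, seed-coat
texture, dust, or perspective foreshortening, and adhesion geometry is
limited to shallow pairwise contacts and short chains. Recovery rates
measured here (mean CR ≥ 95% over 20 scenes of 50–400 grains with up to
30% adhering grains; exact counts on adhesion-free scenes) therefore bound
the method's behaviour under its own assumptions, not its accuracy on any
particular camera's output.

## Numerical choices and degenerate inputs

* Erosion extent and count rounding use round-half-up (floor(x + 0.5)),
  not banker's rounding.
* The corner threshold is strict (fraction > 0.66), and NMS ties break by
  scan order, so results are deterministic.
* Uniform images binarize to an empty mask with a warning; empty masks
  count 0 with a warning.
* Thinning can annihilate 1–2 px specks; the skeletonizer then keeps one
  representative pixel so the short axis stays defined.
* Skeleton length sums unique 8-adjacency steps (diagonal = √2); thinning
  retracts rounded ends, so a 40×8 px rectangle measures ≈ 34 px.
* Problem sizes in the test suite (scenes up to 400 grains on a
  1440×1920 canvas, a 3-scene sweep benchmark) were chosen to exercise the
  50–400 grain operating range at realistic pixel scales.

## Known limitations

* Dense many-grain clumps (4+ mutually touching grains) exceed what
  shallow-contact erosion plus pairwise corner geometry can resolve;
  counts degrade gracefully (the corner formula undercounts occluded
  junctions) rather than failing loudly.
* The linear-adhesion rule needs a population of normal regions to define
  the mean skeleton length; on images containing only one cluster the
  rule cannot fire, and the half-up rounding of the corner formula is the
  only correction.
* Grains must contrast with white paper after grayscale conversion;
  pale-yellow grains on cream paper would fall below the contrast guard.
* The average-area correction assumes grains of one crop per image; mixing
  crops of very different sizes skews the mean single-grain area.
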