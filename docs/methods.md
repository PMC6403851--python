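# Methods

`glutenpna` reimplements protein network analysis (PNA) for confocal
micrographs of gluten networks: segmentation of the protein phase,
skeleton-based morphometry, gliding-box lacunarity, and a rule-based
classification of the network into five morphological types. Because
no real image set ships with the package, a synthetic micrograph
generator with exact ground truth stands in for confocal data; this
note records the models, the parameter choices, and what the synthetic
validation does and does not show.

## Segmentation

Protein threads are bright, roughly tubular structures on a dark
background. Segmentation runs in four steps:

1. **Ridge enhancement.** A Sato (Hessian-eigenvalue) tubeness filter
   responds to bright ridges. The two thread-diameter settings, 3 and
   5 px, are interpreted as Gaussian scales σ = d/2 (1.5 and 2.5 px);
   the per-pixel maximum over scales is taken and the response is
   rescaled to [0, 255]. The interpretation of "diameter" as 2σ is the
   standard convention for diameter-parameterized vessel filters; the
   original tool's exact transfer function is unpublished, so absolute
   agreement with it is not claimed.
2. **Intensity window.** Pixels with enhanced value in [15, 255] become
   foreground. The window applies to the enhanced image, not the raw
   intensities, mirroring the order of operations of vessel-analysis
   tools.
3. **Particle filter.** 8-connected components with area strictly below
   35 px are removed ("removed under 35": a 35-px component survives).
4. **Hole filling** (off by default): background regions not 4-connected
   to the border become foreground.

The default calibration is 4.76 pixel/µm, stored as its reciprocal
(≈0.2101 µm per pixel).

## The five attributes

All morphometry runs on the binary mask. The skeleton is a
topology-preserving thinning; foreground connectivity is 8-connected
throughout.

* **Branching rate** — junction count per 1000 µm² of protein area.
  Junctions are skeleton pixels with ≥3 skeleton neighbors; 8-adjacent
  junction pixels merge into one junction. Thinning smears one many-way
  crossing into ~2 nearby 3-way points, so `skeletonize_mask` accepts a
  `junction_merge_radius_px` that widens the merge; counts then agree
  with a generating graph on sparse geometry (radius ≈ one thread
  width), but on dense meshes a large radius would chain distinct
  crossings, so the default (plain 8-adjacency) is used everywhere in
  classification. The raw operator over-counts crossings by a roughly
  constant factor, which cancels in the ratios the classifier uses.
* **End-point rate** — skeleton pixels with exactly one neighbor, per
  1000 µm² of protein area.
* **Average protein length** — mean geodesic skeleton length per
  connected component ("one continuous protein particle" = one
  component). Geodesic length sums axial steps at 1 px and diagonal
  steps at √2 px, skipping diagonals that are redundant with two axial
  steps through a corner; isolated single pixels count one pixel.
  Note this attribute is dominated by the largest component in
  well-connected masks and is the noisiest of the five.
* **Protein width** — protein area divided by total skeleton
  (centerline) length. Deterministic and consistent with the
  area-normalized attribute family; end effects bias a finite ribbon's
  width upward by ~2%.
* **Lacunarity** — gliding box: an r×r window slides at step 1 over all
  fully-inside positions; with M the foreground mass per window,
  Λ(r) = var(M)/mean(M)². The summary is the arithmetic mean of Λ(r)
  over box sizes {2, 4, 8, 16, 32, 64} px. Whether the original tool
  summarizes by mean or by a slope is unpublished; the mean was chosen
  and all band values below refer to this implementation's scale. Box
  masses come from a summed-area table and are exact integers, so the
  result is bit-identical to the brute-force definition.

## Classification

Profiles are normalized to a designated standard (the unmodified
flour-water system): branching, end-point rate, width and length become
ratios; lacunarity stays absolute because the published bands are
absolute. Ratios map to five levels through fixed cut points

    very_low ≤ 0.75 < low ≤ 0.92 < median < 1.08 ≤ high < 1.25 ≤ very_high

chosen so that the reported shifts land in the intended levels (−21% →
low, +27% → very_high, +9% → high). Lacunarity maps to four bands with
edges 0.16, 0.27 and 0.55: the first two are the published boundaries
(the printed ranges "0–0.16", "0.17–0.26", ">0.27" leave two-decimal
gaps; the bands are half-open with the printed labels as boundary
values, so 0.16 is still "low" and 0.27 still "median"). The 0.55 edge
separating dense from scattered agglomerates is not published; it sits
above 2.5× a median-band standard (≈0.50), the highest dense-agglomerate
exemplar, and is configurable.

The rule table is evaluated I → V, first match wins:

| type | band      | branching        | end-point    | width        |
|------|-----------|------------------|--------------|--------------|
| I    | low       | ≤ low            | ≥ high       | ≥ high       |
| II   | median    | ≥ median         | ≤ median     | ≤ median     |
| III  | median    | ≤ median         | ≥ high       | ≥ high       |
| IV   | high      | ≤ low            | ≥ high       | ≥ high       |
| V    | very_high | ≤ low            | —            | —            |

The rules are mutually exclusive (II and III share a band but have
disjoint end-point sets), so evaluation order is cosmetic. Type III's
branching includes very_low for determinism. A profile matching no rule
is UNCLASSIFIED and carries the minimal number of level steps to any
rule, for triage rather than forced assignment.

## Synthetic micrographs

The generator emulates what the classifier needs to see: bright
anastomosing threads, dark circular occlusions (starch granules), and
detector noise, in five regimes mapped to the five types.

**Thread networks** (branched, fragmented, contracted): nodes sit on a
jittered grid (low count variance keeps junction densities stable
across seeds), edges come from a Delaunay triangulation pruned by
length and by a random keep fraction, restricted to the largest
connected piece, and are drawn as ribbons of fixed width via a distance
transform around the rasterized centerlines. **Rupture** blanks a gap
adjacent to one end of an edge: the node loses that incidence (this is
what lets the measured branching rate fall, the reduction mechanism)
while the surviving fragment keeps one open end. Exactly
round(rate·n) edges are cut — those with the lowest per-edge uniforms —
so the marginal probability per edge equals the rate, rupture counts
are deterministic, and raising the rate only adds cuts to the same
geometry (the monotonicity the tests rely on). Edges whose fragment
would strand a speck below the particle filter are ineligible.

**Agglomerates** (dense, scattered): Gaussian clusters of fat blobs;
dense tiles the field with many clusters, scattered places a few far
apart.

**Photometry**: background 25, foreground 190, boundaries anti-aliased
by a σ=0.8 blur, and Gaussian noise whose standard deviation is
`noise_sd` at the foreground level and scales with √(signal) —
shot-noise-like, so dark occlusions stay quiet. All randomness flows
from one integer seed through named substreams; outputs are
byte-identical given (spec, seed).

**Defaults are the study conditions.** Images default to 512×512 px at
1/4.76 µm/px — a quarter field of the study's 1024² at identical pixel
scale, which keeps per-image counts high enough for stable attribute
ratios at desk-scale runtimes. Regime parameters were calibrated once,
end to end through the pipeline, so each regime lands where its type
description says it should on this implementation's lacunarity scale:
branched ≈0.19 (median band), fragmented ≈0.10 (low), contracted ≈0.20
(median), dense agglomerate ≈0.43 (high), scattered ≫0.55. No absolute
attribute values are published for any real sample, so reported
percentage shifts are treated as directional targets only.

**Agent series** interpolate spec parameters with concentration:
glutathione/bromelain raise rupture (toward the fragmented regime),
ascorbic acid contracts (thicker threads, larger occlusions), glucose
oxidase densifies the mesh and heals ruptures, transglutaminase
densifies at low dose and crosses to dense agglomerates above half the
maximal dose, and hydration increase produces scattered agglomerates.
The whole series shares one seed so dose effects are paired on the same
geometry.

**What passing tests show — and don't.** The synthetic images share the
real data's geometry only at the level the attributes measure
(tubular/blob morphology, gap structure, rupture topology). They have
no point-spread function, no depth sectioning, no staining
heterogeneity, no intensity gradients, and their threads are straight
segments rather than curved filaments. Recovery of the generating type
therefore validates the internal consistency of
segmentation → morphometry → classification, not performance on real
confocal data; the absolute band edges in particular are known to be
implementation-scale (a `--recalibrate` path is the classifier's
configurable band edges).

## Statistics

Pearson correlations are computed on per-sample means by default (the
source data averaged 8 images × 3 doughs per sample; whether
correlations used images or samples is unstated, so a flag switches).
PCA standardizes attributes (they mix units) and fixes signs by making
each loading's largest-magnitude entry positive; explained fractions
cover all components and sum to 1. Exponential decays y = a·e^(−bx) + c
are fit by bounded least squares (b ≥ 0) with c₀ = min y,
a₀ = max y − min y, and b₀ from a log-linear regression on y − c₀;
R² = 1 − SS_res/SS_tot, undefined (reported as missing) for constant y.
One-way ANOVA is classical; Tukey HSD uses the studentized-range
distribution, two-sided, with no significance gating; group summaries
are mean ± SEM (sd/√n).

## Numerical notes and limitations

* Thinning (Zhang-Suen) is not exactly equivariant under rotation on
  dense masks; junction/endpoint counts move by up to ~10% under 90°
  rotation. Fixture shapes are exactly invariant.
* The ridge filter's boundary handling is asymmetric within ~3σ of the
  image edge; the enhancement is equivariant to <1e-4 away from that
  band.
* Lacunarity restricts windows to fully-inside positions, so a uniform
  mask gives exactly 0 at every box size; the empty mask is an error
  (mean mass 0), as are box sizes below 2 or above half the image.
* The average-length attribute collapses to "total length" whenever the
  mask fuses into one component, which happens at realistic densities;
  its dose-series direction is still reproduced, but it is the weakest
  attribute and the classifier does not use it in any rule.
* Dense agglomerate masks partially fuse at the coverage the high
  lacunarity band implies; their component ground truth refers to the
  generating clusters, not the drawn union.
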