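# Methods

## Problem and approach

Farmed gilthead seabream (*Sparus aurata*) often lack the golden-yellow
patches on the forefront and operculum that wild fish show, and dietary
carotenoids are the main lever for restoring them. This package implements a
non-invasive, photograph-based measurement of that pigmentation and the
inference used to compare dietary groups:

1. **Masking.** Each photograph is reduced to an 8-bit RGB array plus a
   boolean fish-foreground mask. The mask comes from an explicit policy —
   alpha channel, chroma key (Chebyshev distance from a key color above a
   tolerance), or an external single-channel mask — so background removal is
   deterministic and auditable. Images whose policy leaves no foreground are
   rejected, not silently zeroed.
2. **Color calibration (optional).** A photographed ColorChecker 24 chart
   gives 24 measured/reference RGB pairs; an affine map (3×3 matrix plus
   offset) is fit by ordinary least squares and applied to all pixels, with
   rounding half-up and clamping to [0, 255]. An affine fit is the simplest
   standard chart correction; the reference sRGB patch values ship as a CSV
   fixture. Whether counts are taken on raw or calibrated pixels is a config
   choice; both paths are supported because acquisition pipelines differ in
   where they calibrate.
3. **Yellow quantification.** "Yellow" is an inclusive per-channel RGB box;
   the default is the box derived for seabream from sampled yellow pixels:
   R 205–255, G 130–255, B 0–15. Per image we report the in-box foreground
   pixel count, the *yellow fraction* (count / foreground size — the
   size-standardized measure used for all between-fish comparisons), and the
   **Standard Distance Deviation (SDD)**, in pixels.
4. **Inference.** Per-fish feature = (frontal yellow fraction, lateral
   yellow fraction). Manhattan distances over these 2-vectors are tested by
   two-way crossed ANOSIM (treatment × replicate) with Bonferroni-corrected
   pairwise post-hocs, and associated with Euclidean distances on the scalar
   dietary carotenoid concentration by a Spearman Mantel test. Growth traits
   (total length, weight) are compared by one-way ANOVA with Tukey HSD and a
   compact letter display.

## SDD

The phrase "standard deviation of the mean distance among pixels" admits two
readings, so both are implemented:

- `centroid` (default): the classical GIS *standard distance* about the mean
  center, `sqrt(Σ[(r_i − r̄)² + (c_i − c̄)²] / n)` — this is the quantity
  conventionally named Standard Distance Deviation;
- `pairwise`: the population standard deviation of the n(n−1)/2 inter-point
  Euclidean (optionally city-block) distances.

Coordinates are row-major, origin top-left, 0-based. With fewer than two
yellow pixels dispersion is undefined and reported as NaN — never 0, which
would claim maximal concentration. Such images stay in count-based analyses
and are dropped (with a logged warning) from SDD summaries.

## Permutation tests

- **One-way ANOSIM.** All n(n−1)/2 dissimilarities are ranked (average ranks
  on ties); `R = (r̄_between − r̄_within) / (M/2)` with `M = n(n−1)/2`.
  R ∈ [−1, 1] and is invariant to monotone transforms of the distances.
- **Two-way crossed ANOSIM.** For factor A, the one-way R is computed within
  each level of factor B and averaged; the null permutes A labels
  independently *within* each stratum of B (and symmetrically for B). This
  is the standard crossed extension of the rank-based design. Here factor A
  is diet (9 levels) and factor B the replicate index (1–3), crossed because
  every diet has tanks 1–3.
- **Mantel.** Spearman (default) or Pearson correlation between the two
  upper triangles; the null permutes rows and columns of the second matrix
  jointly. Because a joint permutation preserves the off-diagonal multiset,
  ranks, centering and scale are computed once and only re-indexed per
  permutation — the test is exact and fast even at n = 486 with 9999
  permutations.
- All permutation p-values use `p = (1 + #{stat_perm ≥ stat_obs}) / (1 +
  n_perm)`: unbiased, never zero, minimum `1/(n_perm + 1)`. All tests are
  bit-reproducible from (seed, n_perm).
- **Tukey HSD** uses the studentized range distribution with the
  Tukey–Kramer standard error; letters come from the insertion–absorption
  algorithm (groups sharing a letter are not significantly different).

## Synthetic studies

No photographs are distributed with the original study, so the package
ships a generator that emulates its structure with known ground truth.

**Design.** 9 treatments × 3 tanks × 18 fish (486 fish, 972 images), two
views per fish, 256×256 px by default. Treatment carotenoid concentrations
are the nine test-diet values (4.6, 3.5, 3.5, 3.5, 3.3, 2.4, 2.7, 5.4,
234.2 mg kg⁻¹ d.w.).

**Images.** A view-specific silhouette (horizontal ellipse plus tail for the
lateral view, vertical ellipse for the frontal) filled with gray-brown body
tones (base RGB ≈ (132, 120, 104), vertical shading, Gaussian channel noise
σ = 5). The body palette keeps the red channel ≥ 60 gray levels below the
yellow box, so body pixels can never classify as yellow; ground-truth and
measured counts therefore agree exactly. Yellow patches (2–3 per image, at
operculum/pectoral/belly anchors laterally and along the head midline
frontally) are grown as nearest-to-center foreground pixels until the
painted count equals `round(area_fraction × foreground)` exactly.

**Patch colors** are drawn uniformly from the *interior* of the yellow box
(inside the 5 %-shrunk bounds, i.e. R 216–242, G 137–242, B 0–14). Real
pigment pixels evidently do not crowd the box boundaries — the original
analysis reported that perturbing the bounds by ±5 % left results unchanged
— and the generator reproduces that property by construction.

**Dose–response.** Mean yellow area fraction of view v at concentration C is
a saturating curve `fmax_v · C/(C + K)` with `fmax_frontal = 0.17`,
`fmax_lateral = 0.015`, `K = 50 mg/kg`: low-carotenoid diets (~2–5 mg/kg)
give small fractions and the microalgae diet (234 mg/kg) approaches fmax,
qualitatively matching the reported frontal coverage range (~8 → 17 %).

**Noise model.** Per-fish, per-view fractions are the view mean times
`exp(u_t + e_iv)` with a shared per-tank intercept `u_t ~ N(0, 0.02²)` and
individual noise `e ~ N(0, 0.5²)`, clipped to [0, 0.4]. The multiplicative
(log-scale) form keeps tank and individual effects proportionally small in
both views despite the ~10× difference in fraction scale; an additive tank
intercept of comparable magnitude would dominate the lateral view entirely.
The individual CV of ≈ 53 % reflects the very high intra-treatment
variability evident in the published per-treatment dispersions (the pixel
columns of the summary table are only consistent with per-fish CVs of this
order when read as standard errors), and the small tank CV of 2 % mirrors
the finding of no replicate effect on pixel counts. Growth traits are drawn
per treatment from normal presets with the published means/SDs, so the
ANOVA reproduces the reported ordering of diets.

**What the generator does not emulate:** real fish shape and texture,
specular highlights, shadowing, inter-fish size variation in the frame,
imperfect masks, and color-cast drift between sessions. Passing tests
demonstrate correctness of the measurement and inference machinery and
internal consistency of the pipeline — not robustness to real photographic
artifacts, which must be assessed on real images with the chart-based
calibration enabled.

## Numerical and design choices

- RGB bounds are inclusive on both ends (the "R = 205–255" notation).
- Range perturbation by p %: expand `lo → ⌊lo(1−p)⌋`, `hi → ⌈hi(1+p)⌉`;
  shrink reversed; clamp to [0, 255]; re-order if crossed. Each bound moves
  by p % of its own value, so a 0 bound is a fixed point.
- Calibrated pixels round half-up (`⌊x + 0.5⌋`) before clamping; the yellow
  box is defined on 0–255 integers.
- Mean images: background filled white (255, 255, 255), bilinear resize to
  the median canvas per view, average of the magenta-overlaid images by
  default (raw averaging behind a flag). No landmark registration — the
  acquisition geometry was physically fixed.
- Ties: average ranks everywhere (ANOSIM ranks, Spearman).
- ANOSIM R for a reported statistic is bounded in [−1, 1] by construction.
- Problem sizes in the shipped analyses: the default study runs at 256×256
  px; the end-to-end replication check uses 20 study replicates; permutation
  null calibration uses 500 replicates at n = 36 (ANOSIM) and n = 30
  (Mantel) with 199 permutations, which resolves rejection at α = 0.05
  exactly. The treatment-factor ANOSIM in the replication check uses 1999
  permutations so that p < 0.001 is attainable under the +1 convention;
  single headline runs use the conventional 999 (ANOSIM) and 9999 (Mantel).

## Known limitations

- The yellow box is a hard threshold in RGB; pixels near the box boundary
  flip classification under calibration changes. HSV/Lab spaces are out of
  scope.
- The two-way ANOSIM requires a fully crossed design with ≥ 2 observations
  per cell; unbalanced or nested layouts are rejected rather than
  approximated.
- Mean images are resize-aligned only; they blur when fish pose varies.
- The saturating dose–response makes closely spaced high doses statistically
  indistinguishable at realistic noise; perfect rank recovery is a property
  only for dose ladders whose response means are separated well beyond
  sampling error.
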