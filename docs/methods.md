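# Methods

## The measurement

`rbcagg` quantifies red-blood-cell (RBC) aggregation from phase-contrast
fields of view of dilute suspensions flowing in a microfluidic channel.
Aggregation is reversible and shear-dependent: at low shear (8.9 s⁻¹)
cells stack into rouleaux and, in pathology, into branched aggregates and
interconnected networks; at high shear (446 s⁻¹) most aggregates disperse.
Per field the package reports

* **AI = S_agg / S1** — the aggregation index, with S1 the field area in
  pixels (1600 × 300 by default) and S_agg the summed pixel area of the
  selected aggregates (conventionally called S2 at low shear, S3 at high
  shear, giving AI_L and AI_H);
* **NA** — the number of objects meeting the aggregate criterion of at
  least three clumped cells (NA_L, NA_H).

Per sample, values are the mean ± SD over that sample's fields (≥ 5 fields
per shear condition by convention). Groups are compared with a two-sided
rank-sum (Mann–Whitney) test at α = 0.05; an exact permutation null is
enumerated for combined n ≤ 15, which covers every pairing of the study's
group sizes (8 controls, 7 non-severe, 6 severe preeclampsia). A paired
signed-rank variant serves the treated/untreated oxidation design, and
Pearson's r (t-transform p) the correlation analyses.

## Pipeline

Per field, in order:

1. **Illumination flattening** (optional, on by default): divide by a
   Gaussian estimate of the shading field (σ = 25 px — large against a
   cell, small against the field). Removes multiplicative gradients up to
   the ±30% amplitude tested.
2. **Contrast stretch** to the full 8-bit range, clipped at the (1, 99)
   intensity percentiles (robust to hot pixels).
3. **Median denoising** (3 × 3, on by default). A median window is used
   instead of linear smoothing deliberately: phase contrast surrounds each
   dark cell body with a bright halo rim, and any linear blur drags that
   rim into boundary pixels, biasing object areas by roughly a half-pixel
   shell (≈ ±10% of AI at these cell sizes). The median filter is
   edge-preserving; the residual AI bias measured on degraded synthetic
   scenes is −2.6% ± 0.3%.
4. **Otsu thresholding** (`fixed` available as an escape hatch) with
   foreground-polarity auto-detection: the side of the threshold occupying
   less than half the pixels is taken as foreground, overridable, since the
   halo can flip naive "dark object" assumptions.
5. **Clean-up**: components below 50 px are removed; interior holes filled.
6. **8-connected labeling** (4-connected available) with per-region area,
   centroid, bounding box, eccentricity, border contact, and skeleton
   endpoint/branch-point counts.
7. **Single-cell area**: the median area of the singlet population,
   identified as the smallest tight cluster of region areas (the first
   ascending area with at least three regions within +35% of it). Singlets
   are near-identical in projected area and are the smallest objects, while
   even a two-cell clump is ≥ 1.7× larger, so the rule is insensitive to
   how aggregate sizes happen to cluster. By default the estimate pools the
   regions of all of a sample's fields (`cell_area_scope="sample"`) — cell
   size is a property of the suspension and the optics, not of one frame,
   and high-shear fields are singlet-rich. A known calibration can be
   supplied instead (`expected_cell_area_px`); with neither available the
   pipeline fails loudly rather than guessing.
8. **Aggregate criterion**: a region is an aggregate iff
   `area ≥ min_cells × single_cell_area × packing_factor`, boundary
   inclusive, with `min_cells = 3`. The packing factor converts the
   clumped-cell count into a projected area: cells in a stack overlap, so a
   three-cell rouleau covers only ≈ 2.43 singlet areas at the generator's
   chain spacing (below). The default 0.75 centres the threshold in the
   gap between every two-cell union (≤ ~1.72 singlet areas) and every
   three-cell union (≥ ~2.43); values much above ~0.79 start rejecting
   genuine three-cell rouleaux through rasterization wobble alone.
9. **Stability check**: the selection is recomputed at the area cutoff
   × (1 ± 5%); regions that flip status are reported, the perturbation is
   halved and re-checked up to three passes, and a selection that never
   stabilizes is flagged for review with both candidate sets — the loop is
   bounded by construction.
10. **Morphology classes** from the skeleton of each aggregate: an
    unbranched chain (≤ 2 endpoints, no branch clusters) is a *rouleau*;
    1–3 branch clusters a *branched* aggregate; more than 3 a *network*;
    degenerate regions stay unclassified. Adjacent branch pixels are merged
    into one branch cluster so a single junction is not counted twice.

Border-touching regions are measured, flagged, and included in the indices
by default (`include_border` switches this). No multiple-testing correction
is applied by default; a Holm option exists.

## Synthetic scenes

The generator emulates the study's imaging conditions so every stage can be
validated against exact ground truth. Objects are unions of discs of radius
8 px (the pixel calibration of the source imagery is not published; the
radius and the µm-per-px convention of 0.44 are package conventions,
exposed in `SceneSpec`):

* *rouleau* — a near-straight chain with centre spacing 1.2 × radius
  (heading jitter ≤ 0.25 rad), giving the coin-stack projected overlap;
  each extra cell adds ≈ 0.715 of a disc area;
* *branched* — a chain of ≥ 4 cells with 1–3-cell side-chains sprouting at
  `branch_probability` per interior cell, roughly perpendicular to the
  chain;
* *network* — 2–4 branched units attached end-to-anchor while a
  `network_merge_probability` coin keeps coming up heads;
* *singlet* — one disc.

Placement is uniform at random with a 2 px background gap between objects
(so labeling can separate them) until the requested areal coverage — the
proxy for the 2% imaging hematocrit — is met within ±10% relative; objects
that cannot be fitted are retried as progressively smaller classes, an
object whose union overshoots the coverage band is removed again, and a
coverage that remains unreachable raises an error naming the achieved
value. Objects are placed fully inside the field by default: the truth
cell count of an edge-clipped aggregate would refer to cells outside the
field that no area criterion can see. `allow_border=True` restores
clipped-and-flagged placement for users who want edge effects.

Rendering uses phase-contrast polarity — cell interiors at gray 60, a 1 px
halo rim at 190, background at 128 — then a multiplicative horizontal
illumination gradient (relative amplitude up to 0.5) and additive Gaussian
noise, clipped to 8 bits. With no degradation the rendered image thresholds
exactly back to the truth mask, which is what makes pixel-exact validation
possible. All randomness flows through one `numpy` generator seeded from
`SceneSpec.seed`; per-image seeds in datasets derive from the master seed
by a stated counter scheme (`seed·1000003 + counter mod 2³¹−1`), so
datasets reproduce byte-for-byte piecewise.

The high-shear transition keeps each aggregate with probability
`aggregate_stability` (geometry preserved exactly) and re-places the cells
of dispersed aggregates as non-touching singlets, conserving total cell
count.

### Group profiles

Three profile factories encode the clinical groups as generator recipes.
Their areal densities are derived from target aggregation indices via the
expected aggregate-area share of the morphology mix, so the truth AI_L of
a rendered field matches the group mean of the source tables:

| profile | target AI_L | morphology weights (singlet/rouleau/branched/network) | aggregate stability |
|---|---|---|---|
| control | 0.085 | 0.45 / 0.42 / 0.11 / 0.02 | 0.060 |
| non-severe PE | 0.107 | 0.45 / 0.30 / 0.20 / 0.05 | 0.056 |
| severe PE | 0.149 | 0.50 / 0.12 / 0.20 / 0.18 | 0.074 |

The stabilities are calibrated as AI_H/AI_L of the corresponding group
means (0.005/0.085 etc.), so a LOW→HIGH run reproduces the ≈ 94% AI
reduction of controls. Weights are package design (the source states no
composition); they are singlet-rich because published fields show many
free cells around the aggregates, and because the singlet population is
what anchors the cell-area estimate. Mild default degradations
(noise SD 10 of 255, gradient amplitude 0.1) emulate routine acquisition.

By default, samples within a group differ only through their derived seeds
(placement stochasticity, a few percent CV in AI). An optional
`between_sample_cv` lognormally scatters the per-sample density target for
users who want patient-like heterogeneity; it is off by default. Note that
at the published patient-level spreads (CV ≈ 34% for severe PE) the 8-vs-6
rank-sum comparison is *not* reliably significant — the published
between-patient SDs are a far stronger stress test than seed noise.

### What the generator does not emulate

Real deformable cells (discs only, no biconcave profiles or orientation),
partial-overlap transparency and defocus, flow motion blur, Dextran
bridging chemistry, channel walls, and camera fixed-pattern noise. Passing
the validation suite therefore shows the measurement chain is correct and
robust to additive noise and shading at the tested levels — not that it
would segment arbitrary clinical imagery without tuning.

## Numerical conventions

* A pixel belongs to a disc when its centre lies within the radius;
  areas are exact pixel counts of the union.
* Otsu ties: the lowest maximizing cut point (library convention); the
  exhaustive between-class-variance search used as its oracle adopts the
  same inclusive-left class convention.
* The aggregate-area cutoff comparison allows a 1e-9 slack so a region
  exactly at the boundary counts as an aggregate (inclusive reading of
  "minimum 3 grouped cells").
* Sample SDs use the n−1 denominator; a single-field sample reports SD 0
  with a flag rather than NaN.
* Exact rank-sum p-values: fraction of all C(n, n_a) mid-rank assignments
  whose rank sum deviates from the null mean by at least the observed
  amount (two-sided by symmetry of deviations, valid under ties).
* Percent presentation rounds to the nearest integer and folds to one
  decimal, as in the source narrative; raw values are always stored
  alongside.
* Degenerate inputs fail loudly and specifically: constant images
  (flagged, not divided by zero), empty manifests, non-numeric table
  cells, zero-variance correlation inputs, missing cell-area priors.

## Problem sizes in the validation suite

The full 1600 × 300 field is used wherever single scenes are measured
(noise-free oracle equivalence, the noise/gradient robustness sweep). The
replicated group experiment (8 + 6 samples × 5 fields × 100 replicates,
and the LOW→HIGH shear run) uses 480 × 150 px fields: AI is an intensive
per-area quantity, so the calibration carries over unchanged while the
experiment stays desk-sized. The published patient tables themselves are
inputs, not simulation outputs — absolute patient values are not
recoverable from synthetic data, only the calibrated relations between
them.

## Known limitations

* The area→cell-count conversion assumes the generator's packing geometry;
  strongly folded 3-D aggregates in real imagery would need a recalibrated
  packing factor.
* The cell-area estimator requires a visible singlet population (≥ 3 free
  cells among a sample's fields); fields consisting solely of large
  aggregates need the explicit prior.
* NA counts only objects meeting the ≥ 3-cell criterion; an
  include-everything variant is available through `min_cells=1`.
* The morphology classifier sees 2-D skeleton topology only; a tightly
  curled rouleau whose skeleton self-touches can grade as branched.
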