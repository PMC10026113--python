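# Methods

This note documents the models, conventions and numerical choices behind
`myoshape`, and what its synthetic-data tests do and do not demonstrate
about real microscopy data.

## Problem setting

Skeletal-muscle-derived cell (SMDC) cultures are heterogeneous: the
fraction of true myogenic precursors, and hence the culture's capacity to
form multinucleated myotubes, varies between donors. The package's core
hypothesis is operational: the shape of proliferating cells in label-free
brightfield imaging, measured early (12–24 h), carries information about
the fusion index measured only after 5 days of differentiation. The
pipeline therefore has two halves: per-image measurement (segmentation →
descriptors → tracking) and cohort-level screening (descriptor summaries
× fusion index × demographics).

## Segmentation chain

Brightfield SMDC are elongated, low-contrast objects on a textured
background. The chain is, in order:

1. **Line enhancement** — `white_tophat − black_tophat` with a disk
   structuring element (default radius 7 px), rescaled to [0, 1]. This
   amplifies ridges narrower than the element (≈15 px) in any direction;
   flat background maps to a common mid value. A consequence worth
   knowing: objects *wider* than the element are hollowed out, so the
   stage assumes spindle-like cells.
2. **Three-class Otsu** — the image is Gaussian-smoothed
   (σ = `smoothing_scale`, default 1.3488 px; the scale is interpreted
   directly as the Gaussian σ, and is configurable), histogrammed into
   256 bins over [0, 1], and the threshold pair maximising the
   three-class between-class variance is found by an exhaustive
   prefix-sum scan over all bin pairs. The foreground is the middle plus
   upper class (pixels above the lower threshold): in enhanced
   brightfield the cells are the brighter phases and the lowest class is
   background/dark rims. The lower threshold is floored at
   `threshold_lower_bound` (default 0.74) — the guard that keeps
   illumination drift from pulling the cut into the background; in
   practice this floor, not the Otsu optimum, usually decides the cut.
3. **Primary objects** — 8-connected labelling, discarding components
   with equivalent diameter < 13 px. 8-connectivity is used throughout
   because thin diagonal cells fragment under 4-connectivity.
4. **Merge** — objects whose minimum pixel-centre-to-pixel-centre
   distance is ≤ 4 px get one label, closed transitively. A 3-px empty
   gap corresponds to distance 4, so it merges; a 6-px gap (distance 7)
   does not. Merging is idempotent and preserves pixel membership.
5. **Major-axis filter** — objects with moment-based major axis < 15 px
   are removed and labels re-compacted to 1..n.

Coordinates are 0-based (row, col) with the origin at top-left. The
threshold correction factor is fixed at 1 (no correction). Confluence is
the foreground pixel fraction.

## Shape descriptors

Descriptors follow the conventions of widely used measurement software
(MATLAB-style regionprops moments), with explicit choices where digital
geometry forces one:

- **Compactness** = 2π · (mean squared pixel distance from the centroid)
  / area. The 2π factor is deliberate: the unnormalised ratio evaluates
  to 1/(2π) for a disk, so without it the defining property "a filled
  circle has compactness 1" fails. This normalisation is validated on a
  radius-50 digital disk (value 1.000).
- **Axis lengths / eccentricity** — eigenvalues λ₁ ≥ λ₂ of the pixel
  coordinate covariance with the standard +1/12 per-pixel correction
  (a pixel is a unit square); axis lengths are 4√λ, eccentricity
  √(1 − λ₂/λ₁). A single pixel thus has axis length 4/√12 ≈ 1.15, not 0.
- **Feret diameters** — rotating calipers on the convex hull of pixel
  *corner* points (pixel centres ± 0.5), so a 1-px line has minimum
  Feret 1 rather than 0. Max Feret is the hull diameter; min Feret is
  the minimum over hull edges of the farthest vertex distance from the
  edge's line. Verified against an exhaustive 0.1°-step projection sweep
  to within 0.5 % on random blobs.
- **Perimeter** — default estimator is 4-direction Cauchy–Crofton
  (`skimage.measure.perimeter_crofton`), chosen because the classical
  weighted contour-step estimator (1 lateral, √2 diagonal) overestimates
  a digital circle's perimeter by ≈5 %, which would push the form factor
  of a disk to ≈0.91 and break the "form factor = 1 for a circle"
  property. Crofton gives 0.992 on a radius-50 disk. The step estimator
  remains available (`perimeter_method="chain"`). Crofton slightly
  underestimates axis-aligned rectangles (≈6 %); no descriptor property
  used downstream depends on that regime.
- **Radii** — Euclidean distance transform to the nearest background
  pixel; maximum/mean/median over object pixels.
- **Solidity** — area over the corner-point convex-hull area, consistent
  with the Feret construction (a rectangle has solidity exactly 1).
- **Neighbour distances** — centroid-to-centroid; the first-closest
  distance requires ≥2 objects, the second ≥3. Undefined statistics
  (SD of a single object, neighbours of a singleton) are NaN, never 0.

Per-image summaries are the object means and sample (n−1) SDs plus the
total labelled area.

## Tracking and growth timing

Frame linking is greedy nearest-neighbour with a hard gate (default
70 px at 5-min frames): candidate pairs sorted by ascending distance
(ties broken by lower (row, col)), each object used once; unmatched
objects end or start tracks. The greedy matcher is deterministic and
auditable; the configured average cell diameter (45 px) is carried for
interface fidelity but not used by the matcher. Motility is *cumulative
path length* (not net displacement) over an inclusive time window — a
2-h window at 5-min cadence spans 25 frames, 24 steps — averaged over
tracks alive for the whole window. The doubling time is the linearly
interpolated time at which the per-frame object count first reaches
twice its first-frame value; NaN if never reached.

## Fluorescence and colour assays

The fusion index assigns each nucleus to the MHC⁺ 8-connected component
containing its centroid (centroid membership rather than pixel majority:
deterministic and robust to thin boundaries); components with ≥2 nuclei
are myotubes; the index is nuclei-in-myotubes over all nuclei. A quality
flag marks images with fewer than 500 MHC⁺ cells. Per-donor values are
unweighted means over the five fields (centre + four cardinal points).

CD56 per nucleus: cell regions grow from each nucleus by nearest-nucleus
assignment capped at 30 px; an optional support mask restricts regions
to stained cytoplasm so background does not dilute the mean. The
CD56-vs-nearest-nucleus-distance relation is a Spearman report.

β-Gal positivity: a cell is positive when ≥10 % of its pixels fall in
the blue hue window 180–260° at saturation ≥ 0.15 (HSV). All three
cut-offs are configuration values — the underlying laboratory criterion
is visual ("presence of blue staining"), so the defaults are a
reasonable operationalisation, not measured constants.

## Plate assay

Standards are a 7-member 1:3 dilution series from 1000 mU/mL
(1000 … 1.37). The blank is subtracted from every OD; the standard curve
is piecewise linear in log-concentration (a 4-parameter logistic is
available behind `model="logistic4"`); non-monotone standard ODs are
repaired by pool-adjacent-violators with a warning. Duplicate sample
wells are averaged before inversion; ODs outside the standard range are
flagged (`below_range`/`above_range`) and never extrapolated.

## Cohort statistics

Spearman rank correlation uses mid-ranks and the t-approximation for
p-values (matching common software at n = 14); an exact permutation
p-value is available for n ≤ 9. A coefficient with |r| > 0.5 is flagged
"correlated" (the screen's rule of thumb), and screen cells are
additionally flagged at p < 0.05. No multiple-testing correction is
applied by default — the screen reports raw per-descriptor p-values —
and missing assay values are handled by pairwise-complete deletion with
n reported per cell. Mann-Whitney and Wilcoxon use exact enumeration for
small samples (pooled n ≤ 12, and ≤ 10 non-zero pairs respectively),
computed on |statistic − mean| so ties are handled consistently;
otherwise tie-corrected normal approximations. The chi-square test is
Pearson's without continuity correction. The asymptotic chi-square
p-value is validated against a Monte-Carlo permutation oracle at sample
sizes where the 1-df reference applies (n = 200); at very small n the
asymptotic and conditional-permutation answers genuinely differ, which
is a property of the tests, not of the implementation.

## Synthetic data: what it emulates, and what it does not

The generators define the test conditions for every stage:

- **Brightfield scenes** — non-overlapping rotated ellipses (semi-major
  ≈ 17 px, elongation 3 → width ≈ 11 px, inside the enhancement
  element's working range) with a bright interior (0.88), a 1.5-px dark
  halo just outside the truth boundary (the optical shadow at the cell
  edge), and a background of 0.50 plus smoothed Gaussian texture.
  Non-overlap, and inter-cell gaps larger than the merge distance, are
  enforced at placement so the ground truth stays unambiguous —
  mirroring the profiling regime, which deliberately measures cells that
  do not overlap. Placement is rejection sampling with bounded retries;
  infeasible densities raise an error naming the achieved count.
- **Time-lapses** — per-cell random walks with Rayleigh step lengths of
  the requested mean and uniform directions; collisions and
  out-of-bounds moves are re-drawn. Identity is preserved in truth.
- **Fluorescence scenes** — myotubes are elongated capsules holding 2–4
  nuclei spaced 22 px along the axis; remaining nuclei sit in
  mononucleated cells; placement uses capsule (segment + radius)
  separation so dense, fully fused scenes still pack. The truth fusion
  index is exact by construction.
- **Cohorts** — ages uniform on 16–92 (the study span, with no stated
  distribution), fusion index = clip(0.8 − 0.005·age + N(0, 0.1), 0, 1),
  senescence fraction rising with age, CD34 falling with fusion index,
  marker percentages and BMI drawn around cohort-scale values. Under
  these defaults the population age–fusion-index correlation is ≈ −0.74,
  and 200-cohort Monte-Carlo means recover the closed-form value
  slope·sd(age)/√(slope²·var(age) + σ²) to within ±0.1.

Deliberately *not* modelled: optical point-spread functions, uneven
illumination, cell–cell contact and overlap, division or fusion dynamics
during a time-lapse, stain variability, or photorealistic texture.
Passing the recovery tests therefore shows the chain is correct and
self-consistent in its intended operating regime (well-separated
elongated cells at adequate contrast); it does not certify performance
on crowded or low-contrast real micrographs, where the threshold floor
and merge distance typically need per-dataset adjustment. Magnification
is not modelled either: all synthetic work is in pixel units.

## Problem sizes and tolerances in the test suite

Synthetic recovery tests use 512-px scenes with 12 cells over 10 seeds
(object count within ±10 %, per-object IoU ≥ 0.7), fluorescence scenes
with 60 nuclei across fusion fractions {0, 0.2, 0.5, 0.8, 1} (recovery
within ±0.05), 200-seed cohort Monte-Carlo runs, and 200-replicate
permutation screens (false-positive rate 0.05 ± 0.03 at α = 0.05).
Feret oracle agreement is 0.5 % over 50 random blobs; disk-normalised
descriptors are checked to 2 % (digitisation error at radius 50);
rectangle Feret closed forms to 1 px. These sizes keep the whole suite
under a minute while leaving each check statistically meaningful.
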