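# myoshape

Cell-shape profiling for predicting the myogenic potency of cultured
skeletal-muscle-derived cells (SMDC).

Autologous muscle-cell therapies need a potency readout before cells are
implanted. The standard readout — the **fusion index**, the fraction of all
nuclei residing in myosin-heavy-chain-positive myocytes with two or more
nuclei after differentiation — takes days to obtain. `myoshape` implements
the alternative: profile the *shape* of proliferating cells in label-free
brightfield time-lapse images early in culture, and screen those shape
descriptors against the fusion index and donor characteristics across a
cohort.

The package provides, as composable library modules with a thin CLI:

- **Segmentation** of elongated (spindle-shaped) cells in brightfield
  frames: line-structure enhancement (difference of white/black top-hats,
  disk radius 7 px), three-class Otsu thresholding with the middle class
  as foreground and a 0.74 floor on the lower threshold, 8-connected
  object identification (minimum diameter 13 px), merging of objects
  within a 4 px gap, and a 15 px minimum-major-axis filter. Confluence is
  the foreground area fraction.
- **Shape profiling**: the 19-descriptor suite per object — area A,
  bounding-box area, compactness (2π·E[d²]/A, 1 for a filled circle),
  eccentricity, equivalent diameter √(4A/π), extent, form factor
  4πA/P², moment-based major/minor axis lengths, min/max Feret diameters
  by rotating calipers, max/mean/median medial radii, perimeter, solidity,
  and first/second closest-neighbour distances — plus per-image means,
  SDs and total area occupied.
- **Tracking**: greedy nearest-neighbour frame linking with a 70 px gate,
  windowed path lengths (e.g. 2 h at 12 h and 24 h of imaging), and the
  time for the per-frame object count to double.
- **Fluorescence assays**: fusion index from DAPI/MHC masks, per-nucleus
  CD56 intensity over distance-grown cell regions, nucleus neighbour
  distances, and the β-galactosidase blue-positive senescent-cell
  fraction from colour fields.
- **Plate assays**: acetylcholinesterase activity from OD 405 nm readings
  via a 1:3 serial-dilution standard curve (1000 → 1.37 mU/mL, 7
  standards), blank correction and monotone interpolation.
- **Cohort statistics**: Spearman/Pearson correlation reports (|r| > 0.5
  rule of thumb), Mann-Whitney, paired Wilcoxon and chi-square tests with
  exact small-sample paths, per-sex demographic summaries, and the
  descriptor × timepoint × passage fusion-index correlation screen.
- **Synthetic data**: generators for brightfield scenes, time-lapses,
  stained fluorescence scenes, senescence fields, OD plates and donor
  cohorts — all with exact ground truth, so every stage is testable
  without microscope data.

A transcribed 14-donor reference cohort (age 16–92, M/F 5/9, fusion
index per donor) ships with the package (`myoshape.load_donor_cohort()`).

## Worked example

```python
import myoshape as ms

# a synthetic brightfield field of 12 spindle cells, then the full chain
scene = ms.make_cell_scene(n_cells=12, size=512, seed=1)
labels = ms.segment_pipeline(scene.image)
summary = ms.summarize_image(labels)
print(f"objects found: {summary.n_objects} (truth: {scene.truth_mask.max()})")
print(f"mean major axis: {summary.means['major_axis_length']:.1f} px")
print(f"mean eccentricity: {summary.means['eccentricity']:.3f}")

# cohort-level statistics on the bundled 14-donor table
cohort = ms.load_donor_cohort()
rep = ms.product_moment_correlation(cohort["Age"], cohort["FusionIndex"])
print(f"age vs fusion index: r = {rep.r:.3f}, p = {rep.p:.3f}, n = {rep.n}")
```

prints

```
objects found: 12 (truth: 12)
mean major axis: 31.5 px
mean eccentricity: 0.952
age vs fusion index: r = -0.579, p = 0.030, n = 14
```

All twelve synthetic cells are recovered at the default configuration;
their measured shape (long axis ≈ 31 px, eccentricity ≈ 0.95) reflects the
elongated cell geometry the segmentation chain is tuned for. On the donor
cohort, age correlates negatively with the fusion index (r ≈ −0.58,
p = 0.03): older donors' cells fuse less.

From a shell, the same steps are:

```sh
myoshape simulate sim/ --n-cells 12 --size 512 --seed 1
myoshape profile sim/ out/            # per_object.csv, per_image.csv
myoshape correlate sim/cohort.csv out/corr
```

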