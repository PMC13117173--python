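# Methods

`nucrisk` implements a recurrence-risk pipeline for resected lung squamous
cell carcinoma (LSQCC) built on quantitative nuclear morphometry of H&E
histology: per-nucleus shape and chromatin-texture features, cell-level
co-occurrence (CFLCM) heterogeneity aggregation over 1 mm² regions of
interest (ROIs), a six-model SVM / random-forest ensemble over three
recurrence horizons, and an integer risk score integrated with pathologic
stage. Because the original slide images and clinical tables are not
publicly available, the package ships a first-class synthetic-data module
that generates cohorts with the statistical structure the analysis assumes;
all benchmarks run against it.

## Per-nucleus morphometry (90 features)

Input is a labelled nucleus mask (one positive integer per nucleus, 0
background) plus the matching grayscale image. Coordinates are 0-based
pixel centres, `x` rightward / `y` downward; orientation is the
principal-axis angle from +x, axial on [0, 180)°. Nuclei touching the image
border are excluded by default (truncated shapes bias the size features).

The exact composition of the 90-entry vector is not dictated by the
analysis it supports — only its total and a set of named members are — so
the registry (`nucrisk.registry`) freezes one explicit composition:

* **24 shape descriptors** — area, perimeter (Crofton estimator, nearly
  unbiased on smooth digital boundaries so a disk's form factor stays ~1),
  form factor 4πA/P² (clipped to 1), eccentricity, solidity, extent,
  major/minor axis, aspect ratio, equivalent diameter, convex area,
  max/mean/median centroid-to-pixel radius, compactness, roundness,
  bounding-box area and aspect, maximum Feret diameter, orientation
  (circular), and the first four Hu moments.
* **66 texture descriptors** — 8 Haralick statistics (ASM, contrast,
  correlation, variance, homogeneity, entropy in bits, dissimilarity,
  energy) of the within-mask gray-level co-occurrence matrix at the four
  distance-1 offsets, their isotropic means, isotropic means at distance 2,
  and 18 first-order intensity statistics of the masked pixels.

The GLCM is accumulated **only over pixel pairs that both lie inside the
nucleus mask** (8 gray levels, per-nucleus min–max scaling, symmetric). A
constant-intensity nucleus degenerates cleanly: contrast 0, ASM 1, entropy
0, correlation defined as 1. Offsets with no valid pair fall back to the
same degenerate form.

## CFLCM ROI aggregation (960 features)

Each nucleus is collapsed to one grid cell ("one nucleus = one pixel"):
centroids are rasterized at a pitch equal to the median nearest-neighbour
distance (configurable), anchored at the centroid bounding box so the
occupancy pattern is translation invariant. When two nuclei share a raster
cell the displaced one moves to the nearest free cell via a deterministic
ring search processed in a canonical position-derived order, keeping the
nucleus→cell map one-to-one and independent of table row order. With the
default generator geometry a median ~4% of nuclei per ROI need relocation.

Each nuclear feature is quantized to G = 8 levels by equal-frequency
binning with one deliberate refinement: equal values always share the level
of their lowest-ranked member, so a constant feature occupies a single
level and cannot manufacture spurious heterogeneity. Axial features
(orientation) use equal-width bins of the doubled angle instead. A
symmetric co-occurrence matrix is accumulated over occupied neighbouring
cells (4 distance-1 offsets); if no neighbouring pair exists the ROI is
flagged and the level distribution is placed on the diagonal.

The 960-entry vector = 90 × (mean, variance, 8 co-occurrence heterogeneity
statistics) + 60 ROI-global spatial descriptors (density, nearest-neighbour
spacing, quadrat dispersion, convex-hull geometry, Clark–Evans index,
circular orientation statistics, occupancy-grid texture, neighbour
alignment). Orientation means/variances are circular (doubled-angle
resultant). Every positional statistic is computed relative to the centroid
cloud, making the entire vector invariant to global translation. ROIs with
fewer than 10 nuclei are skipped with a warning.

## Study design and tasks

Cases carry stage I–III, a recurrence indicator and months of
recurrence-free follow-up; non-recurrent cases require ≥ 24 months of
follow-up for inclusion. Eight recurrence/follow-up categories stratify the
hold-out split (recurrence ≤12 / 13–24 / 25–60 / >60 months → 1–4;
no recurrence with follow-up 24–36 / 36–60 / 60–84 / ≥84 months → 5–8;
these bin edges are configurable defaults chosen to respect the 2- and
5-year horizons). The split draws round(0.25·n) cases per category (round
half up) into a frozen test set, strictly at the case level so no patient's
ROIs straddle the sets.

Three tasks: recurrence within 2 years (REC2; the 24-month boundary counts
as "within"), within 5 years (REC5), and the three-category horizon
(≤2y / 3–5y / >5y-or-none). Non-recurrent cases with follow-up under 60
months are ambiguous for the 5-year horizon and are used for REC2 training
only — the reason three separate models exist rather than one.

## Models

Each task is fitted twice on ROI-level rows: a linear-kernel SVM (features
z-standardized with training statistics, probabilities by Platt-type
sigmoid calibration fitted on internal 5-fold splits of the training data,
one-vs-one in the multiclass case) and a 500-tree random forest on raw
features (√p features per split, out-of-bag error reported; tree-averaged
class distributions serve as the one-vs-rest vote fractions). No class
reweighting or hyperparameter search — deliberately "default settings".
A case's likelihood is the arithmetic mean over its ROI likelihoods.
Cross-validation folds partition cases, never ROIs.

## Risk scoring

For each scoring unit the SVM/RF likelihood pair is coloured: red (2 pts)
when both ≥ 0.5, orange (1 pt) when exactly one, blue (0 pts) otherwise;
0.5 itself counts as positive. The default schema uses **five units** —
REC2, REC5, and the three class pairs of the three-category task (≤2y,
3–5y, and "any recurrence" = 1 − P(>5y/none)) — because a 10-point maximum
is attainable only with five 2-point units; pairing the six models into
three units would cap the score at 6, inconsistent with the published 6–10
high-risk band. AI-score bands: high 6–10, middle 3–5, low 0–2 (0 is
attainable and mapped to low). Total score = AI score + stage score
(I = 1, II = 2, III = 3); bands high ≥ 7, middle 3–6, low ≤ 2. A red REC2
unit raises an early-recurrence flag used only for temporal stratification
in survival displays; it never alters points.

## Evaluation

ROC/AUC with midrank tie handling (AUC = Mann–Whitney statistic; the
three-class task reports one-vs-rest AUC per class plus the macro mean),
confusion matrices, Kaplan–Meier recurrence-free-survival curves per
stage / AI group / total group, and k-group log-rank tests. Survival
machinery is delegated to lifelines, ROC to scikit-learn; worked
product-limit examples in the tests pin both to hand computations.

## Synthetic cohorts

Each case draws a latent aggressiveness a ~ N(0,1). Two noisy copies
z_orient = (a+ε₁)/√2 and z_tex = (a+ε₂)/√2 drive morphology:
orientation concentration κ = exp(1.2 − 0.9·z_orient) (aggressive tumours
lose nuclear alignment) and mean texture contrast exp(0.8 + 0.5·z_tex)
(aggressive tumours gain chromatin contrast). The recurrence hazard is
exponential with rate
`baseline · exp(β_orient·z_orient + β_tex·z_tex + γ·(stage−1))`;
defaults: baseline 0.01/month, β_orient 1.5, β_tex 0.8, γ 0.4 per stage
step, independent exponential censoring at 0.008/month capped at 120
months, stage mix (58.4, 21.6, 20.0)% matching the motivating surgical
cohort. Cases are resampled until the inclusion rule is met. Nucleus
orientations are axial von Mises (doubled-angle trick) around a per-ROI
mean direction; areas log-normal (median ≈ 350 px², realistic for 20×
scans at ~0.5 µm/px); eccentricities 0.35–0.90 via a Beta draw; derived
shape features follow exact ellipse formulas plus small noise; texture
features are monotone transforms of the per-nucleus contrast draw.
Centroids are placed on a jittered grid (guaranteed minimum separation, no
overlap at default density). Defaults: 21 ROIs/case, 150 nuclei/ROI.

The image path (`render_roi`) paints each nucleus as a rotated filled
ellipse carrying a smoothed-Gaussian chromatin field whose amplitude grows
with the contrast target, over a pale hematoxylin-tinted background, plus a
16-bit label mask. It deliberately does **not** model realistic H&E colour,
stroma, lymphocytes, overlapping nuclei or out-of-focus blur — so passing
tests demonstrate that the pipeline recovers planted morphological signal,
not that it handles real staining variation or segmentation error.

## Numerical choices and edge cases

* Degenerate co-occurrence matrices (single level, no pairs) return
  ASM 1 / entropy 0 / correlation 1 rather than raising.
* Equal-frequency ties: merged to the tied group's first level (see above).
* Recurrence at exactly 24 or 60 months counts as within the horizon
  (closed bounds, fixed for determinism).
* Singleton split strata go to training; the split never empties the
  training side of a stratum.
* Every stochastic component takes an explicit integer seed; identical
  parameters and seed reproduce byte-identical cohort tables and pipeline
  outputs.

## Benchmark problem sizes

The simulation benchmark in the acceptance tests uses 200 cases × 10
ROIs × 150 nuclei per cohort, ten pinned seeds each for the strong-effect
and null conditions — large enough for stable test-set AUC estimates while
keeping the full suite comfortably runnable on a single CPU. Under the
strong-effect defaults the 2-year linear-SVM test AUC clears 0.80 in at
least 8 of the 10 pinned seeds; under the null condition each seed's
pooled two-fold cross-fit case AUC stays inside [0.40, 0.60]; and pooled
recurrence rates rise monotonically across low/middle/high total-score
groups.

## Known limitations

* The 90- and 960-entry registry compositions are explicit stand-ins; the
  original feature lists were never published. Alternative compositions can
  be configured but change the vector length.
* Orientation recovered from rendered masks is accurate to ~2° for clearly
  elongated nuclei but degrades near the circular limit (eccentricity
  ≈ 0.4, ~300 px²), where single-pixel boundary jitter dominates; the
  round-trip tests therefore bound the error in distribution rather than
  per nucleus.
* The synthetic hazard is exponential (constant over time); no competing
  risks, and death without recurrence is treated as censoring.
* Stage enters only the hazard and the total score; the models never see
  it as a feature.
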