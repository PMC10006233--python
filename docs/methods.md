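# Methods

This note documents the models, conventions and numerical choices behind
`imcseg`, in the order the pipeline runs. Conventions throughout: 0-based
`(row, col)` pixel coordinates, areas in px², intensities in raw detector
counts, 1 px = 1 µm unless a ROI says otherwise.

## Preprocessing

**Hot pixels.** IMC detectors produce isolated spike pixels. A pixel whose
value exceeds the maximum of its existing 8-neighbours by strictly more
than `hot_pixel_threshold` (default 50 counts) is replaced by that maximum.
The rule is evaluated in one pass over the original image; it is provably
idempotent (a replaced pixel takes a value that is itself a neighbour
maximum, so no second-pass trigger can appear) and never increases any
value. The threshold is a convention of IMC preprocessing and is exposed so
users can match other variants.

**Background subtraction.** Uneven staining background is removed by
subtracting a Gaussian blur of the channel from itself (`blur_sigma`,
default 40 px — much larger than a cell, so cells survive and plateaus are
removed). The blur uses reflective boundaries and a kernel truncated at 4σ;
these two choices do not follow from the procedure itself and are fixed so
results are bit-reproducible. Negative residuals are clamped to zero
because the downstream weight transform requires nonnegative input.

**Weight transform.** The background-corrected channel becomes DBSCAN
weights: values strictly below the `low_percentile` (default 30) are set to
0, values are clipped at the `high_percentile` (default 99.5), and the
result is divided by its new maximum so the top weight is exactly 1.
Percentiles use linear interpolation over the full pixel population (zeros
included); computing them over nonzero pixels only is available via
`percentile_population="nonzero"` since the original convention is not
recorded. "Below" is strict, which preserves the degenerate all-equal image
(all weights 1) and the all-zero image (all weights 0, no division).

## Weighted DBSCAN

Positive-weight pixels are points `(row, col, weight)`. The transformed
intensity acts as a *sample weight*, not a third coordinate: a point is a
core point iff the weights of all points within Manhattan distance
`eps = 2` (itself included) sum to at least `min_weight = 4`. Treating the
weight as a coordinate would make an integer `min_samples` incoherent with
fractional weights; the sample-weight reading matches the weighted-DBSCAN
contract of mainstream implementations, and the test suite cross-checks the
core-point sets and core partitions against scikit-learn's `DBSCAN` with
`sample_weight`. `leaf_size = 3` is recorded in the configuration for
fidelity with the original tooling but is a tree-search performance
parameter with no effect on output.

DBSCAN leaves two things implementation-defined, fixed here for
determinism: (i) a border point (positive weight, non-core, within eps of a
core) joins its *nearest* core point, with equidistant ties resolved toward
the lowest cluster id; (ii) cluster ids are ordered by the row-major
position of each cluster's first core pixel during border assignment, and
final labels are re-compacted by the row-major position of each cluster's
first member pixel. The result is independent of input point order, and the
implementation (grid neighbourhood sums + sparse connected components) is
tested for exact agreement with a brute-force O(n²) oracle on random maps.
Whether a point's own weight counts toward its core sum is not recorded in
the original description; it is included here (both the implementation and
the oracle), which only matters within 1 weight unit of the threshold.

## Local maxima and cluster splitting

Touching cells merge into one DBSCAN cluster; the pipeline splits clusters
at the local maxima of the background-corrected image (not the weight map).
A pixel is a maximum candidate if it is positive and not below any
neighbour within the footprint; connected equal-valued plateaus merge into
one maximum represented by the lexicographically smallest coordinate. A
cluster containing m ≥ 2 maxima is split into m clusters, each pixel
joining its nearest contained maximum (Euclidean distance, ties to the
lexicographically smaller maximum); clusters with 0 or 1 maxima are
unchanged — a zero-maximum cluster is possible since weights and maxima
derive from different transforms, and it is retained as-is.

The operation's contract is the classical 8-neighbour (3×3) test, and
`detect_local_maxima` defaults to that. The *pipeline* default footprint
radius (`maxima_footprint_radius`) is 4 px (9×9): on count data a 3×3 test
detects a maximum at nearly every counting-noise spike — on a simulated
256×256 ROI it yields ~10 in-cluster maxima per true cell, shattering every
cluster into fragments that the subsequent erosion annihilates — whereas a
footprint at the cell-blob scale (two real intensity peaks closer than
~4 µm cannot be distinct cells here) recovers exactly the per-cell peaks.
The radius is configurable, including back to 1.

## Typing, erosion, area filter

Every CD31 region is an endothelial cell. For each Vimentin region, the
overlap fraction is |pixels ∩ union of all CD31-positive pixels| / own
area; strictly above `overlap_discard_fraction = 0.30` the region is
discarded (a Vimentin⁺CD31⁺ vessel), otherwise it is a fibroblast. The
denominator is the Vimentin region's own area and the numerator uses the
union over all CD31 regions — the most literal reading of "overlap by more
than 30 % of their area". CD68 regions are segmented and retained untyped;
no macrophage analysis is performed.

Typed cells are shrunk by `erosion_iterations = 3` passes of binary
erosion with the 3×3 cross (4-connected) structuring element — the most
plausible reading of "erosion of a factor of 3 pixels", with the 3×3 square
available via configuration. Pixels beyond the image border count as
background. Erosion may empty a region; empty regions fall to the area
filter (area 0 < 10) without special casing. The area filter keeps
`min_area = 10` ≤ area ≤ `max_area = 800` px², both bounds inclusive since
the discard rule is "strictly smaller / strictly bigger". The stage order
is literal: typing, then erosion, then the area filter.

## Quantification

Marker means (LYN, THBS1 by default) are computed over the *eroded* pixel
set on the hot-pixel-cleaned **raw** channels: the blur subtraction and
weight transform are segmentation aids applied only to the lineage
channels, and quantification channels never pass through them. Values are
variance-stabilised as asinh(x / c) with cofactor c = 5 counts, the
standard mass-cytometry convention. No cross-ROI or batch normalisation is
applied; conditions are compared on pooled per-cell arcsinh values.

## Statistics

`compare_groups` pools all cells of one type across ROIs and samples within
each condition and applies Welch's unequal-variance t-test (two-sided;
Student's variant behind `equal_var=True`). Welch is the robust default for
the unequal per-group cell counts typical of such cohorts. Pooling treats
cells as independent and ignores per-sample clustering — faithful to
per-cell violin-plot analyses, but a known limitation: with strong
per-sample random effects the pooled test is anti-conservative. The
degenerate both-groups-constant-and-equal case returns t = 0, p = 1 (df
reported as n₁+n₂−2, since Welch–Satterthwaite is undefined there).

Box summaries use linear-interpolation quantiles (the common default; the
estimator is not otherwise recorded) and Tukey adjacent values: the
smallest observation ≥ Q1 − 1.5·IQR and the largest ≤ Q3 + 1.5·IQR. Violin
KDE rendering is presentation, not computation, and is out of scope.

`cross_layer_concordance` selects identifiers shared by two fold-change
tables with |log₂FC| above the threshold (default 0.8) in *at least one*
layer and returns the Spearman rank correlation (average ranks on ties).
Whether the original filter applied to one or both layers is ambiguous;
"both" is available via `mode="both"`. Fewer than three selected
identifiers is an error rather than a meaningless coefficient.

## The simulator

`generate_roi` emulates the structure the pipeline assumes in Hyperion
data, with defaults chosen as one realistic ROI: 750×750 px at 1 µm/px,
150 cells (a plausible stromal density at this field size), centres
rejection-sampled with ≥ 15 px separation, isotropic Gaussian blobs of
scale σ = 4 px truncated at 3σ (a ~10 µm cell), a flat background of
1 count, Poisson counting noise (the physically appropriate model for ion
counts; Gaussian and noise-free variants are available), and hot pixels at
rate 1e-4 and 200 counts. Lineages are fibroblast (60 %, Vimentin⁺),
endothelial (25 %, CD31⁺ plus weak Vimentin so the overlap-discard rule is
exercised, mirroring real Vimentin⁺CD31⁺ vessels), and "other" (15 %,
CD68⁺). Type counts are apportioned exactly (largest remainder), so truth
counts are deterministic given n.

Per-cell amplitudes are mean-preserving log-normal draws (default mean 30
counts for lineage markers, 20 for LYN/THBS1, coefficient of variation 0.3,
independent across channels); a group effect factor f for (group, type,
channel) multiplies the mean exactly, so simulated effects are calibrated
by construction. One `numpy` generator per ROI, seeded as
`base_seed + roi_index`, makes cohorts reproducible without inter-ROI
correlation.

What the simulator does **not** model: laser-ablation physics, isotope
spillover, autofluorescence, non-circular cell shapes, spatial tissue
architecture, per-sample (patient-level) random effects, and cross-channel
amplitude correlation within a cell. Passing recovery tests therefore shows
the pipeline is correct under its own assumptions, not that it is robust to
every artefact of real tissue.

**Scoring.** `evaluate_segmentation` matches predicted centroids to truth
centres greedily by ascending distance (one-to-one, types must agree,
distance ≤ match radius) and reports precision/recall/F1 plus the Pearson
correlation between matched cells' measured raw mean intensity and true
amplitude. Evaluation is restricted to the typed lineages (fibroblast,
endothelial) by default, because the typing stage deliberately leaves CD68
cells unassigned. One property of this design is worth stating plainly:
even with near-perfect detection, the measured mean over a cell's eroded
region equals amplitude × (mean blob factor over the region), and the
region extent varies with the independent lineage-marker brightness; under
the default amplitude dispersion this extent variability bounds the
amplitude-recovery Pearson r at about 0.92–0.94 (conditional on extent, the
measurement is essentially exact, r ≈ 0.996).

## Problem sizes

The test suite and acceptance script use one full-size ROI (750×750,
150 cells) for recovery, and scaled-down cohorts (2 × 6 ROIs of 256×256 px,
~40 cells each) for effect recovery plus 100 replicates of the same cohort
for null calibration — sizes at which each experiment's Monte-Carlo error
is small relative to the properties asserted.
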