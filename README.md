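# imcseg

Density-based single-cell segmentation, cell typing and marker
quantification for imaging mass cytometry (IMC), with a synthetic
ground-truth simulator and two-group per-cell statistics.

## The problem

IMC reads out metal-isotope-tagged antibodies by laser ablation and mass
cytometry, producing one low-count intensity image per marker for each
ablated region of interest (ROI, here 750 µm × 750 µm at 1 µm/px). To
compare stromal marker expression between conditions — e.g. LYN kinase or
THBS1 in lymph-node fibroblasts from leukemia patients versus healthy
controls — the images must be turned into single cells with per-cell marker
intensities. `imcseg` implements that computation for users who have
channel TIFFs in hand and want a deterministic, auditable pipeline:

1. **Hot-pixel removal** — a pixel exceeding its 8-neighbour maximum by
   more than a threshold (default 50 counts) is replaced by that maximum.
2. **Background subtraction** — each lineage channel minus a σ = 40 px
   Gaussian blur of itself, clamped at zero.
3. **Weight transform** — values below the 30th percentile are zeroed,
   clipped at the 99.5th percentile, and divided by the new maximum, giving
   per-pixel weights w ∈ [0, 1].
4. **Weighted DBSCAN** — positive-weight pixels (x, y, w) are clustered
   under the Manhattan metric with ε = 2; a pixel is a core point iff
   Σ w over its ε-neighbourhood (itself included) ≥ min_samples = 4.
5. **Local-maxima splitting** — clusters containing several local maxima of
   the background-corrected channel are split, each pixel joining its
   nearest maximum.
6. **Typing** — CD31⁺ regions are endothelial cells; Vimentin⁺ regions
   overlapping CD31⁺ pixels by more than 30 % of their own area are
   discarded (Vimentin⁺CD31⁺ vessels), the rest are fibroblasts; CD68
   regions are segmented but left type-unassigned.
7. **Erosion and area filter** — 3 passes of binary erosion (4-connected
   cross), then cells with area outside [10, 800] px² are dropped.
8. **Quantification** — per-cell mean raw intensity of LYN and THBS1 on the
   cleaned channels, variance-stabilised as asinh(x / 5).
9. **Statistics** — per-cell arcsinh values pooled per condition are
   compared with Welch's independent two-sided t-test; box summaries are
   Tukey's (median, quartiles, adjacent values). A helper computes the
   Spearman concordance of log₂ fold changes shared between two omics
   layers after an |log₂FC| > 0.8 filter.

Because patient IMC images of this kind are typically not public, the
package ships a first-class simulator (`imcseg.simulate`) that renders
multi-channel ROIs of Gaussian-blob cells from three lineages with
background, Poisson counting noise and hot pixels — with full ground truth
(centres, types, per-channel amplitudes, label masks) — so every stage of
the pipeline is verifiable end to end.

## Worked example

```python
from imcseg import SimulationConfig, generate_cohort, run_cohort, compare_groups

cfg = SimulationConfig(
    image_size=(256, 256), n_cells=40,
    group_effects={"CLL-LN": {"fibroblast": {"LYN": 1.5}}},
)
cohort = generate_cohort(cfg, {"HC-LN": 3, "CLL-LN": 3}, base_seed=7)
table, results = run_cohort([roi for roi, _ in cohort])
comp = compare_groups(table, "LYN", "fibroblast")
print(f"{comp.group_a.group}: n={comp.group_a.n}, median={comp.group_a.median:.3f}  "
      f"{comp.group_b.group}: n={comp.group_b.n}, median={comp.group_b.median:.3f}")
print(f"Welch t = {comp.t_statistic:.2f}, df = {comp.degrees_of_freedom:.1f}, "
      f"p = {comp.p_value:.3g}")
```

prints

```
CLL-LN: n=72, median=2.113  HC-LN: n=70, median=1.745
Welch t = 8.05, df = 137.4, p = 3.5e-13
```

Six small ROIs yield 203 cells; the simulated ×1.5 fibroblast LYN effect in
the CLL-LN group is recovered as a higher median arcsinh intensity
(2.113 vs 1.745) and a strongly positive Welch t (CLL-LN minus HC-LN),
while endothelial cells, which carry no effect, are unaffected. The same
stages are available from a shell via the `imcseg` console script
(`simulate`, `segment`, `compare`, `concordance`).

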