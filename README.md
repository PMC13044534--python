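# tmequant

Single-cell quantification of the tumor microenvironment (TME) from
multiplexed imaging and mass cytometry, built for studies comparing
primary and metastatic pancreatic ductal adenocarcinoma (PDAC) — and for
anyone who needs calibrated, reproducible per-cell phenotyping from
whole-slide single-cell exports.

The package takes per-cell measurement tables (QuPath-style exports: cell
id, centroid in µm, mean intensity per marker channel), grayscale pixel
arrays for collagen scoring, and mass-cytometry event tables, and produces
the quantities such studies report: marker positivity calls with explicit
false-positive guarantees, exclusive phenotype compositions and densities,
spatial distance/community/margin structure, and Boolean checkpoint
co-expression profiles. Because cohort-scale patient data are rarely
shareable, a synthetic-tissue generator with planted ground truth is a
first-class module: every pipeline stage is validated by recovering what
the generator planted.

## What it computes

**Gating.** Per image and marker, intensities are compressed with
`asinh(x / c)` (cofactor `c = 150`) and thresholded by exact two-class
1-D k-means (the global within-class variance-minimizing split), falling
back to `median + 3·MAD` (MAD unscaled) for unimodal channels. Thresholds
are clipped into `[floor, cap]`: caps at a per-image high percentile (99th
for the fibroblast panel) and floors calibrated on unstained negative
controls — either the control 99.5th percentile (macrophage panel) or the
control `(1 − q)` quantile for a per-marker false-positive budget `q`
(PDPLN 5%, PDGFRβ 10%, CK19 4%, αSMA 1%). Positivity is strict
(`intensity > threshold`), so the in-sample control FPR never exceeds its
budget, by order statistics. Images with fewer than 500 cells are excluded.

**Phenotyping.** Exclusive lineage labels by configurable precedence
(default CK19 > CD3 > CD19 > CD68 > αSMA, with CD4+CD8+ double positives
as their own class on the T-cell panel); myCAF (αSMA⁺IL6⁻) vs iCAF
(αSMA⁺IL6⁺) subtyping; percentages of total and of phenotyped cells;
densities per occupancy-grid tissue area; collagen positive-area fraction;
transcription-factor profiles per T-cell subset.

**Spatial.** Directional nearest-neighbor summaries (median and minimum of
per-reference-cell nearest-target distances), hierarchically clustered
target ordering, phenotype networks (node = percent of cells, edge
attraction `exp(−d/λ)`), spin-glass community detection with a fixed seed
(123), and four tumor-structure regions (intratumoral, internal margin,
external margin, stroma) from a rasterized tumor mask, with per-region
infiltration of non-tumor cells.

**Mass cytometry.** Bead exclusion and Gaussian-parameter/event-length
percentile cleanup, cisplatin live gate, DNA1/DNA2 singlet box, ≥500
live-cell sample retention, hierarchical lineage gating (CD45± → CD3⁺ T →
CD4/CD8/double-positive; CD3⁻CD19⁺ B), 25-event parent cutoffs, B-cell
subset rules, and 32-way Boolean combination frequencies over the five
checkpoints CTLA4, LAG3, PD-1, TIGIT, TIM3.

**Statistics.** Mann–Whitney (exact for small tie-free samples), Wilcoxon
signed-rank, two-way ANOVA (type-II SS), Šídák/Bonferroni adjustment.

## Worked example

Calibrating the fibroblast-panel gates on a synthetic 20,000-cell unstained
control (`examples/02_gating_calibration.py`):

```
marker   method        floor    final    control FPR  budget
PDPLN    mad_fallback  0.2549   0.2549    5.00%      5%
PDGFRb   mad_fallback  0.2194   0.2358    7.12%      10%
CK19     mad_fallback  0.2675   0.2675    4.00%      4%
aSMA     mad_fallback  0.3328   0.3328    1.00%      1%
```

Each row shows the arcsinh-scale control floor, the final threshold after
clipping, and the fraction of control cells the calibrated gate calls
positive — at or below the marker's budget in every case. PDGFRβ sits
below its 10% budget because the adaptive raw threshold already exceeds
the budget floor.

Gating and phenotyping a synthetic metastatic image and comparing against
the planted truth (`examples/03_phenotype_composition.py`):

```
class  pct_of_total   planted
CK19          39.79     40.19
CD3            6.11      6.20
CD19           2.95      2.96
CD68           7.78      7.86
aSMA          10.62     10.71
other         32.75     32.08
```

The full pipeline recovers every planted class fraction to well under one
percentage point at 10,000 cells. The other scripts in `examples/`
demonstrate the spatial layer (distances, communities, margin regions),
the mass-cytometry chain (checkpoint combinations), and the cohort
statistics, each printing its results with a note on what they mean.

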