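# Methods

This note records the models, conventions and numerical choices behind
`tmequant`, and what the synthetic validation does and does not establish.

## Synthetic cohort model

The generator (`tmequant.synthgen`) emulates the statistical structure of
whole-slide single-cell exports and mass-cytometry event tables, with the
planted truth carried alongside every table.

**Marker intensities** are two-component log-normals per marker: background
`LogNormal(µ₋, σ₋)` and stain `LogNormal(µ₊, σ₊)` in arbitrary fluorescence
units (defaults µ₋ = 3.0, µ₊ = 6.0, σ = 0.4; validation enforces µ₋ < µ₊).
Fluorescence is right-skewed and multiplicative-noise-like, which is what
makes the arcsinh compression downstream meaningful; the default positive
location sits above the background 99.9th percentile, so the two
populations are separable in principle and gating error, not model overlap,
drives recovery error.

**Composition** is planted per site by a multinomial draw over exclusive
phenotype labels (not fixed counts), so recovered fractions carry sampling
error of order `sqrt(p(1−p)/n)` — about 0.5 pp at the default 10,000 cells
per image — and all recovery tolerances are stated against that. The
default site profiles plant the cohort means reported for primary vs.
metastatic disease where those are published (αSMA 25.5%/11.2%, CD68
2.44%/8.29%, CD4 3.19%/5.04%, CD8 7.99%/0.90% of nucleated cells); the
remaining fractions are chosen once as plausible cohort values (scarce
T cells in metastases, a larger epithelial compartment there) and are not
tuned. Modifier states (IL6; T-bet/FoxP3/RORγt; CAF co-markers) are
independent Bernoulli draws conditional on the lineage label.

**Spatial layout** (µm, origin top-left, y downward — the image
convention of whole-slide exports): tumor (CK19⁺) cells uniform over a few
planted circular nests; a configurable fraction of immune cells placed
around shared community anchors with Gaussian scatter; T cells thinned
inside nests by rejection (acceptance 0.2) to plant an infiltration
gradient; everything else uniform. This is the simplest mechanism that
makes nearest-neighbor structure, community detection and margin mapping
non-trivial. Median within-nest tumor–tumor nearest-neighbor distance is
verified against the analytic complete-spatial-randomness mean `0.5/√λ`.

**Collagen images** are uint8 arrays with a circular tissue region on a
dark slide background; tissue pixels carry bright fiber signal with the
planted probability. Fixed classifier levels (tissue > 30, signal > 128)
sit many noise SDs from both pixel populations, so the recovered area
fraction differs from the planted one only by Bernoulli error (< 0.15 pp
at 512²).

**Mass-cytometry events** carry a bead flag, four Gaussian acquisition
parameters and event length (standard normal for clean events; merged ion
clouds displaced ±8σ with an independent random sign per channel, so
two-sided percentile windows catch them), a cisplatin viability channel
and DNA1/DNA2 intercalators (log-normal mixtures with planted dead,
debris and doublet classes; doublets are sums of two singlet draws),
lineage channels per subset, and the five checkpoint channels. Checkpoint
positivity on T cells follows a Gaussian copula: a latent per-cell
exhaustion score shared across markers (correlation ρ, default 0.5) is
thresholded at each marker's marginal quantile, so marginals are exact by
construction and joint positivity exceeds independence for ρ > 0 (ρ = 0
recovers independence, which the tests verify by counting).

**Determinism.** Every generator call derives its RNG stream from
`(config.seed, CRC32 of operation and identifiers)`; identical configs
give byte-identical outputs, independent of call order.

What the generator does *not* emulate: segmentation error and cell-shape
features, spatial intensity gradients and batch effects, spectral
spillover between channels, marker-correlated backgrounds, irregular
tissue boundaries, or realistic image texture. Passing recovery tests
therefore shows the *quantification machinery* is correct and calibrated
under its stated model, not that these defaults span real staining
variability.

## Gating

* Quantiles everywhere (floors, caps, percentile floors) are type-7
  (linear interpolation between order statistics), stated once here.
* Two-class 1-D k-means is solved exactly: the optimal two-cluster
  partition in one dimension is a contiguous split of the sorted values,
  found by prefix sums over the n−1 cut points (ties broken toward the
  lowest cut). This removes any iteration/initialization dependence,
  makes gating permutation-invariant by construction, and guarantees the
  threshold agrees with an exhaustive variance-minimizing scan.
* MAD fallback: `median + 3·median(|x − median|)`, MAD unscaled (no
  1.4826 factor). On a log-normal background this threshold sits near the
  95th percentile, so the fallback alone over-calls a few percent — the
  control floors exist precisely to bound that.
* Unimodality criterion (the choice of k-means vs. fallback): declare
  unimodal when the two k-means centers are separated by less than
  3.5× the pooled within-cluster SD, or when the smaller cluster holds
  under 0.2% of cells. The factor matters: two-class k-means splits even
  a pure Gaussian into halves ~1.6σ apart with pooled within-SD ~0.6σ
  (ratio ≈ 2.7), so any factor below that would call every unimodal
  channel bimodal; 3.5 leaves balanced mixtures separated by ≥ 4σ on the
  bimodal side (ratio ≈ 3.6). The size guard is kept tiny so genuinely
  rare populations (down to ~0.5% positive cells) are still split by
  k-means rather than swallowed by the fallback.
* Positivity is strict (`> threshold`); ties at the threshold are
  negative. Combined with type-7 floors at the `(1−q)` control quantile,
  the fraction of calibration controls above the floor is ≤ q exactly.
* Caps are computed per image (whether a cohort-level cap was intended is
  ambiguous; per-image is flagged in `PanelSpec` and configurable via the
  transform/cap fields). FPR floors are applied on the transformed scale
  so floors and data share one scale.
* The adaptive (non-CAF) imaging panel also gates on the arcsinh scale by
  default: the k-means midpoint on the raw skewed scale cuts into the
  positive cluster (~10% false negatives at the default intensity model),
  while on the compressed scale the residual error is a few tenths of a
  percentage point. Manual per-marker overrides (`manual_gates`) reproduce
  the visual-cutoff workflow.

## Phenotyping

Lineage precedence CK19 > CD3 > CD19 > CD68 > αSMA: epithelial identity
dominates (CK19 marks the malignant compartment), immune lineages before
stroma. Published panels do not state how multi-lineage-positive cells are
resolved, so the order is configurable and combination classes (CD4⁺CD8⁺)
are matched before single markers. Tissue area is an occupancy grid with a
50 µm default bin (~2 cell diameters); it is a surrogate for the true
stained area, so density checks compare pipeline output against truth
computed with the same surrogate. The myCAF:iCAF ratio is undefined
(reported missing) when a sample has no iCAF.

## Spatial analysis

Distance summaries are directional by design (ref→target ≠ target→ref);
missing classes yield missing entries, never zeros. Cohort pooling is the
element-wise median across per-image summaries. The community network
inverts distances into attractions `exp(−d/λ)` because spin-glass
community detection needs positive affinities; λ defaults to the cohort
median of all pairwise summaries and is configurable. Community detection
runs the igraph spin-glass sampler (25 spins, γ = 1) under a seeded RNG
(default 123); because annealing can stall on small graphs, it restarts
five times from seeds derived deterministically from the main seed and
keeps the highest-modularity partition — still bit-reproducible. On
planted ≤ 8-node two-block graphs the result matches exhaustive
modularity maximization over all set partitions.

Tumor-structure mapping rasterizes tumor-cell counts on a 50 µm grid;
mask bins exceed 25% of the mean non-empty tumor-bin count; only the
largest connected component is analyzed when the mask fractures, and
pinholes (sampling-noise bins inside the mask) are filled — they are not
real stroma. Margins extend 100 µm on either side of the mask boundary by
default. Eligibility for infiltration analysis is a deterministic
surrogate for a human "clear tumor–stroma boundary" call: the mask must
cover 5–95% of occupied tissue bins and the boundary must span at least
10 bins. All three constants are explicit parameters, chosen once; they
are surrogates, not reconstructions of any published tool's internals.

## Mass cytometry

Cleanup windows default to the 1st–99th percentile per sample and channel
(two-sided, inclusive). The live gate and DNA box are taken at the
generator's known mixture valleys in synthetic mode (`default_*_gates`);
real data supply a manual threshold table, matching practice where gates
are set against healthy-donor references. Sample retention (≥ 500 live
cells) and parent cutoffs (≥ 25 events) are inclusive at the boundary and
monotone in their thresholds. The checkpoint combination order is fixed
to CTLA4 → LAG3 → PD-1 → TIGIT → TIM3 throughout, including the sunburst
table. B-cell subset rules are a configurable table; the defaults
(naïve IgD⁺CD27⁻, memory CD27⁺, regulatory-potential PD-1⁺ and/or PD-L1⁺,
extrafollicular IgD⁻CD27⁻, plasmablast-like CD27⁺IgD⁻Ki67⁺, proliferating
Ki67⁺) are conventional definitions, not a reconstruction of any
particular published rule set.

## Statistics

Mann–Whitney is exact (full enumeration via the hypergeometric null) for
combined n ≤ 12 without ties, otherwise normal approximation with tie and
continuity corrections; Wilcoxon signed-rank drops zero differences, is
exact for n ≤ 15 tie-free, and degenerates to p = 1 (flagged) when all
differences are zero. Two-way ANOVA uses type-II sums of squares because
per-sample class percentages are unbalanced across sites; percentage
responses are analyzed untransformed. Šídák `1−(1−p)^m` and Bonferroni
`min(1, mp)` adjustments; Šídák never exceeds Bonferroni. Significance is
0.05 two-sided throughout.

## Validation scale

The test suite and acceptance script run at desk scale, chosen as the
package's own validation conditions: 10,000 cells per image and 20,000
control cells for imaging recovery and calibration; 50,000 events per
CyTOF sample; 1,000 simulations for null-calibration checks and 200 for
the ANOVA power check; brute-force oracles at n ≤ 2,000 (k-means), n ≤ 500
(nearest neighbors) and ≤ 8 nodes (modularity). The end-to-end determinism
check runs a reduced cohort (2 samples/site, 3,000 cells/image, 10,000
events/sample) — determinism is independent of problem size.

## Known limitations

* The MAD fallback is weak on sparse positives (majority ties give MAD 0);
  the floor/cap clipping is the guard, and channels with ≥ ~0.5% positives
  are handled by the k-means path instead.
* The unimodality test is a heuristic; mixtures separated by less than
  ~3.5 pooled SDs are deliberately routed to the conservative fallback.
* Occupancy-grid area underestimates sparsely populated tissue and
  depends on the bin size; densities are comparable within a cohort run
  with one bin size, not across conventions.
* Spin-glass modularity optimization is exact only as verified on small
  planted graphs; on larger graphs the restart-best partition is
  reproducible but carries no global-optimality guarantee.
* CyTOF thresholds in synthetic mode assume the generator's known
  mixtures; real-data use depends entirely on the supplied manual gates.
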