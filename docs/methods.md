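# Methods

This note documents the models, the numerical choices, and what the synthetic
data does and does not establish.

## Data model and conventions

Internal coordinates are 0-based half-open; GTF input (1-based inclusive) is
converted on read. The TSS of a transcript is its 5′-most transcribed
position in transcript orientation and the PAS its 3′-most; *upstream* always
means upstream in the direction of transcription, so reversing the strand
swaps TSS and PAS and leaves length invariant. A transcript is *coding* iff
its `transcript_biotype` is `protein_coding`; UTR/CDS lengths are derived from
CDS records when present and are otherwise missing. Transcripts without a
transcript support level are retained with TSL missing and removed only by
the TSL1 filter, so the filter semantics live in one place.

## QC and pseudobulk

Barcode filters are applied in order: (1) at least 100 detected genes and at
most 20% mitochondrial content (genes matching `^mt-` by symbol, the mouse
convention; the regex is configurable); (2) of the survivors, barcodes whose
detected-gene count strictly exceeds the empirical 98th percentile are
removed. Computing the percentile on the post-filter set and removing with
strict inequality makes toy cases exact (1,000 barcodes with distinct counts
lose exactly 20).

The transcript prevalence filter keeps an isoform iff it is TSL1 and detected
in ≥0.5% of the cells of at least one cell-type × sex × region stratum. It is
applied to cells, before pseudobulking.

Pseudobulk units are (sample, cell type) count sums. Size factors are
median-of-ratios: the reference is the per-isoform geometric mean over units
restricted to isoforms positive in every unit, and a unit's factor is the
median of its count/reference ratios (computed in linear space — the even-
count median differs between linear and log space). When no isoform is
positive everywhere, the pipeline falls back to a gene-level reference.
Usage is computed from raw pseudobulk counts (it is scale-free) and is
missing where a gene's total is zero.

## Dirichlet-multinomial differential usage

For a gene with J isoforms, counts in unit *u* are modeled
`x_u ~ DM(n_u, γ·π)`; γ (the concentration or precision) controls
overdispersion relative to the multinomial, which the γ → ∞ limit recovers.
Proportions at fixed γ are fitted by the standard MM fixed-point update
(renormalized so the concentration stays at γ), stopping when the
log-likelihood improves by less than 1e-8 or after 200 iterations;
non-convergence is flagged, not dropped. γ is profiled by bounded scalar
search on log γ ∈ [log 1e-2, log 1e6]; endpoints are checked explicitly so
under-dispersed genes return the upper bound.

The gene-level test compares per-group usage vectors against a shared one
with a likelihood-ratio statistic referred to χ² with (G−1)(J−1) df. The
concentration is treated as a nuisance profiled under each hypothesis: the
null fit uses its own common-proportions estimate; the full fit uses a
Cox–Reid-adjusted full-model estimate (the adjustment subtracts half the log
determinant of the observed information of each group's fitted proportions,
so profiling γ is not biased by the per-group overfit). Two alternatives
were tried and rejected: holding a null-estimated γ fixed for both fits
absorbs genuine switches into apparent overdispersion and collapses power
(an extreme two-group reversal only reaches p ≈ 0.009), while holding the
unadjusted full-model γ fixed for both fits leaves a heavy null tail
(several of 450 null genes below p = 0.001 at depth 2,000). The adopted
profile LRT detects the extreme reversal at p ≈ 1e-12, gives no null gene
below p = 0.001 in the same simulation, and has type-I error ≈ 0.05–0.08 at
the hardest tested condition (two groups of six units, depth 500) — a known
mild small-sample anticonservativeness of dispersion-estimated LRTs that
shrinks with more units. No information is shared across genes.

Feature-level results collapse each isoform against the rest of its gene and
run the analogous beta-binomial LRT (df = G−1) at the gene's full-model γ.
The effect size is the mean per-unit usage in the group of interest minus the
mean in the other groups; its sign defines the "high usage" / "low usage"
direction. Multiple testing is Benjamini–Hochberg within each scan.

One-vs-rest cell-type contrasts pool all other cell types into a single
group. At the bundled fixture scale the pipeline pools sexes and regions
within a scan (two units per sex × region stratum cannot support the fit);
per-stratum scanning is a config switch.

## Usage-weighted attributes

`A_g = Σ_i u_i a_i` with usages summing to 1 (tolerance 1e-6). TSS and PAS
positions are normalized per gene: the most upstream site (in transcription
direction) is bin 0 and the others are binned by `floor(distance/bin)` with
20 nt TSS bins and 75 nt PAS bins. Coding potential is encoded +1/−1. For
condition deltas, the reference of a one-vs-rest comparison is the unweighted
mean of the other groups' A values (balanced across unequal group sizes), and
the TSS delta is negated so that positive deltas uniformly mean longer
isoforms, upstream TSS, downstream PAS, and higher coding potential. CDS and
UTR metrics are computed only for genes with at least two protein-coding
isoforms, with usages renormalized over the coding isoforms; genes whose
attribute is undefined for an expressed isoform are excluded for that
attribute. The top increasing/decreasing isoform pair of a gene (ties broken
lexicographically by isoform id) is compared on {TSS, PAS, exon count,
length, coding potential}; attribute-delta couplings are Spearman rank
correlations across genes, reported with their sample size and undefined
below three genes.

## Temporal trajectories

Traces are size-factor-normalized pseudobulk expression divided by the young
value, per (isoform, cell type); traces with zero young expression are
dropped with a reason. The screen fits flat and quadratic Gaussian models on
centered age and uses `lr = n · log(RSS_flat/RSS_quad)` with χ² df 2. In the
pipeline the screen runs on per-sample observations (replicates at each age)
rather than the four collapsed age means: with only four points the quadratic
is nearly saturated and the χ² reference badly calibrated, while at n ≈ 8–12
per trace it is usable and at n = 100 (the calibration simulations) the null
p-values are uniform. Constant traces give lr = 0 exactly; traces fitted
exactly by a quadratic (RSS_quad ≤ 1e-12 · RSS_flat) give p = 0.

Clustering fits a mixture of quadratic mean curves with cluster-specific
isotropic variances by EM (responsibilities in the log domain; 10 restarts
keeping the best log-likelihood; empty or zero-variance clusters trigger a
restart). The cluster count is chosen from the candidate grid {8, 10, 12,
14} by mean silhouette on per-trace standardized vectors — each trace is
centered and scaled by its own standard deviation, since per-timepoint
scaling would amplify pure noise at the young point, which every trace fixes
at 1. Clusters are ordered by increasing geriatric/young fold change of
their mean curve. This quadratic mixture is a declared simplification of
spline mixed-effects clustering with the same contract (grouping by temporal
shape), consistent with the quadratic screening model. Geriatric ages that
differ by sex (27 vs 31 months) are averaged on the trace grid.

The length analysis computes per-isoform log₂((old + 0.5)/(young + 0.5)) on
normalized expression (pseudocount 0.5, a standard stabilizer), keeps
transcripts in the top 50% of either age, splits them into length tertiles,
and compares tertile distributions with a two-sided Wilcoxon rank-sum test
(normal approximation, tie-corrected; all-tied inputs return p = 1).

## Senescence

The raw score of a cell is the mean expression of all marker-gene isoforms
after scaling the cell's counts to 10,000 (depth-invariant by construction);
"mean over marker isoforms" rather than per-gene sums is the adopted reading,
and the per-gene alternative can be built from `usage_features`. The
normalized score divides by the mean raw score of young cells of the same
cell type, so young cells average exactly 1 per type; cell types without
young cells are excluded with a reason. Thresholds are strict: senescent
iff norm > 5; machine-learning labels 0 iff norm < 4, 1 iff norm > 7,
otherwise excluded — boundary values fall in the guard band or on the
non-senescent side.

Marker discovery reuses the DM scan on immune pseudobulk units split by
(sample, senescence label), all timepoints pooled, at BH padj < 0.01, and
requires at least two units per group. Classifier features are per-cell
isoform usages of the marker genes with undefined usage (gene total zero)
left as missing and routed natively by the trees; PCA mean-imputes instead.
The 90/5/5 split is stratified by label × age × sex × region and guarantees
at least one cell of each label in validation and test whenever the label has
three cells overall (plain rounding would silently empty the 5% splits of a
rare class). XGBoost runs with learning rate 0.01, binary logistic
objective, aucpr evaluation, approximate tree method, max depth 7, min child
weight 16, subsample 0.9967762267267729, per-split column subsample
0.4100293732438932, L2 6.001086886655973, up to 10,000 rounds with 50-round
early stopping on the validation split, single-threaded for determinism.
Reported metrics (ROC curve, AUROC, average precision) come from the
held-out test split.

## Synthetic data

The generator emulates the study design: four age timepoints (4, 16, 22.5,
and 27/31 months by sex), both sexes, five cell types at brain-like
proportions (35% neuron, 25% oligo, 20% astrocyte, 10% vascular, 10%
immune), 500 genes with 1–4 isoforms, and ~2,000 UMIs per cell. Per-cell
gene totals are Poisson with a log-normal depth factor (σ = 0.35) — the
simplest model producing realistic sparsity; isoform splits are
Dirichlet-multinomial with γ = 30. Planted effects: 10% of genes get a
cell-type usage switch and 10% an age-onset switch (Δu = 0.3; baselines are
pinned so the shift fits in the simplex), 20 genes get senescence-coupled
switches, every gene follows one of eight quadratic temporal shapes, and 5%
of immune cells in aged samples are senescent with 10× marker expression
over 20 marker genes. One global seed feeds a counter-based child seed per
operation, so outputs do not depend on call order.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, sequencing error, cell-type-specific depth, gene-gene correlation,
or realistic gene-length/expression couplings. Passing tests therefore
demonstrate that the implementations are correct and calibrated under the
stated model, not that the pipeline is robust to the artifacts of real
long-read single-cell data.

## Problem sizes

The default dataset (2,000 cells, 500 genes) runs the full pipeline in under
a minute on one CPU; the calibration simulations use 1,000 null genes (DM
type-I), 500 genes (power/FDR), 2,000 traces (trajectory null), 800 traces
(clustering recovery), and 5,000 cells (classifier null), chosen so each
check has enough resolution for its acceptance band while the whole suite
stays fast.
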