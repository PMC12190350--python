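# isousage

Single-cell RNA **iso**form **usage** analysis for aging time-course designs.

Long-read single-cell sequencing quantifies full-length RNA isoforms per cell,
which makes it possible to ask not just *how much* a gene is expressed but
*which isoform* of it each cell type uses, and how that choice shifts with
age. `isousage` is a library for that analysis: it takes a barcode × isoform
UMI matrix, an Ensembl-dialect GTF, and cell metadata (cell type, age, sex,
brain region), and provides

- **QC and pseudobulk**: the barcode filters (≥100 detected genes, ≤20%
  mitochondrial content, ≤98th percentile of detected genes), the transcript
  filters (TSL1 support, detected in ≥0.5% of the cells of some
  cell-type × sex × region stratum), (sample, cell type) pseudobulk sums,
  DESeq-style median-of-ratios size factors, and within-gene isoform usage
  `u_i = x_i / Σ_j x_j`.
- **Differential isoform usage** via a Dirichlet-multinomial model: counts of
  a gene's isoforms in unit *u* follow `x_u ~ DM(n_u, γ·π)` with concentration
  γ; the gene-level test is a likelihood-ratio test of per-group usage vectors
  π_g against a shared π (χ², df = (G−1)(J−1)), with γ a profiled nuisance
  (Cox–Reid-adjusted under the full model). A per-isoform beta-binomial test
  gives feature-level effects ("high usage"/"low usage"). The same scan runs
  one-vs-rest cell-type contrasts (cell-type isoform-specific genes), pairwise
  age contrasts (age isoform-specific genes), and senescent-vs-normal
  contrasts.
- **Usage-weighted attribute metrics**: `A_g = Σ_i u_i·a_i` for attributes
  a_i ∈ {length, TSS bin, PAS bin, coding potential (±1), exon count, CDS/UTR
  lengths}; TSS and PAS are binned from the most upstream site of the gene (20
  nt / 75 nt bins), and condition deltas follow the sign convention *positive
  = longer / upstream TSS (negated) / downstream PAS / more coding*.
- **Temporal trajectories**: per-(isoform, cell type) expression traces
  normalized to the young timepoint, a quadratic-vs-flat Gaussian LRT screen
  (χ², df 2), EM clustering with quadratic mean curves and silhouette-based
  selection of the cluster count, and length-tertile log₂ fold-change tests.
- **Senescence**: per-cell marker scores (counts scaled to 10,000; normalized
  by the young-cell mean of the same cell type; senescent if the normalized
  score exceeds 5), isoform-usage marker discovery (BH padj < 0.01), usage
  PCA, and an XGBoost classifier on per-cell isoform usages with a stratified
  90/5/5 split.
- **A synthetic-data generator** that emulates all inputs with planted,
  recorded ground truth (cell-type and age usage switches, temporal shapes, a
  senescent immune subpopulation), so every component is testable end to end.

## Worked example

```sh
python examples/02_differential_usage.py
```

simulates the default dataset (2,000 cells over 4 ages × 2 sexes, 500 genes),
applies QC, and scans immune cells against all others:

```
tested 331 genes; 25 significant at p<0.05
planted immune switches: 10 (7 testable after QC), recovered: 7
median weighted-length delta over significant genes: -53 nt
```

Ten genes carried a planted immune-specific usage shift (Δu = 0.3); seven
survive the TSL1/prevalence filters with ≥2 isoforms, and the scan recovers
all seven. The negative weighted-length delta says immune cells shift usage
toward shorter isoforms of the significant genes, measured by the
usage-weighted length difference against the mean of the other cell types.
The other scripts in `examples/` walk through QC (`01`), trajectory screening
and clustering (`03`), and senescence scoring + classification (`04`).

The whole pipeline also runs from a declarative YAML config:

```sh
isousage run --seed 1 --out run1        # or: isousage run --config cfg.yaml
isousage simulate --seed 1 --out fixture/
```

`run` executes simulate/ingest → QC → pseudobulk → cell-type scan →
attributes → trajectories → age scan → senescence, writes TSVs for every
stage, and records a manifest with content hashes; identical configs
reproduce byte-identical outputs.

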