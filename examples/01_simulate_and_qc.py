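"""Generate a synthetic aging-brain isoform dataset and apply the QC filters.

Builds a barcode x isoform UMI matrix over 8 samples (4 ages x both sexes),
then removes low-quality barcodes (<100 detected genes, >20% mitochondrial
content, top-2% detected genes) and weakly supported transcripts (non-TSL1,
seen in <0.5% of cells of every cell-type stratum), and aggregates the result
to (sample, cell type) pseudobulk with median-of-ratios size factors.
"""

from isousage import (
    SimulationConfig,
    filter_barcodes,
    filter_transcripts,
    pseudobulk,
    simulate_dataset,
    size_factors,
)

config = SimulationConfig(seed=1)
catalog, cells, counts, truth = simulate_dataset(config)
print(f"simulated: {len(cells)} cells, {len(catalog)} isoforms, "
      f"{counts.total} UMIs")

counts, cells = filter_barcodes(counts, cells, catalog)
print(f"after barcode QC: {len(cells)} cells "
      f"(min 100 genes, <=20% mito, <=98th percentile detected genes)")

counts = filter_transcripts(counts, catalog, cells)
print(f"after transcript filter (TSL1 + 0.5% prevalence): "
      f"{len(counts.isoforms)} isoforms")

pb = pseudobulk(counts, cells)
pb.size_factors = size_factors(pb)
print(f"pseudobulk: {pb.n_units} (sample, cell type) units; "
      f"size factors span {pb.size_factors.min():.2f}-{pb.size_factors.max():.2f}")
# The factor spread reflects per-unit sequencing depth; usage analyses are
# scale-free and use raw pseudobulk counts.
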