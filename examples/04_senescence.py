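"""Senescence scoring, isoform marker discovery, and classification.

Scores every cell by depth-normalized mean marker expression relative to young
cells of its type, labels cells with a normalized score over 5 as senescent,
discovers genes whose isoform usage differs between senescent and
non-senescent immune cells, and trains a gradient-boosted classifier on the
per-cell isoform usages of those genes.
"""

from isousage import (
    SimulationConfig,
    discover_markers,
    senescence_proportions,
    senescence_score,
    simulate_dataset,
    train_classifier,
    usage_features,
    usage_pca,
)

# an immune-rich population so the classifier has enough labeled cells
props = {"neuron": 0.2, "oligo": 0.15, "astrocyte": 0.15,
         "vascular": 0.1, "immune": 0.4}
cfg = SimulationConfig(seed=5, cell_type_proportions=props, n_cells_per_sample=400)
catalog, cells, counts, truth = simulate_dataset(cfg)

scores = senescence_score(counts, cells, truth.marker_genes, catalog)
props_tab = senescence_proportions(scores, cells)
immune_aged = props_tab[(props_tab.cell_type == "immune")
                        & (props_tab.age_category != "young")]
frac = immune_aged["n_senescent"].sum() / immune_aged["n_labeled"].sum()
print(f"senescent fraction in aged immune cells: {frac:.3f} "
      f"(planted rate {cfg.senescent_fraction})")

markers, scan = discover_markers(counts, cells, scores, catalog)
overlap = len(set(markers) & set(truth.senescence_usage_genes))
print(f"marker discovery: {len(markers)} genes at BH padj<0.01; "
      f"{overlap}/{len(truth.senescence_usage_genes)} planted switches recovered")

immune = cells.df.index[(cells.df["cell_type"] == "immune").to_numpy()]
feats = usage_features(counts.subset_barcodes(immune), catalog, list(markers))
pcs, evr = usage_pca(feats)
print(f"usage PCA: PC1/PC2 explain {evr[0]:.1%} / {evr[1]:.1%} of variance")

ml = scores.df.loc[feats.index, "ml_label"]
labeled = ml.isin(["0", "1"])
clf = train_classifier(feats[labeled], ml[labeled].astype(int),
                       strata=cells.df.loc[feats.index[labeled],
                                           ["age_category", "sex", "region"]],
                       seed=0)
print(f"classifier: test AUROC {clf.auroc:.3f}, "
      f"average precision {clf.average_precision:.3f} "
      f"({labeled.sum()} labeled cells, {len(clf.feature_names)} usage features)")
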