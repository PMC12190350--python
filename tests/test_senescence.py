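import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import make_catalog, make_cells
from isousage.annotation_io import CellTable, CountMatrix
from isousage.senescence import (
    SenescenceError,
    predict_scores,
    senescence_proportions,
    senescence_score,
    stratified_split,
    train_classifier,
    usage_features,
    usage_pca,
)


def marker_setup(norm_scores=None):
    """20 marker genes (1 isoform each) + 1 background gene."""
    rows = [dict(isoform_id=f"m{j}", gene_id=f"M{j}") for j in range(20)]
    rows.append(dict(isoform_id="bg", gene_id="BG"))
    cat = make_catalog(rows)
    markers = [f"M{j}" for j in range(20)]
    return cat, markers


class TestScore:
    def test_raw_score_arithmetic(self):
        """Total 10,000 counts; marker isoform counts (10, 0, ..., 0) give a
        raw score of 10/20 = 0.5 after scaling to 10,000."""
        cat, markers = marker_setup()
        cells = make_cells(1)
        X = np.zeros((1, 21))
        X[0, 0] = 10
        X[0, 20] = 9990
        counts = CountMatrix(cells.barcodes, cat.isoform_ids, sp.csr_matrix(X))
        s = senescence_score(counts, cells, markers, cat)
        assert s.df["raw_score"].iloc[0] == pytest.approx(0.5)

    def test_depth_invariance(self):
        cat, markers = marker_setup()
        cells = make_cells(2)
        X = np.zeros((2, 21))
        X[0, :5] = 10; X[0, 20] = 100
        X[1, :5] = 30; X[1, 20] = 300     # same composition, 3x depth
        counts = CountMatrix(cells.barcodes, cat.isoform_ids, sp.csr_matrix(X))
        s = senescence_score(counts, cells, markers, cat)
        assert s.df["raw_score"].iloc[0] == pytest.approx(s.df["raw_score"].iloc[1])

    def _scored(self, raws, age_categories):
        cat, markers = marker_setup()
        n = len(raws)
        cells = make_cells(n)
        cells.df["age_category"] = age_categories
        cells.df["age_months"] = [4 if a == "young" else 29 for a in age_categories]
        X = np.zeros((n, 21))
        X[:, 0] = raws
        X[:, 20] = 1000 - np.asarray(raws)  # constant totals: exact ratios
        counts = CountMatrix(cells.barcodes, cat.isoform_ids, sp.csr_matrix(X))
        return senescence_score(counts, cells, markers, cat), cells

    def test_threshold_rules(self):
        # young mean marker count 10 -> norm score = raw/young_mean
        raws = [10, 10, 39, 55, 71, 51]
        cats = ["young", "young", "old", "old", "old", "old"]
        s, _ = self._scored(raws, cats)
        ns = s.df["norm_score"].to_numpy()
        assert np.allclose(ns[:2].mean(), 1.0, atol=1e-9)
        assert s.df["ml_label"].tolist()[2:] == ["0", "excluded", "1", "excluded"]
        assert s.df["label"].tolist()[2:] == [
            "non-senescent", "senescent", "senescent", "senescent"]

    def test_boundary_scores_are_strict(self):
        raws = [10, 10, 40, 50, 70]
        cats = ["young", "young", "old", "old", "old"]
        s, _ = self._scored(raws, cats)
        assert s.df["ml_label"].tolist()[2:] == ["excluded", "excluded", "excluded"]
        assert s.df["label"].tolist()[3] == "non-senescent"  # exactly 5 is not over 5

    def test_missing_young_cells_excluded_with_reason(self):
        cat, markers = marker_setup()
        cells = make_cells(2, age_category="old", age_months=29)
        X = np.zeros((2, 21)); X[:, 0] = 5; X[:, 20] = 100
        counts = CountMatrix(cells.barcodes, cat.isoform_ids, sp.csr_matrix(X))
        s = senescence_score(counts, cells, markers, cat)
        assert (s.df["label"] == "excluded").all()
        assert "neuron" in s.excluded

    def test_absent_marker_gene_is_error(self):
        cat, markers = marker_setup()
        cells = make_cells(1)
        counts = CountMatrix(cells.barcodes, cat.isoform_ids,
                             sp.csr_matrix(np.ones((1, 21))))
        with pytest.raises(SenescenceError, match="absent"):
            senescence_score(counts, cells, markers + ["NotAGene"], cat)


class TestRecovery:
    def test_planted_senescence_recovered(self, immune_dataset):
        """Precision and recall of the norm_score>5 label vs planted truth."""
        cfg, (catalog, cells, counts, truth) = immune_dataset
        s = senescence_score(counts, cells, truth.marker_genes, catalog)
        truth_sen = cells.df["senescent"].astype(bool)
        pred = s.df["label"] == "senescent"
        tp = (truth_sen & pred).sum()
        assert tp / max(pred.sum(), 1) >= 0.9       # precision
        assert tp / max(truth_sen.sum(), 1) >= 0.9  # recall
        # young-cell mean normalized score is 1 per cell type
        young = cells.df["age_category"] == "young"
        means = s.df.loc[young.to_numpy(), "norm_score"].groupby(
            cells.df.loc[young, "cell_type"]).mean()
        assert np.allclose(means, 1.0, atol=1e-9)

    def test_proportions_recovered_and_order_invariant(self, immune_dataset):
        cfg, (catalog, cells, counts, truth) = immune_dataset
        s = senescence_score(counts, cells, truth.marker_genes, catalog)
        props = senescence_proportions(s, cells)
        aged_immune = props[(props.cell_type == "immune")
                            & (props.age_category != "young")]
        pooled = aged_immune["n_senescent"].sum() / aged_immune["n_labeled"].sum()
        assert 0.03 <= pooled <= 0.07
        others = props[props.cell_type != "immune"]
        assert (others["fraction"] < 0.01).all()
        perm = np.random.default_rng(0).permutation(len(counts.barcodes))
        s2 = senescence_score(counts.subset_barcodes(counts.barcodes[perm]),
                              cells.subset(cells.barcodes[perm]),
                              truth.marker_genes, catalog)
        props2 = senescence_proportions(s2, cells)
        pd.testing.assert_frame_equal(
            props.sort_values(list(props.columns[:4])).reset_index(drop=True),
            props2.sort_values(list(props2.columns[:4])).reset_index(drop=True))


class TestPCA:
    def test_separated_groups_split_on_pc1(self):
        rng = np.random.default_rng(0)
        a = np.column_stack([np.full(50, 0.9), rng.normal(0, 0.01, 50)])
        b = np.column_stack([np.full(50, 0.1), rng.normal(0, 0.01, 50)])
        f = pd.DataFrame(np.vstack([a, b]), columns=["u1", "u2"])
        scores, evr = usage_pca(f)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:50].min() > pc1[50:].max()) or (pc1[:50].max() < pc1[50:].min())
        assert evr.sum() <= 1 + 1e-9

    def test_identical_cells_give_zero_scores(self):
        f = pd.DataFrame(np.tile([0.3, 0.7], (10, 1)), columns=["u1", "u2"])
        scores, _ = usage_pca(f)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-12)


class TestSplit:
    def _strata(self, n_pos=50, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "label": [1] * n_pos + [0] * (n - n_pos),
            "age": rng.choice(["young", "old"], n),
            "sex": rng.choice(["M", "F"], n),
        })

    def test_split_disjoint_exhaustive_stratified(self):
        strata = self._strata()
        a = stratified_split(strata)
        assert set(a.unique()) == {"train", "validation", "test"}
        assert len(a) == 1000
        assert abs((a == "train").mean() - 0.90) < 0.03
        for split in ("train", "validation", "test"):
            assert strata.loc[a == split, "label"].nunique() == 2

    def test_rare_label_is_error(self):
        strata = self._strata(n_pos=2, n=100)
        with pytest.raises(SenescenceError, match="cannot stratify"):
            stratified_split(strata)


class TestClassifier:
    def _separable(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.Series(rng.integers(0, 2, n))
        X = pd.DataFrame({
            "f1": y + rng.normal(0, 0.05, n),
            "f2": rng.normal(0, 1, n),
        })
        return X, y

    def test_separable_features_reach_auroc_one(self):
        X, y = self._separable()
        clf = train_classifier(X, y, seed=0)
        assert clf.auroc == 1.0

    def test_seeded_determinism(self):
        X, y = self._separable(seed=3)
        a = train_classifier(X, y, seed=1)
        b = train_classifier(X, y, seed=1)
        assert a.auroc == b.auroc
        assert (predict_scores(a, X) == predict_scores(b, X)).all()

    def test_missing_feature_is_error(self):
        X, y = self._separable(n=200)
        clf = train_classifier(X, y, seed=0)
        with pytest.raises(SenescenceError, match="missing features.*f2"):
            predict_scores(clf, X[["f1"]])

    def test_all_missing_row_still_predicts(self):
        X, y = self._separable(n=200)
        clf = train_classifier(X, y, seed=0)
        row = pd.DataFrame({"f1": [np.nan], "f2": [np.nan]})
        p = predict_scores(clf, row)
        assert 0 <= p.iloc[0] <= 1

    def test_transfer_to_unseen_cells_with_same_shift(self, immune_dataset):
        """A classifier trained on immune usage features ranks planted
        senescent cells above matched non-senescent ones elsewhere."""
        cfg, (catalog, cells, counts, truth) = immune_dataset
        s = senescence_score(counts, cells, truth.marker_genes, catalog)
        genes = list(truth.senescence_usage_genes)
        cdf = cells.df
        immune = cdf.index[(cdf["cell_type"] == "immune").to_numpy()]
        feats = usage_features(counts.subset_barcodes(immune), catalog, genes)
        ml = s.df.loc[immune, "ml_label"]
        lab = ml.isin(["0", "1"])
        clf = train_classifier(feats[lab], ml[lab].astype(int), seed=0)
        assert clf.auroc > 0.8
        pred = predict_scores(clf, usage_features(counts, catalog, genes))
        sen = cdf["senescent"].astype(bool)
        assert pred[sen.to_numpy()].median() > pred[~sen.to_numpy()].median()


def test_usage_features_are_within_gene_simplices(immune_dataset):
    cfg, (catalog, cells, counts, truth) = immune_dataset
    genes = list(truth.senescence_usage_genes)[:5]
    f = usage_features(counts, catalog, genes)
    gene_of = catalog.gene_of(f.columns)
    for g in genes:
        cols = f.columns[(gene_of == g).to_numpy()]
        sums = f[cols].sum(axis=1, skipna=False).dropna()
        assert np.allclose(sums, 1.0, atol=1e-9)
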