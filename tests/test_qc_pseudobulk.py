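import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import make_catalog, make_cells
from isousage.annotation_io import CountMatrix
from isousage.qc_pseudobulk import (
    PseudobulkMatrix,
    QCError,
    filter_barcodes,
    filter_transcripts,
    pseudobulk,
    size_factors,
    usage,
)


def one_iso_per_gene_catalog(n, mito_first=0):
    rows = []
    for j in range(n):
        name = f"mt-g{j}" if j < mito_first else f"g{j}"
        rows.append(dict(isoform_id=f"i{j}", gene_id=f"g{j}", gene_name=name))
    return make_catalog(rows)


class TestFilterBarcodes:
    def test_min_genes_and_mito_thresholds(self):
        # 3 barcodes: 99 genes; 150 genes with 25% mito; 150 clean genes
        n_genes = 200
        cat = one_iso_per_gene_catalog(n_genes, mito_first=50)
        rows = []
        X = np.zeros((3, n_genes))
        X[0, 50:149] = 1                      # 99 genes -> removed
        X[1, 12:50] = 1                       # 38 mito genes of 150 -> 25% mito
        X[1, 50:162] = 1
        X[2, 50:200] = 1                      # 150 clean genes
        counts = CountMatrix(pd.Index(["A", "B", "C"]), cat.isoform_ids, sp.csr_matrix(X))
        cells = make_cells(3, prefix="")
        cells.df.index = pd.Index(["A", "B", "C"], name="barcode")
        out_counts, out_cells = filter_barcodes(counts, cells, cat)
        assert list(out_cells.barcodes) == ["C"]
        assert out_cells.df.loc["C", "n_genes_detected"] == 150
        assert out_cells.df.loc["C", "mito_fraction"] == 0.0

    def test_top_percentile_removes_exactly_20_of_1000(self):
        """1000 barcodes with distinct detected-gene counts 100..1099: the
        98th-percentile rule (strictly greater removed) drops exactly 20."""
        n_bc, n_genes = 1000, 1100
        cat = one_iso_per_gene_catalog(n_genes)
        indptr = np.zeros(n_bc + 1, int)
        indices = []
        for i in range(n_bc):
            k = 100 + i
            indices.append(np.arange(k))
            indptr[i + 1] = indptr[i] + k
        X = sp.csr_matrix((np.ones(indptr[-1]), np.concatenate(indices), indptr),
                          shape=(n_bc, n_genes))
        cells = make_cells(n_bc)
        counts = CountMatrix(cells.barcodes, cat.isoform_ids, X)
        _, out_cells = filter_barcodes(counts, cells, cat)
        assert len(out_cells) == 980
        assert out_cells.df["n_genes_detected"].max() == 1079

    def test_all_filtered_is_an_error(self):
        cat = one_iso_per_gene_catalog(5)
        cells = make_cells(2)
        counts = CountMatrix(cells.barcodes, cat.isoform_ids,
                             sp.csr_matrix(np.ones((2, 5))))
        with pytest.raises(QCError, match="all barcodes filtered"):
            filter_barcodes(counts, cells, cat)


class TestFilterTranscripts:
    def _setup(self, hits_immune, n_immune=300):
        cat = make_catalog([
            dict(isoform_id="keep", gene_id="g1", tsl=1.0),
            dict(isoform_id="lowtsl", gene_id="g2", tsl=2.0),
            dict(isoform_id="rare", gene_id="g3", tsl=1.0),
        ])
        cells = make_cells(n_immune, cell_type="immune")
        X = np.zeros((n_immune, 3))
        X[:, 0] = 1
        X[:10, 1] = 1
        X[:hits_immune, 2] = 1
        counts = CountMatrix(cells.barcodes, cat.isoform_ids, sp.csr_matrix(X))
        return counts, cat, cells

    def test_tsl_filter_overrides_prevalence(self):
        counts, cat, cells = self._setup(hits_immune=2)
        kept = filter_transcripts(counts, cat, cells)
        assert "lowtsl" not in kept.isoforms

    def test_prevalence_below_half_percent_removed(self):
        counts, cat, cells = self._setup(hits_immune=1)  # 1/300 = 0.33%
        kept = filter_transcripts(counts, cat, cells)
        assert "rare" not in kept.isoforms
        assert "keep" in kept.isoforms

    def test_prevalence_above_half_percent_kept(self):
        counts, cat, cells = self._setup(hits_immune=2)  # 2/300 = 0.67%
        kept = filter_transcripts(counts, cat, cells)
        assert "rare" in kept.isoforms


class TestPseudobulk:
    def _toy(self):
        cat = make_catalog([dict(isoform_id="i1", gene_id="g1"),
                            dict(isoform_id="i2", gene_id="g1")])
        cells = make_cells(4)
        cells.df.loc[cells.df.index[2:], "cell_type"] = "immune"
        X = np.array([[3, 0], [4, 1], [5, 2], [7, 3]])
        counts = CountMatrix(cells.barcodes, cat.isoform_ids, sp.csr_matrix(X))
        return counts, cells, cat

    def test_unit_sums_and_conservation(self):
        counts, cells, _ = self._toy()
        pb = pseudobulk(counts, cells)
        assert pb.n_units == 2
        neuron = pb.units["cell_type"] == "neuron"
        assert pb.counts[neuron.to_numpy()][0, 0] == 7  # 3 + 4
        assert pb.counts.sum() == counts.total

    def test_zero_cell_units_omitted(self):
        counts, cells, _ = self._toy()
        pb = pseudobulk(counts, cells)
        assert set(pb.units["cell_type"]) == {"neuron", "immune"}

    def test_row_order_invariance(self):
        counts, cells, _ = self._toy()
        perm = [3, 1, 0, 2]
        counts2 = counts.subset_barcodes(counts.barcodes[perm])
        cells2 = cells.subset(cells.barcodes[perm])
        a = pseudobulk(counts, cells)
        b = pseudobulk(counts2, cells2)
        pd.testing.assert_frame_equal(a.units, b.units)
        assert (a.counts == b.counts).all()


class TestSizeFactors:
    def _pb(self, C):
        C = np.asarray(C, float)
        units = pd.DataFrame(index=[f"u{i}" for i in range(C.shape[0])])
        return PseudobulkMatrix(units, pd.Index([f"i{j}" for j in range(C.shape[1])]), C)

    def test_closed_form_example(self):
        sf = size_factors(self._pb([[2, 4], [4, 8]]))
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_identical_units_give_unit_factors(self):
        sf = size_factors(self._pb([[5, 9, 2], [5, 9, 2], [5, 9, 2]]))
        assert np.allclose(sf, 1.0, atol=1e-12)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(0)
        C = rng.integers(1, 1000, size=(6, 50)).astype(float)
        ref = np.exp(np.log(C).mean(axis=0))
        brute = np.median(C / ref, axis=1)
        assert np.abs(size_factors(self._pb(C)) - brute).max() < 1e-12

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        C = rng.integers(1, 500, size=(4, 30)).astype(float)
        sf = size_factors(self._pb(C))
        C2 = C.copy()
        C2[2] *= 3.7
        sf2 = size_factors(self._pb(C2))
        # scaling one unit's counts by c scales its factor by c relative to
        # the others (the geometric-mean reference absorbs a common c^(1/U))
        assert np.allclose(sf2[2] / sf2[0], 3.7 * sf[2] / sf[0], rtol=1e-12)
        assert np.allclose(sf2[1] / sf2[0], sf[1] / sf[0], rtol=1e-12)

    def test_no_reference_isoform_is_an_error(self):
        with pytest.raises(QCError, match="gene-level reference"):
            size_factors(self._pb([[0, 4], [4, 0]]))


class TestUsage:
    def test_ratio_missing_and_single_isoform(self):
        cat = make_catalog([dict(isoform_id="i1", gene_id="g1"),
                            dict(isoform_id="i2", gene_id="g1"),
                            dict(isoform_id="i3", gene_id="g2")])
        units = pd.DataFrame(index=["u1", "u2"])
        pb = PseudobulkMatrix(units, cat.isoform_ids,
                              np.array([[30, 10, 5], [0, 0, 0]]))
        um = usage(pb, cat)
        assert np.allclose(um.values[0, :2], [0.75, 0.25])
        assert um.values[0, 2] == 1.0          # single-isoform gene
        assert np.isnan(um.values[1]).all()    # zero totals -> missing

    def test_usage_invariant_to_unit_scaling(self):
        cat = make_catalog([dict(isoform_id="i1", gene_id="g1"),
                            dict(isoform_id="i2", gene_id="g1")])
        units = pd.DataFrame(index=["u1"])
        a = usage(PseudobulkMatrix(units, cat.isoform_ids, np.array([[30, 10]])), cat)
        b = usage(PseudobulkMatrix(units, cat.isoform_ids, np.array([[300, 100]])), cat)
        assert np.allclose(a.values, b.values)
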