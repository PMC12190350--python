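"""Barcode and transcript filtering, pseudobulk aggregation, normalization,
and isoform usage.

Filters follow the single-cell QC used for brain UMI data: barcodes need at
least 100 detected genes and at most 20% mitochondrial content, barcodes with
more detected genes than the 98th percentile of the remaining barcodes are
dropped, transcripts must carry TSL1 support and be seen in at least 0.5% of
the cells of some cell-type x sex x region stratum.  Pseudobulk units are
(sample, cell type) count sums; size factors are DESeq-style median-of-ratios;
usage is the within-gene count share.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation_io import CellTable, CountMatrix, IsoformCatalog

__all__ = [
    "QCError",
    "PseudobulkMatrix",
    "UsageMatrix",
    "filter_barcodes",
    "filter_transcripts",
    "pseudobulk",
    "size_factors",
    "usage",
]


class QCError(ValueError):
    pass


@dataclass
class PseudobulkMatrix:
    """units x isoforms count sums with per-unit metadata.

    ``units`` is a DataFrame (one row per unit) carrying at least the grouping
    keys; ``counts`` is dense (units are few).
    """

    units: pd.DataFrame
    isoforms: pd.Index
    counts: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.units), len(self.isoforms)):
            raise QCError("pseudobulk shape mismatch")
        if self.units.index.duplicated().any():
            raise QCError("duplicate pseudobulk units")
        if self.size_factors is not None and np.any(self.size_factors <= 0):
            raise QCError("size factors must be positive")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def normalized(self) -> np.ndarray:
        if self.size_factors is None:
            raise QCError("size factors not computed")
        return self.counts / self.size_factors[:, None]

    def subset_units(self, mask: np.ndarray) -> "PseudobulkMatrix":
        sf = None if self.size_factors is None else self.size_factors[mask]
        return PseudobulkMatrix(self.units[mask].copy(), self.isoforms,
                                self.counts[mask], sf)


@dataclass
class UsageMatrix:
    """Per-unit within-gene isoform usage; NaN where the gene total is zero."""

    units: pd.DataFrame
    isoforms: pd.Index
    values: np.ndarray
    gene_ids: pd.Index

    def gene_usage(self, gene_id: str) -> pd.DataFrame:
        cols = np.flatnonzero(self.gene_ids == gene_id)
        return pd.DataFrame(self.values[:, cols], index=self.units.index,
                            columns=self.isoforms[cols])


def _qc_stats(counts: CountMatrix, catalog: IsoformCatalog, mito_regex: str
              ) -> tuple[np.ndarray, np.ndarray]:
    gene_index, G = counts.gene_view(catalog)
    n_genes = np.asarray((G > 0).sum(axis=1)).ravel()
    total = np.asarray(G.sum(axis=1)).ravel()
    name_of = catalog.df.drop_duplicates("gene_id").set_index("gene_id")["gene_name"]
    pat = re.compile(mito_regex)
    mito_cols = np.array([bool(pat.match(str(name_of.get(g, g)))) for g in gene_index])
    mito = np.asarray(G[:, mito_cols].sum(axis=1)).ravel() if mito_cols.any() \
        else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return n_genes, mito_frac


def filter_barcodes(
    counts: CountMatrix,
    cells: CellTable,
    catalog: IsoformCatalog,
    mito_max: float = 0.20,
    min_genes: int = 100,
    top_pct: float = 0.98,
    mito_regex: str = "^mt-",
) -> tuple[CountMatrix, CellTable]:
    """Remove barcodes with <min_genes detected genes or >mito_max
    mitochondrial content, then those above the top_pct percentile of detected
    genes (computed on the survivors, strictly greater removed).

    Returns the filtered matrix and a cell table with ``n_genes_detected`` and
    ``mito_fraction`` filled in.
    """
    aligned = counts.subset_barcodes(cells.barcodes.intersection(counts.barcodes))
    n_genes, mito_frac = _qc_stats(aligned, catalog, mito_regex)
    keep1 = (n_genes >= min_genes) & (mito_frac <= mito_max)
    if not keep1.any():
        raise QCError("all barcodes filtered (min-genes/mito rules)")
    cutoff = np.percentile(n_genes[keep1], 100 * top_pct)
    keep = keep1 & (n_genes <= cutoff)
    if not keep.any():
        raise QCError("all barcodes filtered")
    kept_bc = aligned.barcodes[keep]
    out_cells = cells.subset(kept_bc)
    out_cells.df["n_genes_detected"] = n_genes[keep]
    out_cells.df["mito_fraction"] = mito_frac[keep]
    return aligned.subset_barcodes(kept_bc), out_cells


def filter_transcripts(
    counts: CountMatrix,
    catalog: IsoformCatalog,
    cells: CellTable,
    min_cell_frac: float = 0.005,
    tsl_required: int | None = 1,
) -> CountMatrix:
    """Keep isoforms with the required TSL that are detected in at least
    ``min_cell_frac`` of the cells of some (cell type x sex x region) stratum.
    """
    cdf = cells.df.loc[counts.barcodes]
    tsl = catalog.df.reindex(counts.isoforms)["tsl"]
    ok_tsl = np.ones(len(counts.isoforms), bool) if tsl_required is None \
        else (tsl == tsl_required).to_numpy()
    prevalent = np.zeros(len(counts.isoforms), bool)
    strata = cdf.groupby(["cell_type", "sex", "region"], observed=True).indices
    B = counts.X > 0
    for _, idx in strata.items():
        frac = np.asarray(B[idx].sum(axis=0)).ravel() / len(idx)
        prevalent |= frac >= min_cell_frac
    return counts.subset_isoforms(counts.isoforms[ok_tsl & prevalent])


def pseudobulk(
    counts: CountMatrix,
    cells: CellTable,
    keys: tuple[str, ...] = ("sample_id", "cell_type"),
) -> PseudobulkMatrix:
    """Sum UMI counts over barcodes within each unit defined by ``keys``.

    Unit metadata carries the keys plus any per-sample fields that are
    constant within the unit (age, sex, region...).  Units with zero cells do
    not appear; total count mass is conserved.
    """
    cdf = cells.df.loc[counts.barcodes]
    groups = cdf.groupby(list(keys), observed=True, sort=True).indices
    unit_rows, blocks = [], []
    carry = [c for c in ("age_months", "age_category", "sex", "region", "senescent")
             if c in cdf.columns and c not in keys]
    for key, idx in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row["n_cells"] = len(idx)
        sub = cdf.iloc[idx]
        for c in carry:
            vals = sub[c].unique()
            if len(vals) == 1:
                row[c] = vals[0]
        unit_rows.append(row)
        blocks.append(np.asarray(counts.X[idx].sum(axis=0)).ravel())
    units = pd.DataFrame(unit_rows)
    units.index = pd.Index(["|".join(map(str, k if isinstance(k, tuple) else (k,)))
                            for k in groups], name="unit")
    return PseudobulkMatrix(units, counts.isoforms, np.vstack(blocks).astype(np.int64))


def size_factors(pb: PseudobulkMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    The reference is the per-isoform geometric mean over units, restricted to
    isoforms with all-positive counts; each unit's factor is the median ratio
    of its counts to the reference.
    """
    C = pb.counts.astype(float)
    allpos = (C > 0).all(axis=0)
    if not allpos.any():
        raise QCError(
            "no isoform with positive counts in every unit; "
            "compute size factors on a gene-level reference instead"
        )
    ref = np.exp(np.log(C[:, allpos]).mean(axis=0))
    return np.median(C[:, allpos] / ref, axis=1)


def usage(pb: PseudobulkMatrix, catalog: IsoformCatalog) -> UsageMatrix:
    """Within-gene isoform usage per unit: count / gene total, NaN where the
    gene total is zero.  Raw counts are used (usage is scale-free)."""
    gene_ids = pd.Index(catalog.gene_of(pb.isoforms))
    codes, uniques = pd.factorize(gene_ids)
    totals = np.zeros((pb.n_units, len(uniques)))
    np.add.at(totals.T, codes, pb.counts.T.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = pb.counts / totals[:, codes]
    vals[totals[:, codes] == 0] = np.nan
    return UsageMatrix(pb.units, pb.isoforms, vals, gene_ids)
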