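"""Annotation and matrix input parsing.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  GTF input (1-based, inclusive)
is converted on read.  The transcription start site (TSS) is the 5'-most
transcribed position in transcript orientation: the minimum exon start on the
``+`` strand, the maximum exon end minus one on the ``-`` strand.  The poly(A)
site (PAS) is the 3'-most position, defined analogously.  "Upstream" always
means upstream in the direction of transcription.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "AnnotationError",
    "ValidationError",
    "TranscriptModel",
    "IsoformCatalog",
    "CellTable",
    "CountMatrix",
    "catalog_from_models",
    "parse_gtf",
    "write_gtf",
    "read_counts",
    "write_counts",
    "read_cell_metadata",
    "write_cell_metadata",
]

CELL_TYPES = ("neuron", "oligo", "astrocyte", "vascular", "immune", "other")
AGE_CATEGORIES = ("young", "middle", "old", "geriatric")
SEXES = ("M", "F")
REGIONS = ("cortex", "hippocampus")

CATALOG_COLUMNS = [
    "gene_id", "gene_name", "chrom", "strand", "tss", "pas", "length",
    "exon_count", "coding", "tsl", "cds_length", "utr5_length", "utr3_length",
]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class ValidationError(ValueError):
    """Tabular input violating the declared schema."""


@dataclass
class TranscriptModel:
    """Exon-level model of one transcript (0-based half-open coordinates)."""

    isoform_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]          # sorted by genomic start
    cds: list[tuple[int, int]] | None = None
    biotype: str = "protein_coding"
    tsl: int | None = 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class IsoformCatalog:
    """Per-isoform structural attributes, indexed by isoform id.

    ``df`` columns: gene_id, gene_name, chrom, strand, tss, pas, length,
    exon_count, coding, tsl, cds_length, utr5_length, utr3_length.
    Missing TSL and CDS/UTR lengths are NaN.
    """

    df: pd.DataFrame
    models: dict[str, TranscriptModel] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.df.columns]
        if missing:
            raise AnnotationError(f"catalog missing columns: {missing}")
        if (self.df["length"] <= 0).any():
            raise AnnotationError("catalog contains non-positive lengths")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def isoform_ids(self) -> pd.Index:
        return self.df.index

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.df["gene_id"].unique())

    def gene_of(self, isoforms: Sequence[str] | pd.Index) -> pd.Series:
        return self.df.loc[isoforms, "gene_id"]

    def isoforms_of(self, gene_id: str) -> pd.Index:
        return self.df.index[self.df["gene_id"] == gene_id]

    def subset(self, isoform_ids: Sequence[str] | pd.Index) -> "IsoformCatalog":
        models = None
        if self.models is not None:
            models = {i: self.models[i] for i in isoform_ids if i in self.models}
        return IsoformCatalog(self.df.loc[list(isoform_ids)].copy(), models)


@dataclass
class CellTable:
    """Per-barcode metadata; QC statistics filled in by qc_pseudobulk."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "cell_type", "age_months", "age_category", "sex", "region")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValidationError(f"cell table missing required column {col!r}")
        if not self.df.index.is_unique:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValidationError(f"duplicate barcode {dup!r}")
        self._validate_categories()

    def _validate_categories(self) -> None:
        checks = {
            "cell_type": CELL_TYPES,
            "age_category": AGE_CATEGORIES,
            "sex": SEXES,
            "region": REGIONS,
        }
        for col, allowed in checks.items():
            bad = ~self.df[col].isin(allowed)
            if bad.any():
                row = self.df.index[bad][0]
                raise ValidationError(
                    f"invalid {col} value {self.df.loc[row, col]!r} for barcode {row!r}"
                )
        if "mito_fraction" in self.df.columns:
            mf = self.df["mito_fraction"].dropna()
            if ((mf < 0) | (mf > 1)).any():
                raise ValidationError("mito_fraction outside [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def barcodes(self) -> pd.Index:
        return self.df.index

    def subset(self, barcodes: Sequence[str] | pd.Index) -> "CellTable":
        return CellTable(self.df.loc[list(barcodes)].copy())


@dataclass
class CountMatrix:
    """Sparse barcode x isoform UMI count matrix."""

    barcodes: pd.Index
    isoforms: pd.Index
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes)
        self.isoforms = pd.Index(self.isoforms)
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.barcodes), len(self.isoforms)):
            raise ValidationError(
                f"matrix shape {self.X.shape} does not match axes "
                f"({len(self.barcodes)}, {len(self.isoforms)})"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise ValidationError("negative counts")

    @property
    def total(self) -> int:
        return int(self.X.sum())

    def gene_view(self, catalog: IsoformCatalog) -> tuple[pd.Index, sp.csr_matrix]:
        """Barcode x gene sums (isoforms collapsed onto their genes)."""
        genes = catalog.gene_of(self.isoforms)
        gene_index = pd.Index(pd.unique(genes))
        col = gene_index.get_indexer(genes)
        A = sp.csr_matrix(
            (np.ones(len(genes)), (np.arange(len(genes)), col)),
            shape=(len(genes), len(gene_index)),
        )
        return gene_index, sp.csr_matrix(self.X @ A)

    def subset_barcodes(self, barcodes: Sequence[str] | pd.Index) -> "CountMatrix":
        idx = self.barcodes.get_indexer(barcodes)
        if (idx < 0).any():
            raise ValidationError("unknown barcode in subset")
        return CountMatrix(pd.Index(barcodes), self.isoforms, self.X[idx])

    def subset_isoforms(self, isoforms: Sequence[str] | pd.Index) -> "CountMatrix":
        idx = self.isoforms.get_indexer(isoforms)
        if (idx < 0).any():
            raise ValidationError("unknown isoform in subset")
        return CountMatrix(self.barcodes, pd.Index(isoforms), self.X[:, idx])


# ---------------------------------------------------------------------------
# attribute derivation shared by the generator and the GTF reader
# ---------------------------------------------------------------------------

def _model_attributes(m: TranscriptModel) -> dict:
    exons = sorted(m.exons)
    length = int(sum(e - s for s, e in exons))
    if length <= 0:
        raise AnnotationError(f"transcript {m.isoform_id} has zero exonic length")
    if m.strand == "+":
        tss, pas = exons[0][0], exons[-1][1] - 1
    else:
        tss, pas = exons[-1][1] - 1, exons[0][0]
    cds_length = utr5 = utr3 = np.nan
    if m.cds:
        cds_length = int(sum(e - s for s, e in m.cds))
        cds_sorted = sorted(m.cds)
        # exonic nucleotides strictly 5' of the CDS in transcript orientation
        if m.strand == "+":
            cds_5p = cds_sorted[0][0]
            utr5 = sum(min(e, cds_5p) - s for s, e in exons if s < cds_5p)
        else:
            cds_5p = cds_sorted[-1][1]
            utr5 = sum(e - max(s, cds_5p) for s, e in exons if e > cds_5p)
        utr3 = length - cds_length - utr5
    return {
        "gene_id": m.gene_id,
        "gene_name": m.gene_name,
        "chrom": m.chrom,
        "strand": m.strand,
        "tss": tss,
        "pas": pas,
        "length": length,
        "exon_count": len(exons),
        "coding": m.biotype == "protein_coding",
        "tsl": np.nan if m.tsl is None else float(m.tsl),
        "cds_length": cds_length,
        "utr5_length": utr5,
        "utr3_length": utr3,
    }


def catalog_from_models(models: Mapping[str, TranscriptModel]) -> IsoformCatalog:
    rows = {iso: _model_attributes(m) for iso, m in models.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "isoform_id"
    return IsoformCatalog(df[CATALOG_COLUMNS], dict(models))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def parse_gtf(path: str | os.PathLike) -> IsoformCatalog:
    """Parse an Ensembl-dialect GTF into an :class:`IsoformCatalog`.

    Transcripts are coding iff ``transcript_biotype == "protein_coding"``;
    ``transcript_support_level`` is parsed when present and numeric.
    Transcripts without exon records are collected and reported together.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:",
            disable_infer_genes=True, disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    models: dict[str, TranscriptModel] = {}
    broken: list[str] = []
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        exons = [(e.start - 1, e.end) for e in db.children(t, featuretype="exon")]
        if not exons:
            broken.append(tid)
            continue
        cds = [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
        tsl = None
        raw_tsl = t.attributes.get("transcript_support_level", [None])[0]
        if raw_tsl:
            tok = raw_tsl.split()[0]
            if tok.isdigit():
                tsl = int(tok)
        models[tid] = TranscriptModel(
            isoform_id=tid,
            gene_id=t.attributes["gene_id"][0],
            gene_name=t.attributes.get("gene_name", t.attributes["gene_id"])[0],
            chrom=t.seqid,
            strand=t.strand,
            exons=sorted(exons),
            cds=sorted(cds) or None,
            biotype=t.attributes.get("transcript_biotype", ["protein_coding"])[0],
            tsl=tsl,
        )
    if broken:
        raise AnnotationError(
            f"{len(broken)} transcript(s) without exon records: {broken[:10]}"
        )
    if not models:
        raise AnnotationError(f"no transcripts found in {path}")
    return catalog_from_models(models)


def _gtf_attrs(pairs: Iterable[tuple[str, object]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs if v is not None)


def write_gtf(models: Mapping[str, TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcript models as Ensembl-dialect GTF (1-based inclusive)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models.values():
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for gid in sorted(by_gene):
            ms = sorted(by_gene[gid], key=lambda m: m.isoform_id)
            g0 = min(m.start for m in ms)
            g1 = max(m.end for m in ms)
            chrom, strand, gname = ms[0].chrom, ms[0].strand, ms[0].gene_name
            fh.write(
                f"{chrom}\tisousage\tgene\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t"
                + _gtf_attrs([("gene_id", gid), ("gene_name", gname)]) + "\n"
            )
            for m in ms:
                base = [
                    ("gene_id", gid), ("transcript_id", m.isoform_id),
                    ("gene_name", gname), ("transcript_biotype", m.biotype),
                    ("transcript_support_level", m.tsl),
                ]
                fh.write(
                    f"{chrom}\tisousage\ttranscript\t{m.start + 1}\t{m.end}\t.\t"
                    f"{strand}\t.\t" + _gtf_attrs(base) + "\n"
                )
                for s, e in m.exons:
                    fh.write(
                        f"{chrom}\tisousage\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        + _gtf_attrs(base) + "\n"
                    )
                for s, e in m.cds or []:
                    fh.write(
                        f"{chrom}\tisousage\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                        + _gtf_attrs(base) + "\n"
                    )


# ---------------------------------------------------------------------------
# Matrix Market + axis files
# ---------------------------------------------------------------------------

def read_counts(
    mtx_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
) -> CountMatrix:
    """Read a barcode x isoform sparse matrix.

    Axes follow file order; duplicate triplets are summed.  The features file
    is headerless TSV with columns isoform_id, gene_id, gene_name.
    """
    M = scipy.io.mmread(str(mtx_path))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(features_path, sep="\t", header=None)
    if M.shape != (len(barcodes), len(features)):
        raise ValidationError(
            f"matrix header {M.shape} does not match axis files "
            f"({len(barcodes)}, {len(features)})"
        )
    X = sp.csr_matrix(M)  # conversion sums duplicate triplets
    X.sum_duplicates()
    return CountMatrix(pd.Index(barcodes), pd.Index(features[0].astype(str)), X)


def write_counts(
    counts: CountMatrix,
    catalog: IsoformCatalog,
    mtx_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(counts.X), field="integer")
    pd.Series(counts.barcodes).to_csv(barcodes_path, sep="\t", header=False, index=False)
    feat = catalog.df.loc[counts.isoforms, ["gene_id", "gene_name"]].reset_index()
    feat.to_csv(features_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# cell metadata TSV
# ---------------------------------------------------------------------------

def read_cell_metadata(path: str | os.PathLike) -> CellTable:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    if "barcode" not in df.columns:
        raise ValidationError("cell metadata must have a 'barcode' column")
    df = df.set_index("barcode")
    return CellTable(df)


def write_cell_metadata(cells: CellTable, path: str | os.PathLike) -> None:
    cells.df.to_csv(path, sep="\t", index=True, index_label="barcode")
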