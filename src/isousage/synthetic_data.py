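"""Synthetic single-cell isoform data with planted, recorded ground truth.

The generator emulates the structure of a multi-age, two-sex, two-region
single-cell isoform UMI experiment: an isoform catalog with realistic
structural attributes (TSS spread over <=2 kb, PAS over <=5 kb, exon models,
coding flags, TSL), a cell table over a sample design of age timepoints, and a
Dirichlet-multinomial count matrix with planted cell-type-specific usage
(CIG), age-dependent usage (AIG), temporal expression trajectories, a
senescent immune subpopulation with elevated marker expression, and
senescence-coupled usage switches.

Per-cell gene totals are Poisson with a log-normal per-cell depth factor;
isoform splits within a gene are Dirichlet-multinomial with concentration
``precision_gamma``.  One global seed feeds a counter-based child seed per
operation so results do not depend on call order.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation_io import (
    CellTable,
    CountMatrix,
    IsoformCatalog,
    TranscriptModel,
    catalog_from_models,
    write_cell_metadata,
    write_counts,
    write_gtf,
)

__all__ = [
    "ConfigurationError",
    "SampleSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_catalog",
    "generate_cells",
    "simulate_counts",
    "simulate_dataset",
    "write_fixture",
    "load_fixture",
    "default_design",
    "age_category_of",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def age_category_of(age_months: float) -> str:
    """Age-category bins: young 4, middle 16, old 22-23, geriatric 27-31 months."""
    if age_months < 10:
        return "young"
    if age_months < 19:
        return "middle"
    if age_months < 25:
        return "old"
    return "geriatric"


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    age_months: float
    sex: str
    region: str

    @property
    def age_category(self) -> str:
        return age_category_of(self.age_months)


def default_design() -> list[SampleSpec]:
    """Four timepoints x both sexes, cortex: young 4, middle 16, old 22.5,
    geriatric 31 (males) / 27 (females) months."""
    design = []
    for age_m, age_f, tag in [(4, 4, "young"), (16, 16, "middle"),
                              (22.5, 22.5, "old"), (31, 27, "geriatric")]:
        design.append(SampleSpec(f"{tag}_M", age_m, "M", "cortex"))
        design.append(SampleSpec(f"{tag}_F", age_f, "F", "cortex"))
    return design


# Eight distinct temporal shapes: value = 1 + b1*s + b2*s^2 on s = (age-4)/27,
# so every curve equals 1 at young age.  Chosen to span up/down, accelerating,
# decelerating and non-monotone trends.
DEFAULT_TRAJECTORY_SHAPES: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),      # flat
    (1.0, 1.5, 0.0),      # linear up
    (1.0, -0.8, 0.0),     # linear down
    (1.0, 3.0, -3.0),     # up then down
    (1.0, -1.6, 1.6),     # down then up
    (1.0, 0.0, 2.5),      # late up
    (1.0, 0.2, -1.0),     # late down
    (1.0, 2.8, 0.0),      # strong linear up
)

DEFAULT_PROPORTIONS: dict[str, float] = {
    "neuron": 0.35, "oligo": 0.25, "astrocyte": 0.20,
    "vascular": 0.10, "immune": 0.10,
}


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the desk-scale study conditions."""

    n_genes: int = 500
    isoforms_min: int = 1
    isoforms_max: int = 4
    n_cells_per_sample: int = 250
    design: list[SampleSpec] = field(default_factory=default_design)
    cell_type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    cig_fraction: float = 0.10
    aig_fraction: float = 0.10
    usage_effect_size: float = 0.30
    trajectory_cluster_shapes: tuple[tuple[float, float, float], ...] = (
        DEFAULT_TRAJECTORY_SHAPES)
    senescent_fraction: float = 0.05
    marker_fold: float = 10.0
    precision_gamma: float = 30.0
    depth_mean: float = 2000.0
    depth_sigma: float = 0.35
    n_marker_genes: int = 20
    n_senescence_usage_genes: int = 20
    n_mito_genes: int = 5
    coding_prob: float = 0.7
    tsl1_prob: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not (1 <= self.isoforms_min <= self.isoforms_max):
            raise ConfigurationError("need 1 <= isoforms_min <= isoforms_max")
        props = np.array(list(self.cell_type_proportions.values()), float)
        if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ConfigurationError("cell_type_proportions must be a simplex")
        for name in ("cig_fraction", "aig_fraction", "senescent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.usage_effect_size < 1.0:
            raise ConfigurationError("usage_effect_size must be in [0, 1)")
        if self.precision_gamma <= 0 or self.depth_mean <= 0:
            raise ConfigurationError("precision_gamma and depth_mean must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Counter-based child generator: stream index decouples operations."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """Every planted effect, recorded for downstream recovery checks."""

    cig_genes: dict[str, str] = field(default_factory=dict)          # gene -> cell type
    cig_targets: dict[str, str] = field(default_factory=dict)        # gene -> isoform
    aig_genes: dict[str, str] = field(default_factory=dict)          # gene -> onset age category
    aig_targets: dict[str, str] = field(default_factory=dict)
    senescence_usage_genes: dict[str, str] = field(default_factory=dict)  # gene -> isoform
    trajectory_assignments: dict[str, int] = field(default_factory=dict)  # isoform -> shape id
    marker_genes: list[str] = field(default_factory=list)
    senescent_barcodes: set[str] = field(default_factory=set)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["senescent_barcodes"] = sorted(self.senescent_barcodes)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["senescent_barcodes"] = set(d["senescent_barcodes"])
        d["trajectory_assignments"] = {k: int(v) for k, v in d["trajectory_assignments"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def _split_exons(rng: np.random.Generator, start: int, end: int, k: int
                 ) -> list[tuple[int, int]]:
    """Split [start, end) into k exons separated by k-1 introns (>=30 nt each)."""
    span = end - start
    min_piece = 30
    if k <= 1 or span < (2 * k - 1) * min_piece:
        return [(start, end)]
    n_pieces = 2 * k - 1
    w = rng.dirichlet(np.ones(n_pieces))
    lengths = min_piece + np.floor(w * (span - n_pieces * min_piece)).astype(int)
    lengths[-1] += span - lengths.sum()
    exons, pos = [], start
    for i, ln in enumerate(lengths):
        if i % 2 == 0:
            exons.append((pos, pos + int(ln)))
        pos += int(ln)
    return exons


def _cds_intervals(exons: list[tuple[int, int]], strand: str,
                   utr5: int, cds_len: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate CDS (after utr5, length cds_len) to genomic
    intervals by walking exons in transcript orientation."""
    ordered = sorted(exons, reverse=(strand == "-"))
    out: list[tuple[int, int]] = []
    skip, take = utr5, cds_len
    for s, e in ordered:
        ln = e - s
        if skip >= ln:
            skip -= ln
            continue
        avail = ln - skip
        use = min(avail, take)
        if strand == "+":
            out.append((s + skip, s + skip + use))
        else:
            out.append((e - skip - use, e - skip))
        take -= use
        skip = 0
        if take == 0:
            break
    return sorted(out)


def generate_catalog(config: SimulationConfig) -> IsoformCatalog:
    """Generate an isoform catalog with per-gene TSS/PAS spreads and exon models.

    Isoforms of one gene share chromosome and strand; TSSs of a gene are spread
    over <=2 kb and PASs over <=5 kb; mitochondrial genes carry the ``mt-``
    name prefix on chromosome chrM.
    """
    rng = config.rng(1)
    models: dict[str, TranscriptModel] = {}
    n_iso = rng.integers(config.isoforms_min, config.isoforms_max + 1,
                         size=config.n_genes)
    for g in range(config.n_genes):
        gid = f"G{g + 1:05d}"
        mito = g < config.n_mito_genes
        gname = f"mt-{gid}" if mito else f"Gene{g + 1:05d}"
        chrom = "chrM" if mito else f"chr{1 + g % 19}"
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = int(rng.integers(10_000, 2_000_000))
        J = int(n_iso[g])
        # 5' window (2 kb) and 3' window (5 kb) in transcription direction
        tss_off = rng.choice(2000, size=J, replace=False)
        pas_off = rng.choice(5000, size=J, replace=False)
        for j in range(J):
            iid = f"{gid}.{j + 1:02d}"
            if strand == "+":
                five = gstart + int(tss_off[j])
                three = gstart + 4000 + int(pas_off[j])
                span = (five, three + 1)
            else:
                five = gstart + 7001 + int(tss_off[j])
                three = gstart + int(pas_off[j])
                span = (three, five + 1)
            k = int(rng.integers(1, 7))
            exons = _split_exons(rng, span[0], span[1], k)
            coding = bool(mito or rng.random() < config.coding_prob)
            length = sum(e - s for s, e in exons)
            cds = None
            if coding and length >= 200:
                utr5 = int(rng.integers(20, max(21, length // 5)))
                utr3 = int(rng.integers(20, max(21, length // 4)))
                cds_len = length - utr5 - utr3
                cds = _cds_intervals(exons, strand, utr5, cds_len)
            if mito:
                tsl: int | None = 1
            else:
                u = rng.random()
                if u < config.tsl1_prob:
                    tsl = 1
                elif u < config.tsl1_prob + 0.12:
                    tsl = int(rng.integers(2, 6))
                else:
                    tsl = None
            models[iid] = TranscriptModel(
                isoform_id=iid, gene_id=gid, gene_name=gname, chrom=chrom,
                strand=strand, exons=exons, cds=cds,
                biotype="protein_coding" if coding else "processed_transcript",
                tsl=tsl,
            )
    return catalog_from_models(models)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_cells(config: SimulationConfig) -> CellTable:
    """Draw barcodes, cell types, and the senescent flag for each sample."""
    if not config.design:
        raise ConfigurationError("design must contain at least one sample")
    rng = config.rng(2)
    types = list(config.cell_type_proportions)
    probs = np.array(list(config.cell_type_proportions.values()), float)
    rows = []
    seen: set[str] = set()
    for s_idx, sample in enumerate(config.design, start=1):
        ct = rng.choice(types, size=config.n_cells_per_sample, p=probs)
        aged = sample.age_category != "young"
        for i in range(config.n_cells_per_sample):
            while True:
                bc = "".join(rng.choice(_BASES, size=16)) + f"-{s_idx}"
                if bc not in seen:
                    seen.add(bc)
                    break
            senescent = bool(
                aged and ct[i] == "immune" and rng.random() < config.senescent_fraction
            )
            rows.append((bc, sample.sample_id, ct[i], sample.age_months,
                         sample.age_category, sample.sex, sample.region, senescent))
    df = pd.DataFrame(
        rows,
        columns=["barcode", "sample_id", "cell_type", "age_months",
                 "age_category", "sex", "region", "senescent"],
    ).set_index("barcode")
    return CellTable(df)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _multinomial_rows(rng: np.random.Generator, n: np.ndarray, p: np.ndarray
                      ) -> np.ndarray:
    """Vectorized multinomial with per-row totals ``n`` and probabilities ``p``
    (rows of p sum to 1), via a binomial cascade over categories."""
    n = n.astype(np.int64)
    C, J = p.shape
    out = np.zeros((C, J), dtype=np.int64)
    remaining = n.copy()
    ptail = np.clip(p[:, ::-1].cumsum(axis=1)[:, ::-1], 1e-300, None)
    for j in range(J - 1):
        cond = np.clip(p[:, j] / ptail[:, j], 0.0, 1.0)
        draw = rng.binomial(remaining, cond)
        out[:, j] = draw
        remaining -= draw
    out[:, -1] = remaining
    return out


def _shifted(pi: np.ndarray, target: int, delta: float) -> np.ndarray:
    """Shift usage toward ``target`` by ``delta``, scaling the rest."""
    out = pi.copy()
    rest = 1.0 - pi[target]
    if rest <= delta:  # invariant guarded at plant time
        raise ConfigurationError("usage_effect_size >= baseline usage complement")
    out[target] = pi[target] + delta
    scale = (rest - delta) / rest
    for j in range(len(pi)):
        if j != target:
            out[j] = pi[j] * scale
    return out


_AGE_ORDER = {"young": 0, "middle": 1, "old": 2, "geriatric": 3}


def simulate_counts(
    catalog: IsoformCatalog,
    cells: CellTable,
    config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Draw the barcode x isoform UMI matrix and record all planted effects.

    Per cell and gene the total is Poisson with rate
    ``depth_factor * baseline_share * trajectory(age)`` (marker genes in
    senescent cells multiplied by ``marker_fold``); the split across the
    gene's isoforms is Dirichlet-multinomial with concentration
    ``precision_gamma`` around the cell's condition-specific usage vector.
    """
    rng = config.rng(3)
    df = catalog.df
    genes = list(dict.fromkeys(df["gene_id"]))
    iso_by_gene = {g: list(df.index[df["gene_id"] == g]) for g in genes}
    n_cells = len(cells)
    cdf = cells.df

    truth = GroundTruth()

    # --- gene baseline expression shares (log-normal), markers boosted ------
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    non_mito = [g for g in genes if not df.loc[iso_by_gene[g][0], "gene_name"].startswith("mt-")]
    markers = [str(g) for g in rng.choice(
        non_mito, size=min(config.n_marker_genes, len(non_mito)), replace=False)]
    truth.marker_genes = sorted(markers)
    med = float(np.median(base))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in markers:
        base[gene_pos[g]] = max(base[gene_pos[g]], med)
    share = base / base.sum()

    # --- plant usage effects ------------------------------------------------
    multi = [g for g in genes if len(iso_by_gene[g]) >= 2]
    rng.shuffle(multi)
    n_cig = int(round(config.cig_fraction * config.n_genes))
    n_aig = int(round(config.aig_fraction * config.n_genes))
    n_sen = config.n_senescence_usage_genes
    cig_set = multi[:n_cig]
    aig_set = multi[n_cig:n_cig + n_aig]
    sen_set = multi[n_cig + n_aig:n_cig + n_aig + n_sen]
    cell_types = list(config.cell_type_proportions)

    pis: dict[str, np.ndarray] = {}
    for g in genes:
        J = len(iso_by_gene[g])
        pi = rng.dirichlet(np.full(J, 2.0))
        planted = g in cig_set or g in aig_set or g in sen_set
        if planted:
            # pin the target isoform so the shift fits inside the simplex
            target = int(rng.integers(J))
            pi_t = min(0.3, (1.0 - config.usage_effect_size) / 2)
            pi = pi * (1.0 - pi_t) / (pi.sum() - pi[target])
            pi[target] = pi_t
            tgt_iso = iso_by_gene[g][target]
            if g in cig_set:
                truth.cig_genes[g] = cell_types[len(truth.cig_genes) % len(cell_types)]
                truth.cig_targets[g] = tgt_iso
            elif g in aig_set:
                onset = ("middle", "old", "geriatric")[len(truth.aig_genes) % 3]
                truth.aig_genes[g] = onset
                truth.aig_targets[g] = tgt_iso
            else:
                truth.senescence_usage_genes[g] = tgt_iso
        pis[g] = pi

    # --- trajectories: each gene gets one shape; isoforms inherit it --------
    shapes = np.array(config.trajectory_cluster_shapes, float)
    shape_id = rng.integers(len(shapes), size=len(genes))
    for g, sid in zip(genes, shape_id):
        for iso in iso_by_gene[g]:
            truth.trajectory_assignments[iso] = int(sid)
    s = (cdf["age_months"].to_numpy(float) - 4.0) / 27.0
    traj_mult = np.clip(
        shapes[shape_id][:, 0][None, :]
        + np.outer(s, shapes[shape_id][:, 1])
        + np.outer(s ** 2, shapes[shape_id][:, 2]),
        0.05, None,
    )  # cells x genes

    # --- per-cell depth and group indices -----------------------------------
    depth = config.depth_mean * rng.lognormal(
        -config.depth_sigma ** 2 / 2, config.depth_sigma, size=n_cells)
    ct_arr = cdf["cell_type"].to_numpy()
    age_rank = cdf["age_category"].map(_AGE_ORDER).to_numpy()
    sen_arr = cdf["senescent"].to_numpy(bool) if "senescent" in cdf else np.zeros(n_cells, bool)
    truth.senescent_barcodes = set(cdf.index[sen_arr])

    iso_index = pd.Index(df.index)
    iso_pos = {iso: k for k, iso in enumerate(iso_index)}
    rows_all, cols_all, vals_all = [], [], []

    for gi, g in enumerate(genes):
        isos = iso_by_gene[g]
        J = len(isos)
        lam = depth * share[gi] * traj_mult[:, gi]
        if g in markers:
            lam = np.where(sen_arr, lam * config.marker_fold, lam)
        totals = rng.poisson(lam)
        nz = np.flatnonzero(totals)
        if nz.size == 0:
            continue
        if J == 1:
            rows_all.append(nz)
            cols_all.append(np.full(nz.size, iso_pos[isos[0]]))
            vals_all.append(totals[nz])
            continue
        # condition-specific usage per cell
        pi_cell = np.tile(pis[g], (nz.size, 1))
        if g in truth.cig_genes:
            t = isos.index(truth.cig_targets[g])
            mask = ct_arr[nz] == truth.cig_genes[g]
            if mask.any():
                pi_cell[mask] = _shifted(pis[g], t, config.usage_effect_size)
        elif g in truth.aig_genes:
            t = isos.index(truth.aig_targets[g])
            mask = age_rank[nz] >= _AGE_ORDER[truth.aig_genes[g]]
            if mask.any():
                pi_cell[mask] = _shifted(pis[g], t, config.usage_effect_size)
        elif g in truth.senescence_usage_genes:
            t = isos.index(truth.senescence_usage_genes[g])
            mask = sen_arr[nz]
            if mask.any():
                pi_cell[mask] = _shifted(pis[g], t, config.usage_effect_size)
        # Dirichlet draw then multinomial split
        gam = rng.standard_gamma(config.precision_gamma * pi_cell)
        gam_sum = gam.sum(axis=1, keepdims=True)
        zero = gam_sum[:, 0] <= 0
        if zero.any():
            gam[zero] = pi_cell[zero]
            gam_sum = gam.sum(axis=1, keepdims=True)
        p = gam / gam_sum
        counts = _multinomial_rows(rng, totals[nz], p)
        r, c = np.nonzero(counts)
        rows_all.append(nz[r])
        cols_all.append(np.array([iso_pos[isos[j]] for j in c]))
        vals_all.append(counts[r, c])

    if rows_all:
        X = sp.coo_matrix(
            (np.concatenate(vals_all),
             (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(n_cells, len(iso_index)),
        ).tocsr()
    else:
        X = sp.csr_matrix((n_cells, len(iso_index)), dtype=np.int64)
    return CountMatrix(cdf.index, iso_index, X), truth


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[IsoformCatalog, CellTable, CountMatrix, GroundTruth]:
    """Catalog, cells and counts from one config (convenience wrapper)."""
    catalog = generate_catalog(config)
    cells = generate_cells(config)
    counts, truth = simulate_counts(catalog, cells, config)
    return catalog, cells, counts, truth


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(
    catalog: IsoformCatalog,
    cells: CellTable,
    counts: CountMatrix,
    truth: GroundTruth,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write matrix.mtx + barcodes/features TSVs, GTF, cell metadata, marker
    list and ground_truth.json; round-trips losslessly through annotation_io."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "gtf": out / "annotation.gtf",
        "cells": out / "cells.tsv",
        "markers": out / "markers.txt",
        "truth": out / "ground_truth.json",
    }
    write_counts(counts, catalog, paths["mtx"], paths["barcodes"], paths["features"])
    if catalog.models is None:
        raise ConfigurationError("catalog has no transcript models to write as GTF")
    write_gtf(catalog.models, paths["gtf"])
    write_cell_metadata(cells, paths["cells"])
    with open(paths["markers"], "w") as fh:
        for g in truth.marker_genes:
            fh.write(g + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def load_fixture(out_dir: str | os.PathLike
                 ) -> tuple[IsoformCatalog, CellTable, CountMatrix, GroundTruth, list[str]]:
    from .annotation_io import parse_gtf, read_cell_metadata, read_counts

    out = Path(out_dir)
    catalog = parse_gtf(out / "annotation.gtf")
    cells = read_cell_metadata(out / "cells.tsv")
    counts = read_counts(out / "matrix.mtx", out / "barcodes.tsv", out / "features.tsv")
    with open(out / "ground_truth.json") as fh:
        truth = GroundTruth.from_json(json.load(fh))
    markers = [l.strip() for l in open(out / "markers.txt") if l.strip()]
    return catalog, cells, counts, truth, markers
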