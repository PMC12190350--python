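"""Usage-weighted isoform attribute analysis.

For a gene g with isoform usages u_i and attribute values a_i, the weighted
attribute metric is A_g = sum_i u_i * a_i.  TSS and PAS coordinates are first
normalized per gene: the most upstream site (in transcription direction) is
set to 0 and the others binned by distance (20 nt bins for TSS, 75 nt for
PAS).  Coding potential is encoded +1 (protein-coding) / -1 (non-coding).

Sign conventions for condition deltas: positive means longer isoform / CDS /
5' UTR / 3' UTR, upstream TSS (the raw TSS-bin difference is negated),
downstream PAS, and higher coding potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotation_io import IsoformCatalog
from .qc_pseudobulk import PseudobulkMatrix

__all__ = [
    "ATTRIBUTES",
    "PAIR_ATTRIBUTES",
    "bin_positions",
    "isoform_attribute_table",
    "weighted_attribute",
    "weighted_attributes_by_group",
    "attribute_delta",
    "classify_pair_change",
    "delta_correlations",
]

ATTRIBUTES = ("length", "tss_bin", "pas_bin", "coding_score",
              "exon_count", "cds_length", "utr5_length", "utr3_length")
# attributes compared between the top increasing/decreasing isoform pair
PAIR_ATTRIBUTES = ("TSS", "PAS", "exon count", "length", "coding potential")
# attributes whose condition delta is negated so positive = upstream shift
NEGATED = ("tss_bin",)
# attributes defined only over protein-coding isoforms (usages renormalized)
CODING_ONLY = ("cds_length", "utr5_length", "utr3_length")

TSS_BIN_SIZE = 20
PAS_BIN_SIZE = 75


def bin_positions(sites: np.ndarray, strand: str, bin_size: int) -> np.ndarray:
    """Bin genomic positions by distance from the most upstream site.

    Upstream is in transcription direction: minimum position on '+', maximum
    on '-'.  The most upstream site gets bin 0; bin = floor(distance / size).
    """
    sites = np.asarray(sites)
    if sites.size == 0:
        return sites.astype(int)
    if strand == "+":
        dist = sites - sites.min()
    else:
        dist = sites.max() - sites
    return (dist // bin_size).astype(int)


def isoform_attribute_table(
    catalog: IsoformCatalog,
    tss_bin_size: int = TSS_BIN_SIZE,
    pas_bin_size: int = PAS_BIN_SIZE,
) -> pd.DataFrame:
    """Per-isoform attribute vector: length, tss_bin, pas_bin, coding_score
    (+1/-1), exon_count, and CDS/UTR lengths (NaN for non-coding)."""
    df = catalog.df
    out = pd.DataFrame(index=df.index)
    out["gene_id"] = df["gene_id"]
    out["length"] = df["length"].astype(float)
    out["exon_count"] = df["exon_count"].astype(float)
    out["coding_score"] = np.where(df["coding"], 1.0, -1.0)
    out["cds_length"] = df["cds_length"]
    out["utr5_length"] = df["utr5_length"]
    out["utr3_length"] = df["utr3_length"]
    out["tss_bin"] = 0.0
    out["pas_bin"] = 0.0
    for _, sub in df.groupby("gene_id", sort=False):
        strand = sub["strand"].iloc[0]
        out.loc[sub.index, "tss_bin"] = bin_positions(
            sub["tss"].to_numpy(), strand, tss_bin_size).astype(float)
        out.loc[sub.index, "pas_bin"] = bin_positions(
            sub["pas"].to_numpy(), strand, pas_bin_size).astype(float)
    return out


def weighted_attribute(usages: np.ndarray, values: np.ndarray) -> float:
    """A_g = sum_i u_i * a_i for one gene in one condition.

    Usages must sum to 1 (tolerance 1e-6) and the attribute must be defined
    wherever usage is positive; otherwise the metric is undefined (NaN).
    """
    u = np.asarray(usages, float)
    a = np.asarray(values, float)
    if abs(u.sum() - 1.0) > 1e-6:
        raise ValueError(f"usages sum to {u.sum()!r}, not 1")
    if np.isnan(a[u > 0]).any():
        return float("nan")
    return float(np.nansum(u * np.where(u > 0, a, 0.0)))


def _condition_usage(pb: PseudobulkMatrix, groups: pd.Series) -> pd.DataFrame:
    """Pooled counts per condition (isoforms x conditions)."""
    conds = pd.unique(groups.dropna())
    pooled = {}
    for c in conds:
        mask = (groups == c).to_numpy()
        pooled[c] = pb.counts[mask].sum(axis=0)
    return pd.DataFrame(pooled, index=pb.isoforms)


def weighted_attributes_by_group(
    pb: PseudobulkMatrix,
    catalog: IsoformCatalog,
    groups: np.ndarray | pd.Series,
    attribute: str,
    attrs: pd.DataFrame | None = None,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene A_g for each condition (genes x conditions), from counts pooled
    within the condition.

    For CDS/UTR attributes only protein-coding isoforms enter and usages are
    renormalized over them; genes without >=2 coding isoforms are NaN there.
    Genes whose attribute is undefined for an expressed isoform are NaN.
    """
    if attrs is None:
        attrs = isoform_attribute_table(catalog)
    groups = pd.Series(np.asarray(groups, dtype=object), index=pb.units.index)
    pooled = _condition_usage(pb, groups)
    a = attrs.loc[pb.isoforms]
    gene_ids = a["gene_id"]
    target_genes = pd.Index(pd.unique(gene_ids)) if genes is None else pd.Index(genes)
    coding_only = attribute in CODING_ONLY
    rows = {}
    for g in target_genes:
        sel = gene_ids == g
        sub_counts = pooled[sel.to_numpy()]
        sub_a = a.loc[sel, attribute].to_numpy(float)
        if coding_only:
            cod = a.loc[sel, "coding_score"].to_numpy() > 0
            if cod.sum() < 2:
                rows[g] = {c: np.nan for c in pooled.columns}
                continue
            sub_counts = sub_counts[cod]
            sub_a = sub_a[cod]
        vals = {}
        for c in pooled.columns:
            tot = sub_counts[c].sum()
            if tot == 0:
                vals[c] = np.nan
                continue
            u = sub_counts[c].to_numpy(float) / tot
            try:
                vals[c] = weighted_attribute(u, sub_a)
            except ValueError:
                vals[c] = np.nan
        rows[g] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class WeightedAttributeDelta:
    gene_id: str
    attribute: str
    A_condition: float
    A_reference: float
    delta: float


def attribute_delta(
    A_by_condition: pd.DataFrame,
    condition,
    attribute: str,
    reference=None,
) -> pd.DataFrame:
    """Per-gene delta of A_g between a condition and a reference.

    ``reference`` names another condition column; None means one-vs-rest, with
    the reference taken as the unweighted mean of the other conditions' A.
    TSS deltas are negated so positive = shift toward upstream TSSs.  Genes
    with an undefined A on either side are excluded.
    """
    A_cond = A_by_condition[condition]
    if reference is None:
        others = [c for c in A_by_condition.columns if c != condition]
        A_ref = A_by_condition[others].mean(axis=1)
    else:
        A_ref = A_by_condition[reference]
    raw = A_cond - A_ref
    sign = -1.0 if attribute in NEGATED else 1.0
    out = pd.DataFrame({
        "A_condition": A_cond,
        "A_reference": A_ref,
        "delta": sign * raw,
    })
    out["attribute"] = attribute
    return out.dropna(subset=["delta"])


def classify_pair_change(
    feature_results: pd.DataFrame,
    attrs: pd.DataFrame,
) -> set[str]:
    """Attributes on which a gene's top increasing and top decreasing isoforms
    differ, among TSS / PAS / exon count / length / coding potential.

    ``feature_results`` is the feature-level table for one gene (isoform_id,
    effect).  Ties in effect size break lexicographically by isoform id.
    """
    fr = feature_results.sort_values(["effect", "isoform_id"],
                                     ascending=[False, True])
    if len(fr) < 2:
        raise ValueError("need >=2 isoforms with feature-level effects")
    up = fr.iloc[0]["isoform_id"]
    down = fr.sort_values(["effect", "isoform_id"],
                          ascending=[True, True]).iloc[0]["isoform_id"]
    if up == down:
        return set()
    cols = {"TSS": "tss_bin", "PAS": "pas_bin", "exon count": "exon_count",
            "length": "length", "coding potential": "coding_score"}
    changed = set()
    for name, col in cols.items():
        if attrs.loc[up, col] != attrs.loc[down, col]:
            changed.add(name)
    return changed


def delta_correlations(
    deltas: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations of per-gene attribute deltas.

    ``deltas`` has one row per gene and one column per attribute delta.
    Returns (rho matrix, n matrix); pairs with fewer than 3 genes having both
    deltas defined are NaN with n reported.
    """
    cols = list(deltas.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    rho = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    nmat = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    np.fill_diagonal(rho.values, 1.0)
    for a, b in pairs:
        sub = deltas[[a, b]].dropna()
        nmat.loc[a, b] = nmat.loc[b, a] = len(sub)
        if len(sub) < 3:
            continue
        r = spearmanr(sub[a], sub[b]).statistic
        rho.loc[a, b] = rho.loc[b, a] = r
    return rho, nmat
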