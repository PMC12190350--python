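"""Cell-level senescence scoring, marker discovery, and classification.

The raw senescence score of a cell is the mean expression of all isoforms of a
marker gene panel after scaling the cell's total counts to 10,000.  The
normalized score divides by the mean raw score of young cells of the same cell
type, so young cells average 1 within each type.  Cells with a normalized
score over 5 are labeled senescent; machine-learning labels use a guard band
(below 4 -> 0, above 7 -> 1, otherwise excluded).

Marker discovery reuses the Dirichlet-multinomial usage scan on immune
pseudobulk units split senescent / non-senescent (BH-adjusted p < 0.01).  The
classifier is gradient-boosted trees (XGBoost) on per-cell isoform usages of
the marker genes, with a stratified 90/5/5 train/validation/test split and
early stopping on the validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xgboost as xgb
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .annotation_io import CellTable, CountMatrix, IsoformCatalog
from .qc_pseudobulk import pseudobulk
from .usage_dm import UsageScanResult, run_usage_scan

__all__ = [
    "SenescenceError",
    "SenescenceScores",
    "SenescenceClassifier",
    "senescence_score",
    "senescence_proportions",
    "discover_markers",
    "usage_features",
    "usage_pca",
    "stratified_split",
    "train_classifier",
    "predict_scores",
    "DEFAULT_XGB_PARAMS",
]

# Hyperparameters shipped as defaults for the senescence classifier.
DEFAULT_XGB_PARAMS: dict = {
    "eta": 0.01,
    "objective": "binary:logistic",
    "eval_metric": "aucpr",
    "tree_method": "approx",
    "max_depth": 7,
    "min_child_weight": 16,
    "subsample": 0.9967762267267729,
    "colsample_bynode": 0.4100293732438932,
    "lambda": 6.001086886655973,
    "nthread": 1,
}
DEFAULT_NUM_ROUNDS = 10_000
DEFAULT_EARLY_STOPPING = 50


class SenescenceError(ValueError):
    pass


@dataclass
class SenescenceScores:
    """Per-barcode scores and labels, aligned to the cell table."""

    df: pd.DataFrame  # raw_score, norm_score, label, ml_label
    marker_isoforms: pd.Index
    excluded: dict[str, str] = field(default_factory=dict)


def _marker_isoforms(catalog: IsoformCatalog, markers: list[str],
                     isoforms: pd.Index) -> pd.Index:
    df = catalog.df.reindex(isoforms)
    hit = df["gene_id"].isin(markers) | df["gene_name"].isin(markers)
    found = set(df.loc[hit, "gene_id"]) | set(df.loc[hit, "gene_name"])
    missing = [m for m in markers if m not in found]
    if missing:
        raise SenescenceError(f"marker genes absent from catalog/matrix: {missing}")
    return isoforms[hit.to_numpy()]


def senescence_score(
    counts: CountMatrix,
    cells: CellTable,
    markers: list[str],
    catalog: IsoformCatalog,
    sen_threshold: float = 5.0,
    ml_low: float = 4.0,
    ml_high: float = 7.0,
    target_sum: float = 10_000.0,
) -> SenescenceScores:
    """Score each cell and apply the strict senescence / ML-label thresholds.

    Depth-invariant by construction: counts are scaled to ``target_sum`` per
    cell before the marker mean.  Cell types without young cells (or with zero
    young mean) are excluded with a reason.
    """
    cdf = cells.df.loc[counts.barcodes]
    marker_iso = _marker_isoforms(catalog, markers, counts.isoforms)
    tot = np.asarray(counts.X.sum(axis=1)).ravel()
    scale = np.divide(target_sum, tot, out=np.zeros_like(tot, float), where=tot > 0)
    cols = counts.isoforms.get_indexer(marker_iso)
    M = np.asarray(counts.X[:, cols].todense(), float) * scale[:, None]
    raw = M.mean(axis=1)

    young = (cdf["age_category"] == "young").to_numpy()
    out = pd.DataFrame(index=counts.barcodes)
    out["raw_score"] = raw
    out["norm_score"] = np.nan
    excluded: dict[str, str] = {}
    for ct in pd.unique(cdf["cell_type"]):
        in_ct = (cdf["cell_type"] == ct).to_numpy()
        ym = raw[in_ct & young].mean() if (in_ct & young).any() else np.nan
        if not np.isfinite(ym) or ym <= 0:
            excluded[ct] = "no young cells with positive marker expression"
            continue
        out.loc[in_ct, "norm_score"] = raw[in_ct] / ym
    ns = out["norm_score"]
    out["label"] = np.where(ns > sen_threshold, "senescent", "non-senescent")
    out.loc[ns.isna(), "label"] = "excluded"
    out["ml_label"] = np.select(
        [ns < ml_low, ns > ml_high], ["0", "1"], default="excluded")
    out.loc[ns.isna(), "ml_label"] = "excluded"
    return SenescenceScores(out, marker_iso, excluded)


def senescence_proportions(scores: SenescenceScores, cells: CellTable) -> pd.DataFrame:
    """Senescent fraction per (cell type x age category x sex x region)."""
    df = scores.df.join(cells.df[["cell_type", "age_category", "sex", "region"]])
    df = df[df["label"] != "excluded"]
    grp = df.groupby(["cell_type", "age_category", "sex", "region"], observed=True)
    out = grp["label"].agg(
        n_labeled="size", n_senescent=lambda s: int((s == "senescent").sum()))
    out["fraction"] = out["n_senescent"] / out["n_labeled"]
    return out.reset_index()


def discover_markers(
    counts: CountMatrix,
    cells: CellTable,
    scores: SenescenceScores,
    catalog: IsoformCatalog,
    cell_type: str = "immune",
    padj_max: float = 0.01,
    min_units: int = 2,
) -> tuple[pd.Index, UsageScanResult]:
    """Genes with significant isoform usage change (BH padj < ``padj_max``)
    between senescent and non-senescent cells of one lineage, all timepoints
    pooled.  Units are (sample, senescence label) pseudobulks."""
    cdf = cells.df.loc[counts.barcodes].copy()
    cdf["sen_label"] = scores.df.loc[counts.barcodes, "label"]
    mask = (cdf["cell_type"] == cell_type) & (cdf["sen_label"] != "excluded")
    if not mask.any():
        raise SenescenceError(f"no labeled {cell_type} cells")
    sub_counts = counts.subset_barcodes(cdf.index[mask])
    sub_cells = CellTable(cdf[mask])
    pb = pseudobulk(sub_counts, sub_cells, keys=("sample_id", "sen_label"))
    lab = pb.units["sen_label"]
    for side in ("senescent", "non-senescent"):
        if (lab == side).sum() < min_units:
            raise SenescenceError(
                f"need >= {min_units} pseudobulk units per group; "
                f"{side} has {(lab == side).sum()}"
            )
    scan = run_usage_scan(pb, catalog, lab.to_numpy(), group_of_interest="senescent",
                          alpha=padj_max, contrast=f"senescent-vs-non ({cell_type})")
    genes = scan.significant_genes(adjusted=True, alpha=padj_max)
    return genes, scan


def usage_features(
    counts: CountMatrix,
    catalog: IsoformCatalog,
    genes: pd.Index | list[str],
) -> pd.DataFrame:
    """Per-cell isoform usage of the given genes (cells x isoforms).

    Usage is count / per-cell gene total; NaN where the gene total is zero
    (handled natively by the tree learner, mean-imputed for PCA).
    """
    gene_of = catalog.gene_of(counts.isoforms)
    keep = gene_of.isin(list(genes)).to_numpy()
    isoforms = counts.isoforms[keep]
    sub = np.asarray(counts.X[:, keep].todense(), float)
    codes, _ = pd.factorize(gene_of[keep])
    totals = np.zeros((sub.shape[0], codes.max() + 1))
    np.add.at(totals.T, codes, sub.T)
    denom = totals[:, codes]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, sub / np.maximum(denom, 1e-300), np.nan)
    return pd.DataFrame(vals, index=counts.barcodes, columns=isoforms)


def usage_pca(features: pd.DataFrame, n_components: int = 2
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """First principal components of mean-imputed usage features.

    Returns (scores with PC columns, explained-variance fractions); fewer
    components are returned (flagged by the shorter output) when the input is
    rank-deficient.
    """
    if features.shape[1] < 2:
        raise SenescenceError("need >=2 usage features for PCA")
    Xf = features.to_numpy(float)
    mu = np.nanmean(Xf, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    idx = np.where(np.isnan(Xf))
    Xf[idx] = mu[idx[1]]
    rank = np.linalg.matrix_rank(Xf - Xf.mean(axis=0))
    k = int(min(n_components, max(rank, 1), Xf.shape[0] - 1, Xf.shape[1]))
    pca = PCA(n_components=k, svd_solver="full")
    Z = pca.fit_transform(Xf)
    cols = [f"PC{i + 1}" for i in range(Z.shape[1])]
    return (pd.DataFrame(Z, index=features.index, columns=cols),
            pca.explained_variance_ratio_)


def stratified_split(
    strata: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05),
    seed: int = 0,
) -> pd.Series:
    """Assign 'train'/'validation'/'test' per row, stratified by the columns
    of ``strata`` (label x age x sex x region).

    Guarantees at least one row of each label value in validation and test
    when that label has >=3 rows overall; otherwise raises.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SenescenceError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assign = pd.Series("train", index=strata.index)
    for _, idx in strata.groupby(list(strata.columns), observed=True).indices.items():
        idx = strata.index[idx]
        perm = rng.permutation(len(idx))
        n_val = int(round(fractions[1] * len(idx)))
        n_test = int(round(fractions[2] * len(idx)))
        assign.loc[idx[perm[:n_val]]] = "validation"
        assign.loc[idx[perm[n_val:n_val + n_test]]] = "test"
    # repair: every label present in every split
    label = strata.iloc[:, 0]
    for lv in label.unique():
        rows = assign.index[label == lv]
        if len(rows) < 3:
            raise SenescenceError(
                f"label {lv!r} has {len(rows)} cells; cannot stratify 3 splits")
        for split in ("validation", "test"):
            if not (assign.loc[rows] == split).any():
                pool = rows[(assign.loc[rows] == "train").to_numpy()]
                if len(pool) <= 1:
                    raise SenescenceError(f"label {lv!r} cannot populate {split}")
                assign.loc[pool[int(rng.integers(len(pool)))]] = split
    for split in ("train", "validation", "test"):
        if set(label[assign == split].unique()) != set(label.unique()):
            raise SenescenceError(f"split {split!r} is missing a class")
    return assign


@dataclass
class SenescenceClassifier:
    booster: xgb.Booster
    feature_names: list[str]
    split: pd.Series
    auroc: float
    roc_points: pd.DataFrame
    average_precision: float
    best_iteration: int


def train_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    strata: pd.DataFrame | None = None,
    params: dict | None = None,
    num_rounds: int = DEFAULT_NUM_ROUNDS,
    early_stopping: int = DEFAULT_EARLY_STOPPING,
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05),
    seed: int = 0,
) -> SenescenceClassifier:
    """Train the gradient-boosted senescence classifier.

    ``labels`` are 0/1 per cell (cells with other values must be excluded
    upstream).  The split is stratified by label plus the ``strata`` columns;
    training uses early stopping on the validation split and reports the ROC
    curve / AUROC and average precision on the test split.
    """
    y = labels.astype(int)
    if set(y.unique()) != {0, 1}:
        raise SenescenceError("labels must contain both classes 0 and 1")
    strat = pd.DataFrame({"label": y})
    if strata is not None:
        strat = pd.concat([strat, strata.loc[features.index]], axis=1)
    split = stratified_split(strat, fractions, seed)
    p = dict(DEFAULT_XGB_PARAMS if params is None else params)
    p["seed"] = seed

    def dmat(which: str) -> xgb.DMatrix:
        m = split == which
        return xgb.DMatrix(features[m].to_numpy(float), label=y[m].to_numpy(),
                           feature_names=list(features.columns), missing=np.nan)

    dtrain, dval, dtest = dmat("train"), dmat("validation"), dmat("test")
    booster = xgb.train(
        p, dtrain, num_boost_round=num_rounds,
        evals=[(dval, "validation")],
        early_stopping_rounds=early_stopping, verbose_eval=False,
    )
    best_it = getattr(booster, "best_iteration", num_rounds - 1)
    prob = booster.predict(dtest, iteration_range=(0, best_it + 1))
    y_test = y[split == "test"].to_numpy()
    fpr, tpr, thr = roc_curve(y_test, prob)
    return SenescenceClassifier(
        booster=booster,
        feature_names=list(features.columns),
        split=split,
        auroc=float(roc_auc_score(y_test, prob)),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        average_precision=float(average_precision_score(y_test, prob)),
        best_iteration=int(best_it),
    )


def predict_scores(model: SenescenceClassifier, features: pd.DataFrame) -> pd.Series:
    """Predicted senescence probability for any cells.

    Features must match the model's feature list; missing values are handled
    as in training (native NaN routing in the trees).
    """
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise SenescenceError(f"missing features: {missing}")
    X = features[model.feature_names].to_numpy(float)
    d = xgb.DMatrix(X, feature_names=model.feature_names, missing=np.nan)
    prob = model.booster.predict(
        d, iteration_range=(0, model.best_iteration + 1))
    return pd.Series(prob, index=features.index, name="predicted_senescence")
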