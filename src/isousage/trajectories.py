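"""Temporal screening and clustering of isoform expression trajectories.

Screening: for each trace (normalized expression vs age in months, centered),
a quadratic Gaussian model is compared with a flat (intercept-only) model by a
likelihood-ratio test, lr = n * log(RSS_flat / RSS_quad), p from chi-square
with 2 df.  Traces are size-factor-normalized pseudobulk expression divided by
the young value (so young = 1 by construction; traces with zero young value
are dropped).

Clustering: EM over a mixture of quadratic mean curves with cluster-specific
isotropic variance, 10 restarts keeping the best log-likelihood; the number of
clusters is picked from a candidate grid by the mean silhouette score on
standardized trace vectors; clusters are ordered by increasing geriatric/young
fold change of their mean curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2, mannwhitneyu
from sklearn.metrics import silhouette_score

from .annotation_io import IsoformCatalog
from .qc_pseudobulk import PseudobulkMatrix

__all__ = [
    "TrajectoryTrace",
    "TrajectoryFit",
    "TrajectoryClusterModel",
    "fit_trajectory",
    "cluster_trajectories",
    "build_traces",
    "expression_change_summary",
    "length_shift_analysis",
]

K_CANDIDATES = (8, 10, 12, 14)


@dataclass
class TrajectoryTrace:
    """One isoform x cell-type expression trace over age."""

    isoform_id: str
    cell_type: str
    ages: np.ndarray       # months, one per observation (replicates allowed)
    values: np.ndarray     # normalized expression, young = 1 by construction


@dataclass
class TrajectoryFit:
    beta0: float
    beta1: float
    beta2: float
    loglik_flat: float
    loglik_quad: float
    lr_stat: float
    p_value: float


def _design(ages: np.ndarray) -> np.ndarray:
    s = ages - ages.mean()
    return np.column_stack([np.ones_like(s), s, s * s])


def fit_trajectory(values: np.ndarray, ages: np.ndarray) -> TrajectoryFit:
    """Quadratic-vs-flat Gaussian LRT on centered age.

    Requires >=4 observations (the quadratic is saturated below that).
    Constant traces give lr = 0, p = 1; an exact quadratic with curvature
    gives p = 0.
    """
    y = np.asarray(values, float)
    ages = np.asarray(ages, float)
    n = y.size
    if n < 4:
        raise ValueError("need >=4 observations for the quadratic LRT")
    X = _design(ages)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_quad = float(np.sum((y - X @ beta) ** 2))
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    rss_quad = min(rss_quad, rss_flat)

    def gauss_ll(rss: float) -> float:
        if rss <= 0:
            return float("inf")
        return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)

    if rss_flat <= 1e-300:                       # exactly constant
        lr, p = 0.0, 1.0
    elif rss_quad <= 1e-12 * rss_flat:           # exact quadratic fit
        lr, p = float("inf"), 0.0
    else:
        lr = n * np.log(rss_flat / rss_quad)
        p = float(chi2.sf(lr, 2))
    return TrajectoryFit(float(beta[0]), float(beta[1]), float(beta[2]),
                         gauss_ll(rss_flat), gauss_ll(rss_quad), lr, p)


@dataclass
class TrajectoryClusterModel:
    K: int
    mean_curves: np.ndarray            # K x 3 quadratic coefficients
    cluster_variances: np.ndarray      # K
    weights: np.ndarray                # K
    assignments: np.ndarray            # N, argmax responsibility
    responsibilities: np.ndarray       # N x K
    silhouette: float
    ordering: np.ndarray               # rank 1..K by geriatric/young fold change
    loglik: float
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    ages: np.ndarray | None = None

    def mean_trace(self, k: int, ages: np.ndarray | None = None) -> np.ndarray:
        a = self.ages if ages is None else np.asarray(ages, float)
        return _design(a) @ self.mean_curves[k]


def _em_once(Y: np.ndarray, X: np.ndarray, K: int, rng: np.random.Generator,
             max_iter: int = 300, tol: float = 1e-8, ll_history: list | None = None
             ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    N, T = Y.shape
    XtX_inv_Xt = np.linalg.pinv(X)
    # init from K random traces
    centers = Y[rng.choice(N, size=K, replace=False)]
    d = ((Y[:, None, :] - centers[None]) ** 2).sum(-1)
    R = np.zeros((N, K))
    R[np.arange(N), d.argmin(1)] = 1.0
    ll_prev = -np.inf
    beta = np.zeros((K, 3))
    var = np.ones(K)
    w = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        # M-step
        Nk = R.sum(0)
        if (Nk < 1e-9).any():
            raise FloatingPointError("empty cluster")
        w = Nk / N
        for k in range(K):
            ybar = (R[:, k][:, None] * Y).sum(0) / Nk[k]
            beta[k] = XtX_inv_Xt @ ybar
            resid = Y - X @ beta[k]
            var[k] = float((R[:, k] * (resid ** 2).sum(1)).sum() / (T * Nk[k]))
            if var[k] < 1e-12:
                raise FloatingPointError("zero-variance cluster")
        # E-step
        logp = np.empty((N, K))
        for k in range(K):
            resid = Y - X @ beta[k]
            logp[:, k] = (np.log(w[k]) - 0.5 * T * np.log(2 * np.pi * var[k])
                          - (resid ** 2).sum(1) / (2 * var[k]))
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        if ll_history is not None:
            ll_history.append(ll)
        R = np.exp(logp - norm[:, None])
        if ll - ll_prev < tol * max(1.0, abs(ll)) and ll >= ll_prev:
            ll_prev = ll
            break
        ll_prev = ll
    return ll_prev, beta.copy(), var.copy(), w.copy(), R


def cluster_trajectories(
    traces: np.ndarray,
    ages: np.ndarray,
    K_candidates: tuple[int, ...] = K_CANDIDATES,
    seed: int = 0,
    n_restarts: int = 10,
) -> TrajectoryClusterModel:
    """Fit the quadratic-mixture model for each candidate K and return the one
    maximizing the mean silhouette on standardized trace vectors."""
    Y = np.asarray(traces, float)
    ages = np.asarray(ages, float)
    N = Y.shape[0]
    K_candidates = tuple(k for k in K_candidates if k < N)
    if not K_candidates:
        raise ValueError("more cluster candidates than traces")
    X = _design(ages)
    rng = np.random.default_rng(seed)
    # standardize each trace (shape, not scale, drives cluster identity);
    # per-timepoint scaling would amplify noise at the young point, which is
    # 1 for every trace by construction
    sd = Y.std(axis=1, ddof=0, keepdims=True)
    Z = (Y - Y.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)

    best: TrajectoryClusterModel | None = None
    sil_by_k: dict[int, float] = {}
    for K in K_candidates:
        fit = None
        for _ in range(n_restarts):
            try:
                cand = _em_once(Y, X, K, rng)
            except FloatingPointError:
                continue
            if fit is None or cand[0] > fit[0]:
                fit = cand
        if fit is None:
            raise RuntimeError(f"all EM restarts degenerate at K={K}")
        ll, beta, var, w, R = fit
        labels = R.argmax(1)
        if len(np.unique(labels)) < 2:
            sil = -1.0
        else:
            sil = float(silhouette_score(Z, labels, metric="euclidean"))
        sil_by_k[K] = sil
        if best is None or sil > best.silhouette:
            fc = (X[-1] @ beta.T) / np.maximum(X[0] @ beta.T, 1e-12)
            order = np.empty(K, int)
            order[np.argsort(fc)] = np.arange(1, K + 1)
            best = TrajectoryClusterModel(
                K=K, mean_curves=beta, cluster_variances=var, weights=w,
                assignments=labels, responsibilities=R, silhouette=sil,
                ordering=order, loglik=ll, ages=ages,
            )
    assert best is not None
    best.silhouette_by_k = sil_by_k
    return best


# ---------------------------------------------------------------------------
# trace construction and summaries
# ---------------------------------------------------------------------------

_AGE_ORDER = ("young", "middle", "old", "geriatric")


def build_traces(
    pb: PseudobulkMatrix,
    min_young: float = 1e-9,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Per (isoform, cell type) traces from normalized pseudobulk.

    Returns (grid_traces, grid_ages, sample_points):
    grid_traces has one row per trace with per-age-category values normalized
    to young (geriatric ages averaged per sex when they differ); sample_points
    holds the per-sample normalized observations used for the LRT screen.
    Traces with zero young expression are dropped.
    """
    if pb.size_factors is None:
        raise ValueError("pseudobulk needs size factors")
    norm = pb.normalized()
    units = pb.units
    cats_present = [c for c in _AGE_ORDER if c in set(units["age_category"])]
    grid_ages = np.array([units.loc[units["age_category"] == c, "age_months"]
                          .astype(float).mean() for c in cats_present])
    rows, sample_rows = [], []
    for ct, uidx in units.groupby("cell_type", observed=True).indices.items():
        sub_units = units.iloc[uidx]
        sub = norm[uidx]
        young = sub_units["age_category"] == "young"
        if not young.any():
            continue
        young_val = sub[young.to_numpy()].mean(axis=0)
        grid = np.vstack([
            sub[(sub_units["age_category"] == c).to_numpy()].mean(axis=0)
            for c in cats_present
        ])
        ok = young_val > min_young
        for j in np.flatnonzero(ok):
            iso = pb.isoforms[j]
            rows.append((iso, ct, *(grid[:, j] / young_val[j])))
            for val, age in zip(sub[:, j] / young_val[j],
                                sub_units["age_months"].astype(float)):
                sample_rows.append((iso, ct, age, val))
    cols = ["isoform_id", "cell_type", *cats_present]
    grid_traces = pd.DataFrame(rows, columns=cols)
    sample_points = pd.DataFrame(sample_rows,
                                 columns=["isoform_id", "cell_type", "age", "value"])
    return grid_traces, grid_ages, sample_points


def expression_change_summary(grid_traces: pd.DataFrame) -> pd.Series:
    """Per-cell-type mean relative expression change from young: the mean over
    traces of mean(value_t - 1) for t in {middle, old, geriatric}."""
    late = [c for c in ("middle", "old", "geriatric") if c in grid_traces.columns]
    if not late:
        raise ValueError("no post-young timepoints present")
    per_trace = grid_traces[late].mean(axis=1) - 1.0
    return per_trace.groupby(grid_traces["cell_type"]).mean()


def length_shift_analysis(
    pb: PseudobulkMatrix,
    catalog: IsoformCatalog,
    young_category: str = "young",
    old_category: str = "geriatric",
    pseudocount: float = 0.5,
    n_bins: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 fold change (old vs young) by transcript-length tertile.

    Keeps transcripts in the top 50% of normalized expression in either age,
    bins them into ``n_bins`` groups of increasing length, and compares the
    log2FC distributions between each bin pair with a two-sided Wilcoxon
    rank-sum test (normal approximation, tie-corrected).
    """
    if pb.size_factors is None:
        raise ValueError("pseudobulk needs size factors")
    norm = pb.normalized()
    cats = pb.units["age_category"]
    young = norm[(cats == young_category).to_numpy()].mean(axis=0)
    old = norm[(cats == old_category).to_numpy()].mean(axis=0)
    keep = (young >= np.median(young)) | (old >= np.median(old))
    lengths = catalog.df.reindex(pb.isoforms)["length"].to_numpy(float)
    log2fc = np.log2((old + pseudocount) / (young + pseudocount))
    df = pd.DataFrame({
        "isoform_id": pb.isoforms[keep],
        "length": lengths[keep],
        "log2fc": log2fc[keep],
    })
    ranks = df["length"].rank(method="first")
    df["length_bin"] = np.minimum(
        (n_bins * (ranks - 1) / len(df)).astype(int), n_bins - 1)
    tests = []
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            a = df.loc[df["length_bin"] == i, "log2fc"]
            b = df.loc[df["length_bin"] == j, "log2fc"]
            if len(a) < 2 or len(b) < 2:
                continue
            if pd.concat([a, b]).nunique() <= 1:
                p = 1.0  # all values tied: no rank evidence either way
            else:
                p = float(mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue)
            tests.append((i, j, len(a), len(b), p))
    return df, pd.DataFrame(tests, columns=["bin_a", "bin_b", "n_a", "n_b", "p_value"])
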