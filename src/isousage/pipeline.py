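"""End-to-end orchestration from a single declarative config.

Stages (dependency order): simulate/ingest -> qc -> pseudobulk -> cig ->
attributes -> trajectories -> aig -> senescence.  Every output file is
recorded in a manifest with content hashes, the seed, and the package version;
a rerun with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation_io import parse_gtf, read_cell_metadata, read_counts
from .attributes import (
    PAIR_ATTRIBUTES,
    attribute_delta,
    classify_pair_change,
    delta_correlations,
    isoform_attribute_table,
    weighted_attributes_by_group,
)
from .qc_pseudobulk import (
    QCError,
    filter_barcodes,
    filter_transcripts,
    pseudobulk,
    size_factors,
    usage,
)
from .senescence import (
    SenescenceError,
    discover_markers,
    predict_scores,
    senescence_proportions,
    senescence_score,
    train_classifier,
    usage_features,
    usage_pca,
)
from .synthetic_data import (
    SampleSpec,
    SimulationConfig,
    load_fixture,
    simulate_dataset,
    write_fixture,
)
from .trajectories import (
    build_traces,
    cluster_trajectories,
    fit_trajectory,
    length_shift_analysis,
)
from .usage_dm import ContrastError, run_usage_scan

log = logging.getLogger("isousage")

STAGES = ("simulate", "ingest", "qc", "pseudobulk", "cig", "attributes",
          "trajectories", "aig", "senescence")
_DEPS = {
    "qc": ("simulate", "ingest"),
    "pseudobulk": ("qc",),
    "cig": ("pseudobulk",),
    "attributes": ("cig",),
    "trajectories": ("pseudobulk",),
    "aig": ("pseudobulk",),
    "senescence": ("qc",),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Thresholds:
    """All analysis constants, surfaced as named defaults."""

    p_cig: float = 0.05
    p_aig: float = 0.05
    p_traj: float = 0.01
    padj_sen: float = 0.01
    tsl: int = 1
    min_cell_frac: float = 0.005
    mito_max: float = 0.20
    min_genes: int = 100
    top_pct: float = 0.98
    tss_bin: int = 20
    pas_bin: int = 75
    sen_threshold: float = 5.0
    ml_low: float = 4.0
    ml_high: float = 7.0
    split: tuple[float, float, float] = (0.90, 0.05, 0.05)
    k_candidates: tuple[int, ...] = (8, 10, 12, 14)

    def __post_init__(self) -> None:
        if not (0 < self.p_cig <= 1 and 0 < self.p_traj <= 1 and 0 < self.padj_sen <= 1):
            raise ValueError("p-value thresholds must be in (0, 1]")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class PipelineConfig:
    """Inputs (paths or a simulation config), stage toggles, thresholds, seed."""

    schema_version: int = 1
    out_dir: str = "isousage_run"
    seed: int = 0
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    input_dir: str | None = None          # fixture directory when not simulating
    stages: dict[str, bool] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def enabled(self, stage: str) -> bool:
        if stage == "ingest":
            return self.input_dir is not None
        if stage == "simulate":
            return self.input_dir is None
        return self.stages.get(stage, True)

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = {
            "schema_version": self.schema_version,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "input_dir": self.input_dir,
            "stages": dict(self.stages),
            "thresholds": dataclasses.asdict(self.thresholds),
        }
        d["thresholds"]["split"] = list(self.thresholds.split)
        d["thresholds"]["k_candidates"] = list(self.thresholds.k_candidates)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["design"] = [dataclasses.asdict(s) for s in self.simulation.design]
            sim["trajectory_cluster_shapes"] = [
                list(t) for t in self.simulation.trajectory_cluster_shapes]
            d["simulation"] = sim
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        thr = d.get("thresholds", {})
        if "split" in thr:
            thr["split"] = tuple(thr["split"])
        if "k_candidates" in thr:
            thr["k_candidates"] = tuple(thr["k_candidates"])
        sim = None
        if d.get("simulation") is not None:
            s = dict(d["simulation"])
            s["design"] = [SampleSpec(**x) for x in s["design"]]
            s["trajectory_cluster_shapes"] = tuple(
                tuple(t) for t in s["trajectory_cluster_shapes"])
            s["cell_type_proportions"] = dict(s["cell_type_proportions"])
            sim = SimulationConfig(**s)
        return cls(
            schema_version=d.get("schema_version", 1),
            out_dir=d.get("out_dir", "isousage_run"),
            seed=d.get("seed", 0),
            simulation=sim,
            input_dir=d.get("input_dir"),
            stages=d.get("stages", {}) or {},
            thresholds=Thresholds(**thr),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order and return the run manifest.

    On stage failure the partial manifest is persisted before re-raising as
    :class:`PipelineError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    thr = config.thresholds
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}

    enabled = {s: config.enabled(s) for s in STAGES}
    for s, deps in _DEPS.items():
        if enabled.get(s) and not any(enabled.get(d) for d in deps):
            log.info("stage %s disabled: dependency %s disabled", s, deps)
            enabled[s] = False

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
        manifest["stages"].setdefault(stage, []).append(name)

    def persist() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    state: dict = {}
    try:
        # ------------------------------------------------------ simulate/ingest
        if enabled["simulate"]:
            stage = "simulate"
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            catalog, cells, counts, truth = simulate_dataset(sim)
            paths = write_fixture(catalog, cells, counts, truth, out / "fixture")
            for name, p in paths.items():
                record(stage, f"fixture/{name}", Path(p))
            state.update(catalog=catalog, cells=cells, counts=counts, truth=truth,
                         markers=truth.marker_genes)
        elif enabled["ingest"]:
            stage = "ingest"
            catalog, cells, counts, truth, markers = load_fixture(config.input_dir)
            state.update(catalog=catalog, cells=cells, counts=counts, truth=truth,
                         markers=markers)

        catalog, cells, counts = state["catalog"], state["cells"], state["counts"]

        # ------------------------------------------------------------------ qc
        if enabled["qc"]:
            stage = "qc"
            counts, cells = filter_barcodes(
                counts, cells, catalog, mito_max=thr.mito_max,
                min_genes=thr.min_genes, top_pct=thr.top_pct)
            counts = filter_transcripts(
                counts, catalog, cells,
                min_cell_frac=thr.min_cell_frac, tsl_required=thr.tsl)
            state.update(counts=counts, cells=cells)
            record(stage, "qc/cells",
                   _write_tsv(cells.df, out / "qc_cells.tsv", index=True))
            log.info("qc: %d cells, %d isoforms retained", len(cells), len(counts.isoforms))

        # ---------------------------------------------------------- pseudobulk
        if enabled["pseudobulk"]:
            stage = "pseudobulk"
            pb = pseudobulk(counts, cells)
            try:
                pb.size_factors = size_factors(pb)
            except QCError:
                log.info("size factors: falling back to gene-level reference")
                codes = pd.factorize(catalog.gene_of(pb.isoforms))[0]
                gcounts = np.zeros((pb.n_units, codes.max() + 1))
                np.add.at(gcounts.T, codes, pb.counts.T.astype(float))
                from .qc_pseudobulk import PseudobulkMatrix
                pb.size_factors = size_factors(PseudobulkMatrix(
                    pb.units, pd.Index(range(gcounts.shape[1])), gcounts))
            state["pb"] = pb
            um = usage(pb, catalog)
            sf = pb.units.copy()
            sf["size_factor"] = pb.size_factors
            record(stage, "pseudobulk/size_factors",
                   _write_tsv(sf, out / "size_factors.tsv", index=True))
            record(stage, "pseudobulk/usage", _write_tsv(
                pd.DataFrame(um.values, index=um.units.index, columns=um.isoforms),
                out / "usage.tsv", index=True))

        # ------------------------------------------------------------- cig scan
        attrs = isoform_attribute_table(catalog, thr.tss_bin, thr.pas_bin)
        if enabled["cig"]:
            stage = "cig"
            pb = state["pb"]
            scans = {}
            for ct in pd.unique(pb.units["cell_type"]):
                groups = np.where(pb.units["cell_type"] == ct, ct, "rest")
                if (groups == ct).sum() < 1 or (groups == "rest").sum() < 1:
                    continue
                scans[ct] = run_usage_scan(pb, catalog, groups, group_of_interest=ct,
                                           alpha=thr.p_cig, contrast=f"{ct} vs rest")
            state["cig_scans"] = scans
            gene_tab = pd.concat(
                [s.gene_table.assign(cell_type=ct) for ct, s in scans.items()],
                ignore_index=True)
            iso_tab = pd.concat(
                [s.isoform_table.assign(cell_type=ct) for ct, s in scans.items()],
                ignore_index=True)
            record(stage, "cig/genes", _write_tsv(gene_tab, out / "cig_genes.tsv"))
            record(stage, "cig/isoforms", _write_tsv(iso_tab, out / "cig_isoforms.tsv"))
            cigs = set()
            for s in scans.values():
                cigs |= set(s.significant_genes(alpha=thr.p_cig))
            state["cigs"] = sorted(cigs)
            log.info("cig: %d genes significant in >=1 cell type", len(cigs))

        # ----------------------------------------------------------- attributes
        if enabled["attributes"] and state.get("cig_scans"):
            stage = "attributes"
            pb = state["pb"]
            delta_rows, pair_counts = [], {a: 0 for a in PAIR_ATTRIBUTES}
            n_classified = 0
            ct_groups = pb.units["cell_type"].to_numpy()
            for ct, scan in state["cig_scans"].items():
                sig = scan.significant_genes(alpha=thr.p_cig)
                if not len(sig):
                    continue
                for attribute in ("length", "tss_bin", "pas_bin", "coding_score"):
                    A = weighted_attributes_by_group(
                        pb, catalog, ct_groups, attribute, attrs=attrs,
                        genes=pd.Index(sig))
                    if ct not in A.columns:
                        continue
                    d = attribute_delta(A, ct, attribute)
                    d["cell_type"] = ct
                    d["gene_id"] = d.index
                    delta_rows.append(d)
                for g in sig:
                    fr = scan.isoform_table[scan.isoform_table["gene_id"] == g]
                    if len(fr) < 2:
                        continue
                    changed = classify_pair_change(fr, attrs)
                    n_classified += 1
                    for a in changed:
                        pair_counts[a] += 1
            deltas = (pd.concat(delta_rows, ignore_index=True)
                      if delta_rows else pd.DataFrame())
            record(stage, "attributes/deltas",
                   _write_tsv(deltas, out / "attribute_deltas.tsv"))
            pair_df = pd.DataFrame(
                {"attribute": list(pair_counts), "n_changed": list(pair_counts.values()),
                 "n_classified": n_classified})
            record(stage, "attributes/pair_changes",
                   _write_tsv(pair_df, out / "pair_changes.tsv"))
            if len(deltas):
                wide = deltas.pivot_table(index=["gene_id", "cell_type"],
                                          columns="attribute", values="delta")
                rho, nmat = delta_correlations(wide)
                record(stage, "attributes/correlations",
                       _write_tsv(rho, out / "attribute_correlations.tsv", index=True))
                state["delta_corr"] = rho

        # --------------------------------------------------------- trajectories
        if enabled["trajectories"]:
            stage = "trajectories"
            pb = state["pb"]
            grid, grid_ages, points = build_traces(pb)
            fits = []
            for (iso, ct), sub in points.groupby(["isoform_id", "cell_type"],
                                                 observed=True):
                if len(sub) < 4:
                    continue
                f = fit_trajectory(sub["value"].to_numpy(), sub["age"].to_numpy())
                fits.append((iso, ct, f.lr_stat, f.p_value))
            fit_df = pd.DataFrame(fits, columns=["isoform_id", "cell_type",
                                                 "lr_stat", "p_value"])
            record(stage, "trajectories/fits",
                   _write_tsv(fit_df, out / "trajectory_fits.tsv"))
            sig = fit_df[fit_df["p_value"] < thr.p_traj]
            key = grid.set_index(["isoform_id", "cell_type"])
            sel = key.loc[list(sig[["isoform_id", "cell_type"]]
                               .itertuples(index=False, name=None))]
            state["traj_grid"] = grid
            if len(sel) > max(min(thr.k_candidates), 2) * 2:
                ks = tuple(k for k in thr.k_candidates if k < len(sel)) or (2,)
                model = cluster_trajectories(sel.to_numpy(float), grid_ages,
                                             K_candidates=ks, seed=config.seed)
                assign = sel.reset_index()[["isoform_id", "cell_type"]]
                assign["cluster"] = model.assignments
                assign["cluster_rank"] = model.ordering[model.assignments]
                record(stage, "trajectories/clusters",
                       _write_tsv(assign, out / "trajectory_clusters.tsv"))
                record(stage, "trajectories/mean_curves", _write_tsv(
                    pd.DataFrame(model.mean_curves,
                                 columns=["beta0", "beta1", "beta2"]),
                    out / "trajectory_mean_curves.tsv"))
                state["traj_model"] = model
                log.info("trajectories: %d screened, K=%d (silhouette %.3f)",
                         len(sel), model.K, model.silhouette)
            lsd, lst = length_shift_analysis(pb, catalog)
            record(stage, "trajectories/length_bins",
                   _write_tsv(lsd, out / "length_bin_log2fc.tsv"))
            record(stage, "trajectories/length_tests",
                   _write_tsv(lst, out / "length_bin_tests.tsv"))

        # ------------------------------------------------------------- aig scan
        if enabled["aig"]:
            stage = "aig"
            pb = state["pb"]
            cats = pb.units["age_category"]
            aig_scans = {}
            for older in ("middle", "old", "geriatric"):
                if not ((cats == "young").any() and (cats == older).any()):
                    continue
                groups = np.where(cats == "young", "young",
                                  np.where(cats == older, older, None))
                try:
                    aig_scans[older] = run_usage_scan(
                        pb, catalog, groups, group_of_interest=older,
                        alpha=thr.p_aig, contrast=f"young vs {older}")
                except ContrastError:
                    continue
            state["aig_scans"] = aig_scans
            gene_tab = pd.concat(
                [s.gene_table.assign(comparison=f"young-vs-{c}")
                 for c, s in aig_scans.items()], ignore_index=True)
            record(stage, "aig/genes", _write_tsv(gene_tab, out / "aig_genes.tsv"))
            aigs = set()
            for s in aig_scans.values():
                aigs |= set(s.significant_genes(alpha=thr.p_aig))
            state["aigs"] = sorted(aigs)
            log.info("aig: %d genes significant in >=1 comparison", len(aigs))

        # ----------------------------------------------------------- senescence
        if enabled["senescence"]:
            stage = "senescence"
            present = set(catalog.gene_of(counts.isoforms)) | set(
                catalog.df.loc[counts.isoforms, "gene_name"])
            markers = [m for m in state["markers"] if m in present]
            if len(markers) < len(state["markers"]):
                log.info("senescence: %d/%d marker genes survive filtering",
                         len(markers), len(state["markers"]))
            scores = senescence_score(
                counts, cells, markers, catalog,
                sen_threshold=thr.sen_threshold, ml_low=thr.ml_low,
                ml_high=thr.ml_high)
            record(stage, "senescence/scores",
                   _write_tsv(scores.df, out / "senescence_scores.tsv", index=True))
            props = senescence_proportions(scores, cells)
            record(stage, "senescence/proportions",
                   _write_tsv(props, out / "senescence_proportions.tsv"))
            state["sen_scores"] = scores
            state["sen_props"] = props
            try:
                marker_genes, scan = discover_markers(
                    counts, cells, scores, catalog, padj_max=thr.padj_sen)
                record(stage, "senescence/marker_scan",
                       _write_tsv(scan.gene_table, out / "senescence_marker_genes.tsv"))
                state["sen_marker_genes"] = list(marker_genes)
                with open(out / "senescence_markers.txt", "w") as fh:
                    fh.write("\n".join(marker_genes) + "\n")
                record(stage, "senescence/markers", out / "senescence_markers.txt")
            except SenescenceError as exc:
                log.info("senescence marker discovery skipped: %s", exc)
                marker_genes = pd.Index([])
            if len(marker_genes):
                cdf = cells.df
                immune = counts.subset_barcodes(
                    cdf.index[(cdf["cell_type"] == "immune").to_numpy()])
                feats = usage_features(immune, catalog, marker_genes)
                pcs, evr = usage_pca(feats)
                record(stage, "senescence/pca",
                       _write_tsv(pcs, out / "senescence_pca.tsv", index=True))
                ml = scores.df.loc[feats.index, "ml_label"]
                labeled = ml.isin(["0", "1"])
                if labeled.sum() >= 30 and ml[labeled].nunique() == 2:
                    try:
                        clf = train_classifier(
                            feats[labeled], ml[labeled].astype(int),
                            strata=cdf.loc[feats.index[labeled],
                                           ["age_category", "sex", "region"]],
                            fractions=thr.split, seed=config.seed)
                        record(stage, "senescence/roc", _write_tsv(
                            clf.roc_points, out / "senescence_roc.tsv"))
                        manifest["classifier"] = {
                            "auroc": clf.auroc,
                            "average_precision": clf.average_precision,
                            "n_features": len(clf.feature_names),
                            "best_iteration": clf.best_iteration,
                        }
                        pred = predict_scores(clf, usage_features(
                            counts, catalog, marker_genes))
                        record(stage, "senescence/predicted", _write_tsv(
                            pred.to_frame(), out / "predicted_senescence.tsv",
                            index=True))
                        state["classifier"] = clf
                    except SenescenceError as exc:
                        log.info("classifier skipped: %s", exc)
                else:
                    log.info("classifier skipped: too few labeled immune cells")
    except Exception as exc:
        persist()
        raise PipelineError(stage, exc) from exc

    persist()
    manifest["state"] = state
    return manifest
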