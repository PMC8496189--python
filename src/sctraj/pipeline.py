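"""End-to-end orchestration of the analysis stages from one config.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_tag])`` so stages can be re-run in
isolation and a full synthetic run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster, cytometry, io, markers, qc, simulate, trajectory
from .datatypes import ExpressionMatrix

log = logging.getLogger("sctraj")

STAGE_TAGS = {"simulate": 1, "qc": 2, "cluster": 3, "trajectory": 4, "markers": 5, "cytometry": 6}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), STAGE_TAGS[stage]])
    return int(ss.generate_state(1)[0])


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                  # or "real_data"
    outdir: str = "sctraj_run"
    seed: int = 0
    # input paths (real_data mode)
    matrix_dir: str | None = None
    metadata_path: str | None = None
    tf_list_path: str | None = None
    index_sort_path: str | None = None
    hoechst_path: str | None = None
    # QC
    actb_gene: str = "Actb"
    actb_percentile: float = 1.0
    min_total_counts: int = 65536
    # clustering / embedding
    hvg_mean_cutoff: float = 0.3
    hvg_dispersion_cutoff: float = 0.5
    n_pcs: int = 50
    snn_dims: int = 17
    snn_k: int = 20
    resolution: float = 1.3
    tsne_dims: int = 15
    perplexity: float = 70.0
    tsne_seed: int = 132
    # trajectory
    slope_top_k: int = 10
    trajectory_population: str = simulate.TRAJECTORY_LABEL
    # markers / TF correlogram
    marker_logfc_threshold: float = float(np.log(2.0))
    tf_min_diff_pct: float = 0.10
    tf_logfc_min: float = 0.4
    tf_min_pct: float = 0.3
    tf_fdr_max: float = 0.05
    tf_top_n: int = 3
    # cytometry
    hoechst_mode_factor: float = 1.5
    # synthetic-mode generator parameters (forwarded to SimConfig)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> Path:
    """Run the stages in order and write all artifacts under ``config.outdir``.

    ``stop_after`` (a stage name from ``STAGE_TAGS``) truncates the run
    after that stage, letting the CLI expose per-stage checkpoints.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_TAGS},
        "artifacts": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def emit(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    stage = "simulate"
    try:
        if config.mode == "synthetic":
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
            sim_cfg = simulate.SimConfig(**sim_kwargs)
            matrix, metadata, truth = simulate.simulate_timecourse(sim_cfg)
            matrix, truth = simulate.plant_qc_failures(matrix, truth, sim_cfg)
            index_table = simulate.simulate_index_sort(metadata, sim_cfg)
            hoechst_values, hoechst_labels = simulate.simulate_hoechst(
                10000,
                sim_cfg.s_phase_fraction,
                seed=stage_seed(config.seed, "cytometry"),
            )
            io.write_count_matrix(matrix, out, prefix="raw_")
            manifest["artifacts"] += ["raw_matrix.mtx", "raw_genes.tsv", "raw_cells.tsv"]
            io.write_table(metadata, emit("metadata.tsv"))
            io.write_table(truth.cells_frame(), emit("truth_cells.tsv"))
            io.write_table(truth.genes_frame(), emit("truth_genes.tsv"))
            io.write_table(index_table, emit("index_sort.csv"))
            io.write_table(
                pd.DataFrame({"hoechst": hoechst_values, "s_phase": hoechst_labels}),
                emit("hoechst.csv"),
            )
            # stand-in TF list: the planted archetype signatures plus a
            # slice of background genes, so the correlogram has candidates
            sig = truth.archetype_signature if truth.archetype_signature is not None else []
            tf_list = sorted(set(truth.gene_ids[np.asarray(sig) != ""]))
            tf_list += [g for g in matrix.gene_ids if g.startswith("Gene")][:100]
        else:
            truth = None
            matrix = io.read_count_matrix(config.matrix_dir)
            metadata = io.read_metadata(config.metadata_path)
            index_table = io.read_table(config.index_sort_path) if config.index_sort_path else None
            hoechst_values = (
                io.read_table(config.hoechst_path).iloc[:, 0].to_numpy()
                if config.hoechst_path
                else None
            )
            tf_list = io.read_gene_list(config.tf_list_path) if config.tf_list_path else []
        log.info("stage %s done (%d genes x %d cells)", stage, matrix.n_genes, matrix.n_cells)

        stage = "qc"
        thresholds = qc.QCThresholds(
            actb_gene=config.actb_gene,
            actb_percentile=config.actb_percentile,
            min_total_counts=config.min_total_counts,
        )
        filtered, expr, report, outcomes = qc.run_qc(matrix, metadata, thresholds)
        io.write_table(report, emit("qc_report.tsv"))
        io.write_count_matrix(filtered, out, prefix="filtered_")
        manifest["artifacts"] += ["filtered_matrix.mtx", "filtered_genes.tsv", "filtered_cells.tsv"]
        log.info("stage qc done (%d cells passed)", filtered.n_cells)
        if stop_after == "qc":
            return _finish(out, manifest)

        stage = "cluster"
        hvg = cluster.select_hvg(expr, config.hvg_mean_cutoff, config.hvg_dispersion_cutoff)
        if len(hvg.gene_ids) == 0:
            raise RuntimeError("no highly variable genes selected; cutoffs too strict")
        emb = cluster.scale_and_pca(expr, hvg, n_components=config.n_pcs)
        graph = cluster.build_snn_graph(emb.pca_scores, dims=config.snn_dims, k_neighbors=config.snn_k)
        clusters = cluster.cluster_louvain(graph, resolution=config.resolution, seed=stage_seed(config.seed, "cluster"))
        tsne = cluster.embed_tsne(
            emb.pca_scores, dims=config.tsne_dims, perplexity=min(config.perplexity, (expr.n_cells - 1) / 3 - 1), seed=config.tsne_seed
        )
        emb.tsne_coords, emb.tsne_seed, emb.perplexity = tsne, config.tsne_seed, config.perplexity
        pcs = pd.DataFrame(emb.pca_scores, columns=[f"PC{i+1}" for i in range(emb.pca_scores.shape[1])])
        pcs.insert(0, "cell_id", expr.cell_ids)
        io.write_table(pcs, emit("embeddings.tsv"))
        io.write_table(
            pd.DataFrame({"cell_id": expr.cell_ids, "tSNE1": tsne[:, 0], "tSNE2": tsne[:, 1]}),
            emit("tsne.tsv"),
        )
        io.write_table(
            pd.DataFrame({"cell_id": expr.cell_ids, "cluster": clusters.labels}),
            emit("clusters.tsv"),
        )
        log.info("stage cluster done (%d clusters)", clusters.labels.max() + 1)
        if stop_after == "cluster":
            return _finish(out, manifest)

        stage = "trajectory"
        meta_idx = metadata.set_index("cell_id")
        if truth is not None:
            pop = dict(zip(truth.cell_ids, truth.population_label))
            traj_mask = np.array([pop.get(c) == config.trajectory_population for c in expr.cell_ids])
        else:
            traj_mask = np.ones(expr.n_cells, dtype=bool)
        coords = tsne[traj_mask]
        traj_cells = expr.cell_ids[traj_mask]
        centroids = trajectory.compute_condition_centroids(coords, metadata, cell_ids=traj_cells)
        curve = trajectory.fit_principal_curve(centroids)
        assignment = trajectory.project_pseudotime(coords, curve, centroids, cell_ids=traj_cells)
        io.write_table(assignment.frame(), emit("pseudotime.tsv"))
        traj_expr = expr.subset_cells(traj_cells)
        trends = trajectory.fit_gene_trends(traj_expr, assignment.pseudotime)
        io.write_table(trends, emit("gene_trends.tsv"))
        up, down = trajectory.select_extreme_slope_genes(trends, k=config.slope_top_k)
        heat_expr = traj_expr.subset_genes(np.array(up + down, dtype=object))
        order = trajectory.order_genes_hierarchically(heat_expr)
        heat = pd.DataFrame(
            heat_expr.subset_genes(np.array(order, dtype=object)).values,
            index=order,
            columns=list(traj_cells),
        )
        heat = heat.iloc[:, np.argsort(assignment.pseudotime, kind="stable")]
        heat.insert(0, "gene_id", heat.index)
        io.write_table(heat, emit("heatmap_matrix.tsv"))
        log.info("stage trajectory done (%d trajectory cells)", int(traj_mask.sum()))
        if stop_after == "trajectory":
            return _finish(out, manifest)

        stage = "markers"
        marker_table = markers.find_cluster_markers(
            expr, clusters.labels, logfc_threshold=config.marker_logfc_threshold
        )
        io.write_table(marker_table, emit("markers.tsv"))
        if tf_list:
            correlogram = markers.select_tf_correlogram(
                marker_table,
                tf_list,
                expr,
                min_diff_pct=config.tf_min_diff_pct,
                logfc_min=config.tf_logfc_min,
                min_pct=config.tf_min_pct,
                fdr_max=config.tf_fdr_max,
                top_n=config.tf_top_n,
            )
            correlogram.correlation.to_csv(emit("tf_correlogram.csv"))
            io.write_table(correlogram.tf_cluster, emit("tf_clusters.tsv"))
        log.info("stage markers done (%d records)", len(marker_table))
        if stop_after == "markers":
            return _finish(out, manifest)

        stage = "cytometry"
        if index_table is not None:
            normalized = cytometry.normalize_index_sort(index_table)
            io.write_table(normalized, emit("index_sort_normalized.csv"))
            label_map = dict(zip(expr.cell_ids, (f"cluster{l}" for l in clusters.labels)))
            seq_cells = metadata.loc[
                metadata["cell_id"].isin(set(expr.cell_ids)), ["cell_id", "plate_id", "well"]
            ]
            traced, unmatched = cytometry.facs_traceback(normalized, seq_cells, label_map)
            scatter_cols = ["event_id"] + [c for c in ("CD45", "BSC-A") if c in traced.columns] + ["label"]
            io.write_table(traced[scatter_cols], emit("facs_traceback.tsv"))
            if unmatched:
                io.write_table(pd.DataFrame({"cell_id": unmatched}), emit("facs_unmatched.tsv"))
        if hoechst_values is not None:
            prolif = cytometry.estimate_s_phase_fraction(
                np.asarray(hoechst_values, float), mode_factor=config.hoechst_mode_factor
            )
            io.write_table(
                pd.DataFrame(
                    [{"group": prolif.group or "all", "threshold": prolif.threshold, "fraction_s_phase": prolif.fraction_s_phase}]
                ),
                emit("proliferation.tsv"),
            )
        log.info("stage cytometry done")
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return _finish(out, manifest)


def _finish(out: Path, manifest: dict) -> Path:
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _setup_logging(path: Path) -> None:
    log.setLevel(logging.INFO)
    for h in list(log.handlers):
        log.removeHandler(h)
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
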