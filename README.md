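# sctraj

Analysis toolkit for plate-based (Smart-Seq2-style) single-cell RNA-seq
time courses, built around a condition-centroid-anchored principal-curve
pseudotime. The package covers:

- **`sctraj.simulate`** — synthetic experiment generator: negative-binomial
  counts over a latent trajectory sampled at ordered conditions, discrete
  off-trajectory populations with planted marker signatures, a dominant
  housekeeping gene ("Actb"), `ERCC-` spike-in rows, planted QC failures,
  index-sort fluorescence tables with per-plate shifts, and a DNA-content
  (Hoechst) mixture — all with a machine-readable ground-truth record.
- **`sctraj.qc`** — control-well/spike-in removal, log2(CPM+1)
  normalization, the strict 2^16 total-count filter, the housekeeping
  1st-percentile filter, and per-plate QC accounting (sequenced /
  low-read / low-Actb / passed, with half-even percentage rounding).
- **`sctraj.cluster`** — binned-dispersion HVG selection, z-scaling + exact
  PCA with deterministic signs, shared-nearest-neighbor graph with Jaccard
  weights, seeded Louvain clustering, tSNE embedding.
- **`sctraj.trajectory`** — condition centroids, nearest-centroid
  assignment, natural cubic spline through time-ordered centroids,
  arc-length pseudotime by projection, per-gene OLS trends, extreme-slope
  gene selection, hierarchical gene ordering, loess trend smoothing with a
  95% band.
- **`sctraj.markers`** — one-vs-rest Wilcoxon marker detection
  (logfc.threshold = ln 2), TMM normalization factors, rank-based pairwise
  differential expression, and the transcription-factor correlogram
  (min.diff.pct 0.10 / logFC 0.4 / min.pct 0.3 / FDR 0.05 / top 3 per
  cluster).
- **`sctraj.cytometry`** — per-plate/per-channel index-sort normalization,
  FACS trace-back label joins, and KDE-mode-anchored S-phase fraction
  estimation.
- **`sctraj.pipeline` / `sctraj.cli`** — end-to-end orchestration from a
  YAML config with a fan-out of per-stage seeds and a reproducibility
  manifest.

## CLI

```bash
# full synthetic run (simulate -> qc -> cluster -> trajectory -> markers -> cytometry)
sctraj simulate --seed 1 --outdir run1

# stage checkpoints
sctraj qc --matrix-dir data/ --metadata data/metadata.tsv --outdir qc_out
sctraj cluster --seed 1 --outdir run1      # stop after clustering
sctraj trajectory --seed 1 --outdir run1   # stop after pseudotime
sctraj all --config config.yaml            # real data when --matrix-dir given
```

Count matrices travel as Matrix Market (`matrix.mtx` + `genes.tsv` +
`cells.tsv`); all other artifacts are TSV/CSV plus a `manifest.json`
recording the config hash, per-stage seeds and artifact list. Exit codes:
0 success, 2 configuration/validation error, 1 stage failure.

Example YAML config (all keys optional; shown with defaults):

```yaml
mode: synthetic
seed: 0
min_total_counts: 65536
actb_percentile: 1.0
hvg_mean_cutoff: 0.3
hvg_dispersion_cutoff: 0.5
n_pcs: 50
snn_dims: 17
resolution: 1.3
tsne_dims: 15
perplexity: 70
tsne_seed: 132
slope_top_k: 10
sim:                # forwarded to the synthetic generator
  n_conditions: 12
  cells_per_condition: 150
  n_genes: 2000
```

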