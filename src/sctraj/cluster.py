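"""HVG selection, scaling + PCA, SNN graph construction, Louvain, tSNE."""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
from scipy import sparse
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .datatypes import ExpressionMatrix


@dataclass
class HVGSelection:
    gene_ids: np.ndarray          # selected genes
    means: np.ndarray             # all genes, mean log2-CPM
    normalized_dispersion: np.ndarray
    mean_cutoff: float
    dispersion_cutoff: float
    n_bins: int


@dataclass
class EmbeddingResult:
    pca_scores: np.ndarray
    pca_variance: np.ndarray
    tsne_coords: np.ndarray | None = None
    tsne_seed: int | None = None
    perplexity: float | None = None


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(self.labels) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster labels must be contiguous from 0")


def select_hvg(
    expr: ExpressionMatrix,
    mean_cutoff: float = 0.3,
    dispersion_cutoff: float = 0.5,
    n_bins: int = 20,
) -> HVGSelection:
    """Mean/dispersion gene selection.

    Dispersion of a gene is ``log(var/mean)`` of its de-logged values
    (``2^v - 1``); it is z-scored within ``n_bins`` equal-width bins of the
    gene's mean log2-CPM. Both cutoffs are strict. Constant genes carry a
    dispersion of ``-inf`` and are never selected.
    """
    v = expr.values
    means = v.mean(axis=1)
    delogged = np.exp2(v) - 1.0
    dmean = delogged.mean(axis=1)
    dvar = delogged.var(axis=1, ddof=1) if v.shape[1] > 1 else np.zeros(v.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.log(dvar / dmean)
    dispersion[~np.isfinite(dispersion)] = -np.inf

    edges = np.linspace(means.min(), means.max(), n_bins + 1)
    bin_of = np.clip(np.digitize(means, edges[1:-1]), 0, n_bins - 1)
    norm_disp = np.full_like(dispersion, -np.inf)
    for b in range(n_bins):
        sel = bin_of == b
        vals = dispersion[sel]
        finite = np.isfinite(vals)
        if finite.sum() == 0:
            continue
        if finite.sum() == 1:
            warnings.warn(f"dispersion bin {b} holds a single gene; z-score set to 0", stacklevel=2)
            out = np.where(finite, 0.0, -np.inf)
        else:
            mu = vals[finite].mean()
            sd = vals[finite].std(ddof=1)
            if sd == 0:
                out = np.where(finite, 0.0, -np.inf)
            else:
                out = np.where(finite, (vals - mu) / sd, -np.inf)
        norm_disp[sel] = out

    selected = (means > mean_cutoff) & (norm_disp > dispersion_cutoff)
    return HVGSelection(
        gene_ids=expr.gene_ids[selected],
        means=means,
        normalized_dispersion=norm_disp,
        mean_cutoff=mean_cutoff,
        dispersion_cutoff=dispersion_cutoff,
        n_bins=n_bins,
    )


def scale_and_pca(
    expr: ExpressionMatrix,
    genes: HVGSelection | np.ndarray | list,
    n_components: int = 50,
    clip_max: float = 10.0,
) -> EmbeddingResult:
    """Per-gene z-scaling (clipped at ``clip_max``) followed by exact PCA.

    Sign convention: within each component the loading of largest magnitude
    is positive, which makes the decomposition deterministic.
    """
    gene_ids = genes.gene_ids if isinstance(genes, HVGSelection) else np.asarray(genes)
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 selected genes for PCA")
    sub = expr.subset_genes(gene_ids)
    X = sub.values.T.astype(float)  # cells x genes
    n_cells = X.shape[0]
    max_comp = min(n_cells - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components reduced from {n_components} to {max_comp} (too few cells/genes)",
            stacklevel=2,
        )
        n_components = max_comp

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.minimum((X - mu) / sd, clip_max)

    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic signs
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = U * S * flip
    variance = S**2 / (n_cells - 1)
    return EmbeddingResult(pca_scores=scores, pca_variance=variance)


def build_snn_graph(
    pca_scores: np.ndarray,
    dims: int = 17,
    k_neighbors: int = 20,
    prune: float = 1.0 / 15.0,
) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Neighborhoods are the ``k_neighbors`` nearest points (self included) by
    Euclidean distance in the first ``dims`` components; edges with Jaccard
    overlap below ``prune`` are dropped.
    """
    X = np.asarray(pca_scores, dtype=float)[:, : min(dims, pca_scores.shape[1])]
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(X)
    _, idx = nn.kneighbors(X)

    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (adj @ adj.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * k_neighbors - s)
    keep = jac >= prune
    g = igraph.Graph(n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())))
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_louvain(
    graph: igraph.Graph,
    resolution: float = 1.3,
    seed: int = 0,
) -> ClusterAssignment:
    """Multilevel (Louvain) modularity clustering at the given resolution."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    random.seed(seed)
    igraph.set_random_number_generator(random)
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = graph.community_multilevel(weights=weights, resolution=resolution)
    labels = np.asarray(part.membership, dtype=int)
    # relabel contiguous by first appearance for determinism
    order = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        out[i] = order.setdefault(lab, len(order))
    return ClusterAssignment(labels=out, resolution=resolution)


def embed_tsne(
    pca_scores: np.ndarray,
    dims: int = 15,
    perplexity: float = 70.0,
    seed: int = 132,
) -> np.ndarray:
    """2-D tSNE of the leading components; deterministic for a fixed seed."""
    X = np.asarray(pca_scores, dtype=float)[:, : min(dims, pca_scores.shape[1])]
    n = X.shape[0]
    bound = (n - 1) / 3.0
    if perplexity >= bound:
        raise ValueError(f"perplexity={perplexity} must be < (n_cells - 1)/3 = {bound:.2f}")
    if n and np.allclose(X, X[0]):
        return np.zeros((n, 2))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(X)
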