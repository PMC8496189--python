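"""Cluster markers, TMM normalization factors, pairwise DE, TF correlogram.

Marker log fold changes are on the natural-log scale:
``ln(mean(2^v - 1) + 1)`` within the cluster minus the same outside, which
makes a threshold of ``log(2)`` mean "twofold in de-logged expression".
Rank-based (Wilcoxon) p-values are used throughout; moderated linear models
are deliberately not reimplemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix


def find_cluster_markers(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    logfc_threshold: float = np.log(2.0),
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """One-vs-rest marker table per cluster.

    A gene is tested for a cluster when its in/out log fold change is at
    least ``logfc_threshold`` and it is expressed (value > 0) in at least
    ``min_pct`` of cells on the higher side. P-values are Wilcoxon rank-sum,
    Bonferroni-adjusted over all tests performed.
    """
    labels = np.asarray(labels)
    if expr.n_cells != len(labels):
        raise ValueError("labels length must match number of cells")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    delog = np.exp2(expr.values) - 1.0
    detected = expr.values > 0

    rows = []
    for cl in uniq:
        inside = labels == cl
        if inside.sum() < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; skipped", stacklevel=2)
            continue
        outside = ~inside
        mean_in = delog[:, inside].mean(axis=1)
        mean_out = delog[:, outside].mean(axis=1)
        logfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
        pct_in = detected[:, inside].mean(axis=1)
        pct_out = detected[:, outside].mean(axis=1)
        test = (logfc >= logfc_threshold) & (np.maximum(pct_in, pct_out) >= min_pct)
        for g in np.nonzero(test)[0]:
            a, b = expr.values[g, inside], expr.values[g, outside]
            p = _ranksum_p(a, b)
            rows.append(
                {
                    "gene_id": expr.gene_ids[g],
                    "cluster": cl,
                    "log_fold_change": float(logfc[g]),
                    "pct_in": float(pct_in[g]),
                    "pct_out": float(pct_out[g]),
                    "p_value": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "cluster", "log_fold_change", "pct_in", "pct_out", "p_value"],
    )
    n_tests = len(out)
    out["p_adjusted"] = np.minimum(out["p_value"] * max(n_tests, 1), 1.0)
    return out


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


@dataclass
class TMMFactors:
    factors: np.ndarray
    reference: int

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.size and abs(np.exp(np.log(self.factors).mean()) - 1.0) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")


def tmm_normalization_factors(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> TMMFactors:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Reference library: the one whose 75th-percentile count fraction is
    closest to the mean of those fractions. Per library, gene-wise log2
    ratios (M) and average abundances (A) against the reference are doubly
    trimmed (``trim_m`` per tail on M, ``trim_a`` per tail on A) and the
    factor is ``2**(precision-weighted mean of the surviving M)``.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a genes x libraries matrix with >= 2 libraries")
    libsize = X.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValueError("library sizes must be positive")

    q75 = np.array([np.percentile(X[:, j], 75) for j in range(X.shape[1])]) / libsize
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref:
            continue
        ok = (X[:, j] > 0) & (X[:, ref] > 0)
        if not ok.any():
            warnings.warn(f"library {j} shares no expressed genes with reference; factor 1", stacklevel=2)
            continue
        pj = X[ok, j] / libsize[j]
        pr = X[ok, ref] / libsize[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (libsize[j] - X[ok, j]) / (libsize[j] * X[ok, j]) + (
            libsize[ref] - X[ok, ref]
        ) / (libsize[ref] * X[ok, ref])
        n = len(M)
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            continue
        log_factors[j] = np.average(M[keep], weights=1.0 / w[keep])

    factors = np.exp2(log_factors)
    factors = factors / np.exp(np.log(factors).mean())
    return TMMFactors(factors=factors, reference=ref)


def pairwise_differential_expression(
    counts: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank-based DE between two groups of libraries on TMM-scaled log2-CPM.

    Returns gene, log2 fold change of group means (A minus B), Wilcoxon
    rank-sum p and Benjamini-Hochberg FDR.
    """
    X = np.asarray(counts, dtype=float)
    ga = np.asarray(group_a)
    gb = np.asarray(group_b)
    if ga.dtype == bool:
        ga = np.nonzero(ga)[0]
    if gb.dtype == bool:
        gb = np.nonzero(gb)[0]
    if len(ga) < 3 or len(gb) < 3:
        raise ValueError("each group needs at least 3 libraries")
    if set(ga) & set(gb):
        raise ValueError("groups overlap")

    cols = np.concatenate([ga, gb])
    sub = X[:, cols]
    tmm = tmm_normalization_factors(sub)
    eff = sub.sum(axis=0) * tmm.factors
    logcpm = np.log2(1e6 * sub / eff[np.newaxis, :] + 1.0)

    na = len(ga)
    A, B = logcpm[:, :na], logcpm[:, na:]
    logfc = A.mean(axis=1) - B.mean(axis=1)
    pvals = np.array([_ranksum_p(A[g], B[g]) for g in range(X.shape[0])])
    fdr = _bh_adjust(pvals)
    if gene_ids is None:
        gene_ids = np.array([f"gene{g}" for g in range(X.shape[0])], dtype=object)
    return pd.DataFrame({"gene_id": gene_ids, "log_fold_change": logfc, "p_value": pvals, "fdr": fdr})


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class TFCorrelogram:
    tf_cluster: pd.DataFrame       # tf, cluster, log_fold_change
    correlation: pd.DataFrame      # square, indexed by tf


def select_tf_correlogram(
    markers: pd.DataFrame,
    tf_list: list[str],
    expr: ExpressionMatrix,
    min_diff_pct: float = 0.10,
    logfc_min: float = 0.4,
    min_pct: float = 0.3,
    fdr_max: float = 0.05,
    top_n: int = 3,
) -> TFCorrelogram:
    """Pick the strongest transcription-factor markers and correlate them.

    Filters marker records restricted to ``tf_list``:
    ``pct_in - pct_out >= min_diff_pct``, ``log_fold_change >= logfc_min``,
    ``pct_in >= min_pct`` and ``p_adjusted < fdr_max``. Per cluster keep the
    ``top_n`` by log fold change; a TF claimed by several clusters goes to
    the cluster where its log fold change is highest. The correlation matrix
    is Pearson on log2-CPM across all cells.
    """
    if not tf_list:
        raise ValueError("tf_list is empty")
    sub = markers[markers["gene_id"].isin(tf_list)].copy()
    sub = sub[
        (sub["pct_in"] - sub["pct_out"] >= min_diff_pct)
        & (sub["log_fold_change"] >= logfc_min)
        & (sub["pct_in"] >= min_pct)
        & (sub["p_adjusted"] < fdr_max)
    ]
    # unique ownership: strongest cluster wins
    sub = sub.sort_values(["gene_id", "log_fold_change"], ascending=[True, False])
    sub = sub.drop_duplicates("gene_id", keep="first")
    sub = (
        sub.sort_values(["cluster", "log_fold_change"], ascending=[True, False])
        .groupby("cluster", sort=True)
        .head(top_n)
        .reset_index(drop=True)
    )
    if sub.empty:
        warnings.warn("no transcription factor passed the correlogram filters", stacklevel=2)
        return TFCorrelogram(
            tf_cluster=pd.DataFrame(columns=["gene_id", "cluster", "log_fold_change"]),
            correlation=pd.DataFrame(),
        )
    tfs = list(sub["gene_id"])
    mat = np.vstack([expr.gene_vector(t) for t in tfs])
    corr = np.corrcoef(mat)
    corr = pd.DataFrame(np.atleast_2d(corr), index=tfs, columns=tfs)
    return TFCorrelogram(
        tf_cluster=sub[["gene_id", "cluster", "log_fold_change"]],
        correlation=corr,
    )
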