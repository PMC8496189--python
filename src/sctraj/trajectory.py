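"""Condition-centroid-anchored pseudotime and per-gene expression trends.

The trajectory is a natural cubic spline interpolating the condition
centroids in experimental-time order, parameterized by chord length and
densely resampled; a cell's pseudotime is the normalized cumulative arc
length of its nearest sampled curve point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .datatypes import ExpressionMatrix


@dataclass
class ConditionCentroid:
    condition: str
    time_order: int
    x: float
    y: float


@dataclass
class PrincipalCurve:
    points: np.ndarray          # sampled (x, y), ordered
    arc_length: np.ndarray      # cumulative, same length as points
    anchor_arc_length: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class PseudotimeAssignment:
    cell_ids: np.ndarray
    pseudotime: np.ndarray
    nearest_centroid: np.ndarray
    projection_distance: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "pseudotime": self.pseudotime,
                "nearest_centroid": self.nearest_centroid,
                "projection_distance": self.projection_distance,
            }
        )


def compute_condition_centroids(
    coords: np.ndarray,
    metadata: pd.DataFrame,
    condition_subset: list[str] | None = None,
    cell_ids: np.ndarray | None = None,
) -> list[ConditionCentroid]:
    """Mean embedding coordinates per condition, in time order.

    ``coords`` rows must align with ``metadata`` rows (or with ``cell_ids``
    which are then matched against the metadata).
    """
    coords = np.asarray(coords, dtype=float)
    meta = metadata
    if cell_ids is not None:
        meta = metadata.set_index("cell_id").loc[list(cell_ids)].reset_index()
    if len(meta) != len(coords):
        raise ValueError("coords and metadata length mismatch")
    conditions = (
        condition_subset
        if condition_subset is not None
        else list(meta.sort_values("condition_time_order")["condition"].unique())
    )
    out = []
    for cond in conditions:
        sel = (meta["condition"] == cond).to_numpy()
        if not sel.any():
            raise ValueError(f"condition {cond!r} has no cells")
        order = int(meta.loc[sel, "condition_time_order"].iloc[0])
        xy = coords[sel].mean(axis=0)
        out.append(ConditionCentroid(cond, order, float(xy[0]), float(xy[1])))
    out.sort(key=lambda c: c.time_order)
    return out


def assign_nearest_centroid(
    coords: np.ndarray, centroids: list[ConditionCentroid]
) -> np.ndarray:
    """Condition label of the nearest centroid per cell; ties go to the
    earlier time_order."""
    if not centroids:
        raise ValueError("need at least one centroid")
    ordered = sorted(centroids, key=lambda c: c.time_order)
    pts = np.array([[c.x, c.y] for c in ordered])
    d = np.linalg.norm(np.asarray(coords, float)[:, None, :] - pts[None, :, :], axis=2)
    idx = d.argmin(axis=1)  # argmin returns first minimum -> earlier order wins
    return np.array([ordered[i].condition for i in idx], dtype=object)


def fit_principal_curve(
    centroids: list[ConditionCentroid],
    samples_per_segment: int = 128,
) -> PrincipalCurve:
    """Natural cubic spline through the time-ordered centroids.

    Parameterized by cumulative chord length between anchors and resampled
    at ``samples_per_segment`` points per segment; arc length is measured on
    the resampled polyline. Coincident consecutive centroids collapse to a
    single anchor with a warning.
    """
    ordered = sorted(centroids, key=lambda c: c.time_order)
    anchors = np.array([[c.x, c.y] for c in ordered], dtype=float)
    keep = [0]
    for i in range(1, len(anchors)):
        if np.linalg.norm(anchors[i] - anchors[keep[-1]]) < 1e-12:
            warnings.warn(
                f"coincident consecutive centroids collapsed (index {i})", stacklevel=2
            )
        else:
            keep.append(i)
    anchors = anchors[keep]
    if len(anchors) < 2:
        raise ValueError("need at least 2 distinct centroids")

    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(anchors, axis=0), axis=1))])
    n_seg = len(anchors) - 1
    if len(anchors) == 2:
        ts = np.linspace(chord[0], chord[-1], samples_per_segment + 1)
        pts = np.column_stack(
            [np.interp(ts, chord, anchors[:, 0]), np.interp(ts, chord, anchors[:, 1])]
        )
    else:
        spline = CubicSpline(chord, anchors, bc_type="natural")
        ts = np.unique(
            np.concatenate(
                [
                    np.linspace(chord[i], chord[i + 1], samples_per_segment + 1)
                    for i in range(n_seg)
                ]
            )
        )
        # make sure every anchor parameter is included exactly
        ts = np.unique(np.concatenate([ts, chord]))
        pts = spline(ts)

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    anchor_idx = np.searchsorted(ts, chord)
    return PrincipalCurve(points=pts, arc_length=arc, anchor_arc_length=arc[anchor_idx])


def project_pseudotime(
    coords: np.ndarray,
    curve: PrincipalCurve,
    centroids: list[ConditionCentroid] | None = None,
    cell_ids: np.ndarray | None = None,
) -> PseudotimeAssignment:
    """Normalized arc length of each cell's nearest sampled curve point."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(curve.points)
    dist, idx = tree.query(coords)
    pt = curve.arc_length[idx] / curve.total_length if curve.total_length > 0 else np.zeros(len(coords))
    nearest = (
        assign_nearest_centroid(coords, centroids)
        if centroids
        else np.array([""] * len(coords), dtype=object)
    )
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(len(coords))], dtype=object)
    return PseudotimeAssignment(
        cell_ids=np.asarray(cell_ids, dtype=object),
        pseudotime=pt,
        nearest_centroid=nearest,
        projection_distance=dist,
    )


def fit_gene_trends(expr: ExpressionMatrix, pseudotime: np.ndarray) -> pd.DataFrame:
    """Ordinary least squares of each gene's log2-CPM on pseudotime.

    Returns a frame with gene_id, slope, intercept and r_squared, computed
    from the closed-form normal equations; genes with zero variance get
    slope 0 and r_squared 0.
    """
    t = np.asarray(pseudotime, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("pseudotime has zero variance")
    if expr.n_cells != len(t):
        raise ValueError("pseudotime length must match number of cells")
    Y = expr.values
    tc = t - t.mean()
    stt = (tc**2).sum()
    slope = (Y @ tc) / stt
    intercept = Y.mean(axis=1) - slope * t.mean()
    fitted = intercept[:, None] + slope[:, None] * t[None, :]
    ss_res = ((Y - fitted) ** 2).sum(axis=1)
    ss_tot = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "slope": slope,
            "intercept": intercept,
            "r_squared": np.clip(r2, 0.0, 1.0),
        }
    )


def select_extreme_slope_genes(trends: pd.DataFrame, k: int = 10) -> tuple[list, list]:
    """Top-k genes by most positive and most negative slope.

    Ties break lexicographically on gene_id so the selection is
    deterministic; the two sets are disjoint by construction.
    """
    n = len(trends)
    if k > n // 2:
        raise ValueError(f"k={k} exceeds half the number of genes ({n})")
    up = trends.sort_values(["slope", "gene_id"], ascending=[False, True])
    up_genes = list(up["gene_id"].iloc[:k])
    rest = trends[~trends["gene_id"].isin(up_genes)]
    down = rest.sort_values(["slope", "gene_id"], ascending=[True, True])
    return up_genes, list(down["gene_id"].iloc[:k])


def order_genes_hierarchically(expr_subset: ExpressionMatrix) -> list:
    """Dendrogram leaf order of genes (average linkage, Euclidean on
    per-gene z-scored rows)."""
    if expr_subset.n_genes == 1:
        return list(expr_subset.gene_ids)
    X = expr_subset.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    order = leaves_list(linkage(Z, method="average", metric="euclidean"))
    return list(expr_subset.gene_ids[order])


def smooth_gene_trend(
    expr_gene: np.ndarray,
    pseudotime: np.ndarray,
    span: float = 0.75,
    eval_points: np.ndarray | None = None,
) -> pd.DataFrame:
    """Loess (local linear, tricube weights) fit with a pointwise 95% band.

    Returns a frame with columns x, fit, lower, upper evaluated at
    ``eval_points`` (default: the sorted pseudotimes).
    """
    y = np.asarray(expr_gene, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    n = len(t)
    if n < 10:
        raise ValueError("need at least 10 cells for loess smoothing")
    k = int(np.ceil(span * n))
    if k < 4:
        warnings.warn("span too small for local linear fits; widened", stacklevel=2)
        k = min(4, n)
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    xs = np.sort(eval_points) if eval_points is not None else ts

    fit = np.empty(len(xs))
    se = np.empty(len(xs))
    # residual variance from a pilot pass at the data points
    sigma2 = None
    for pass_no in range(2):
        targets = ts if pass_no == 0 else xs
        out_fit = np.empty(len(targets))
        out_se = np.empty(len(targets))
        for i, x0 in enumerate(targets):
            d = np.abs(ts - x0)
            h = np.partition(d, k - 1)[k - 1]
            if h == 0:
                h = max(d.max(), 1e-12)
            w = np.clip(1 - (d / h) ** 3, 0, 1) ** 3
            sw = w > 0
            Xd = np.column_stack([np.ones(sw.sum()), ts[sw] - x0])
            W = w[sw]
            XtWX = Xd.T @ (Xd * W[:, None])
            XtWy = Xd.T @ (W * ys[sw])
            try:
                beta = np.linalg.solve(XtWX, XtWy)
                inv = np.linalg.inv(XtWX)
                # equivalent-kernel weights l(x0)
                l = inv[0] @ (Xd * W[:, None]).T
            except np.linalg.LinAlgError:
                beta = np.array([np.average(ys[sw], weights=W), 0.0])
                l = W / W.sum()
            out_fit[i] = beta[0]
            out_se[i] = np.sqrt((l**2).sum())
        if pass_no == 0:
            resid = ys - out_fit
            dof = max(n - 2, 1)
            sigma2 = float((resid**2).sum() / dof)
            if eval_points is None:
                fit, se = out_fit, out_se
                break
        else:
            fit, se = out_fit, out_se
    band = 1.96 * np.sqrt(max(sigma2, 1e-300)) * se
    # keep a strictly positive band even for perfectly flat data
    band = np.maximum(band, 1e-12)
    return pd.DataFrame({"x": xs, "fit": fit, "lower": fit - band, "upper": fit + band})
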